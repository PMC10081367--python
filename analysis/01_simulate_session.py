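#!/usr/bin/env python
"""Generate the study's synthetic dataset: one animal, 3 days x 12
trials alternating between two contexts, 200 place cells (15%
feature-sensitive), plus ground truth.

Writes results/session/ (trajectory.csv, events.csv, trials.csv,
ground_truth.json, config.json).
"""

import argparse
from pathlib import Path

from reorient.synth import SessionConfig, generate_session, write_session

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    config = SessionConfig(seed=args.seed)
    session = generate_session(config)
    out = write_session(session, RESULTS / "session")

    meta = session.trials_frame()
    n_fs = sum(1 for l in session.ground_truth.labels if l == "FS")
    print(f"wrote {out}")
    print(f"trials: {len(meta)} over {config.n_days} days; "
          f"contexts per day: {meta.groupby('day')['context'].value_counts().iloc[0]} each")
    print(f"cells: {config.n_cells} ({n_fs} FS ground truth)")
    print("dig outcomes:", meta["dig"].value_counts().to_dict())


if __name__ == "__main__":
    main()
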