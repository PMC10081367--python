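"""Parameter-recovery and calibration measurements on synthetic sessions.

These helpers run the full analysis chain on generated data and compare
the outcome against the generator's ground truth: FS/FI label recovery,
heading and context decoding under known coupling, rate-code decoding
under planted gain differences, Rayleigh-test type-I calibration, and
the structural rotation/center-out signatures expected from
feature-insensitive cells in a two-fold-symmetric arena.
"""

from __future__ import annotations

import numpy as np

from .alignment import FS_FI_CUTOFF
from .decoding import predict_context_dotproduct, predict_from_rates, predict_heading
from .pipeline import (
    AlignmentOutput,
    MapsResult,
    analyze_alignment,
    compute_session_maps,
    _day_cells,
)
from .population import (
    center_out_difference,
    difference_distribution,
    rayleigh_test,
)
from .geometry import center_out_angle, rotation_distribution
from .ratemaps import RateMapParams, filter_by_speed, mean_event_rate
from .synth import Session, SessionConfig, generate_session

__all__ = [
    "SessionAnalysis",
    "analyze",
    "fs_fi_recovery",
    "heading_accuracy",
    "heading_permutation_null",
    "context_dotproduct_accuracy",
    "rate_context_accuracy",
    "session_mfr",
    "rayleigh_type1_error",
    "best_match_concentration",
    "center_out_modal_mass",
]


class SessionAnalysis:
    """Session + rate maps + per-cell alignment, computed once."""

    def __init__(self, config: SessionConfig, params: RateMapParams = RateMapParams()):
        self.session: Session = generate_session(config)
        self.maps: MapsResult = compute_session_maps(self.session, params)
        self.alignment: AlignmentOutput = analyze_alignment(self.maps)


def analyze(config: SessionConfig) -> SessionAnalysis:
    return SessionAnalysis(config)


def fs_fi_recovery(sa: SessionAnalysis) -> tuple[float, int]:
    """Fraction of (cell, day) FS/FI labels matching ground truth."""
    gt = sa.session.ground_truth.labels
    labeled = sa.alignment.profiles[
        sa.alignment.profiles["label"].isin(["FS", "FI"])
    ]
    hits = [gt[int(r.cell_id)] == r.label for r in labeled.itertuples(index=False)]
    return float(np.mean(hits)), len(hits)


def _day_heading(sa: SessionAnalysis, day: int, group: str, digs=None):
    cells = _day_cells(sa.alignment, day, group)
    if len(cells) == 0:
        return None
    sel = np.flatnonzero(sa.maps.days == day)
    seqs = [sa.alignment.details[(day, c)].rotation_bits for c in cells]
    digs = sa.maps.digs[sel] if digs is None else digs
    try:
        return predict_heading(seqs, digs)
    except ValueError:
        return None


def heading_accuracy(sa: SessionAnalysis, group: str = "FI"):
    """Per-day heading (C vs G) decoding accuracy; pooled over days."""
    correct = total = 0
    per_day = {}
    for day in np.unique(sa.maps.days):
        res = _day_heading(sa, int(day), group)
        if res is None:
            continue
        per_day[int(day)] = res.accuracy
        correct += int(round(res.accuracy * res.n))
        total += res.n
    pooled = correct / total if total else float("nan")
    return pooled, total, per_day


def heading_permutation_null(
    sa: SessionAnalysis, n_perm: int = 200, seed: int = 0, group: str = "FI"
) -> np.ndarray:
    """Null pooled accuracies from shuffling dig labels within each day."""
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    days = np.unique(sa.maps.days)
    for p in range(n_perm):
        correct = total = 0
        for day in days:
            sel = np.flatnonzero(sa.maps.days == day)
            digs = sa.maps.digs[sel].copy()
            rng.shuffle(digs)
            res = _day_heading(sa, int(day), group, digs=digs)
            if res is None:
                continue
            correct += int(round(res.accuracy * res.n))
            total += res.n
        accs[p] = correct / total if total else np.nan
    return accs


def context_dotproduct_accuracy(sa: SessionAnalysis, group: str = "FS"):
    """Pooled firing-location context-prediction accuracy for one group."""
    correct = total = 0
    for day in np.unique(sa.maps.days):
        day = int(day)
        cells = _day_cells(sa.alignment, day, group)
        if len(cells) == 0:
            continue
        sel = np.flatnonzero(sa.maps.days == day)
        stack = np.stack(
            [np.stack(sa.alignment.details[(day, c)].aligned_maps) for c in cells]
        )
        res = predict_context_dotproduct(stack, sa.maps.contexts[sel])
        correct += int(round(res.accuracy * res.n))
        total += res.n
    return (correct / total if total else float("nan")), total


def session_mfr(session: Session, params: RateMapParams = RateMapParams()):
    """Per-trial mean firing rates (no maps needed) from filtered data."""
    n_cells = session.config.n_cells
    mfr = np.zeros((len(session.trials), n_cells))
    for ti, trial in enumerate(session.trials):
        traj, events = filter_by_speed(
            trial.trajectory, trial.events, params.speed_threshold_cm_s
        )
        dt = float(np.median(np.diff(trial.trajectory["t"].to_numpy())))
        move_t = len(traj) * dt
        if move_t <= 0:
            continue
        for ci, grp in events.groupby("cell_id"):
            mfr[ti, int(ci)] = mean_event_rate(grp, move_t)
    return mfr


def rate_context_accuracy(session: Session):
    """Pooled rate-code context decoding accuracy across days."""
    mfr = session_mfr(session)
    meta = session.trials_frame()
    correct = total = 0
    for day in sorted(meta["day"].unique()):
        sel = meta["day"] == day
        try:
            res = predict_from_rates(
                mfr[sel.to_numpy()],
                meta.loc[sel, "context"].to_numpy(),
                meta.loc[sel, "dig"].to_numpy(),
                "context",
            )
        except ValueError:
            continue
        correct += int(round(res.accuracy * res.n))
        total += res.n
    return (correct / total if total else float("nan")), total


def rayleigh_type1_error(
    n_replicates: int = 2000, n_samples: int = 100, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical rejection rate of the Rayleigh test under a uniform null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        angles = rng.uniform(0.0, 360.0, size=n_samples)
        if rayleigh_test(angles).pvalue < alpha:
            rejections += 1
    return rejections / n_replicates


def best_match_concentration(sa: SessionAnalysis, group: str = "FI", day: int = 0):
    """Mean per-cell proportion of best-match rotations at 0 and 180."""
    cells = _day_cells(sa.alignment, day, group)
    sel = np.flatnonzero(sa.maps.days == day)
    props = {0: [], 90: [], 180: [], 270: []}
    for c in cells:
        try:
            rd = rotation_distribution([sa.maps.values[c, t] for t in sel])
        except ValueError:
            continue
        for ang in props:
            if np.isfinite(rd["proportions"][ang]):
                props[ang].append(rd["proportions"][ang])
    mean_props = {ang: float(np.mean(v)) if v else float("nan") for ang, v in props.items()}
    return mean_props


def center_out_modal_mass(sa: SessionAnalysis, group: str = "FI"):
    """Joint mass of the two modal 6-degree bins of across-context
    center-out differences, pooled over days; also whether those bins sit
    at 0 and 180 degrees."""
    diffs = []
    for day in np.unique(sa.maps.days):
        day = int(day)
        cells = _day_cells(sa.alignment, day, group)
        sel = np.flatnonzero(sa.maps.days == day)
        ctx = sa.maps.contexts[sel]
        for c in cells:
            angles = np.full(len(sel), np.nan)
            for k, t in enumerate(sel):
                try:
                    angles[k] = center_out_angle(sa.maps.rate_map(c, t))
                except ValueError:
                    pass
            for i in range(len(sel)):
                for j in range(len(sel)):
                    if ctx[i] == "A" and ctx[j] == "B":
                        d = center_out_difference(angles[i], angles[j])
                        if np.isfinite(d):
                            diffs.append(d)
    dist = difference_distribution(diffs)
    order = np.argsort(dist.probabilities)[::-1]
    top2 = order[:2]
    modal_mass = float(dist.probabilities[top2].sum())
    modal_bins = sorted(float(dist.bin_centers[k]) for k in top2)
    return modal_mass, modal_bins, len(diffs)
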