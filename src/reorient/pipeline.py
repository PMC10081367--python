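"""End-to-end orchestration: session -> maps -> alignment -> decoding -> behavior.

Each analysis day is treated as one recording session: trial maps are
built from speed-filtered data, each cell's maps are rotation-aligned
within and across contexts, cells are labeled FS/FI by context
similarity, and the per-day decoding, population and circular analyses
run on top.  :func:`run_pipeline` wires the stages together with
content-hash caching and writes tidy CSV/JSON/HDF5 artifacts plus a
machine-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import behavior as bhv
from .alignment import FS_FI_CUTOFF, CellContextProfile, align_session
from .geometry import center_out_angle, rotation_distribution
from .population import (
    center_out_difference,
    difference_distribution,
    double_angles,
    pixelwise_population_cosine,
    rayleigh_test,
)
from .decoding import (
    predict_context_dotproduct,
    predict_from_rates,
    predict_heading,
    rate_difference_matrix,
)
from .ratemaps import (
    RateMap,
    RateMapParams,
    TrialMapBuilder,
    filter_by_speed,
    mean_event_rate,
)
from .synth import Session, SessionConfig, generate_session, read_session, write_session

log = logging.getLogger("reorient")

__all__ = [
    "RunConfig",
    "MapsResult",
    "compute_session_maps",
    "analyze_alignment",
    "analyze_decoding",
    "analyze_population",
    "analyze_behavior",
    "run_pipeline",
]


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out: str = "results/run"
    session_dir: str | None = None  # load an existing session instead
    session: dict = {}  # overrides for SessionConfig
    ratemap: dict = {}  # overrides for RateMapParams
    fs_fi_cutoff: float = FS_FI_CUTOFF
    svm_c: float = 1.0
    n_behavior_animals: int = 14
    write_h5: bool = True
    verbosity: str = "INFO"

    def model_post_init(self, __context):
        # construct the nested configs now so schema errors surface
        # before any computation
        self.session_config()
        self.ratemap_params()

    def session_config(self) -> SessionConfig:
        return SessionConfig(seed=self.seed, **self.session)

    def ratemap_params(self) -> RateMapParams:
        return RateMapParams(**self.ratemap)


@dataclass
class MapsResult:
    """Per-(cell, trial) masked rate maps plus trial rate summaries."""

    values: np.ndarray  # (n_cells, n_trials, n_rows, n_cols), NaN unsampled
    mfr: np.ndarray  # (n_trials, n_cells) mean firing rates
    movement_time_s: np.ndarray  # per trial
    bin_cm: float
    days: np.ndarray
    contexts: np.ndarray
    digs: np.ndarray

    def rate_map(self, cell: int, trial: int) -> RateMap:
        v = self.values[cell, trial]
        return RateMap(values=v, mask=np.isfinite(v), bin_cm=self.bin_cm)


def compute_session_maps(session: Session, params: RateMapParams) -> MapsResult:
    """Speed-filter every trial and build per-cell rate maps and MFRs."""
    n_cells = session.config.n_cells
    n_trials = len(session.trials)
    first = None
    values = None
    mfr = np.zeros((n_trials, n_cells))
    move_t = np.zeros(n_trials)
    for ti, trial in enumerate(session.trials):
        traj, events = filter_by_speed(
            trial.trajectory, trial.events, params.speed_threshold_cm_s
        )
        dt = float(np.median(np.diff(trial.trajectory["t"].to_numpy())))
        move_t[ti] = len(traj) * dt
        builder = TrialMapBuilder(traj, session.arena, params)
        by_cell = dict(tuple(events.groupby("cell_id")[["t", "weight"]]))
        empty = events.iloc[:0][["t", "weight"]]
        for ci in range(n_cells):
            ev = by_cell.get(ci, empty)
            rm = builder.build(ev)
            if first is None:
                first = rm.shape
                values = np.full((n_cells, n_trials) + first, np.nan)
            values[ci, ti] = rm.masked_values()
            if move_t[ti] > 0:
                mfr[ti, ci] = mean_event_rate(ev, move_t[ti])
    meta = session.trials_frame()
    return MapsResult(
        values=values,
        mfr=mfr,
        movement_time_s=move_t,
        bin_cm=params.bin_cm,
        days=meta["day"].to_numpy(),
        contexts=meta["context"].to_numpy(),
        digs=meta["dig"].to_numpy(),
    )


@dataclass
class AlignmentOutput:
    profiles: pd.DataFrame  # one row per (cell, day)
    details: dict = field(repr=False, default_factory=dict)  # (day, cell) -> profile


def analyze_alignment(maps: MapsResult, cutoff: float = FS_FI_CUTOFF) -> AlignmentOutput:
    """Rotation-align every cell's trial maps day by day and label FS/FI."""
    rows, details = [], {}
    n_cells = maps.values.shape[0]
    for day in np.unique(maps.days):
        sel = np.flatnonzero(maps.days == day)
        contexts = maps.contexts[sel].tolist()
        for ci in range(n_cells):
            trial_maps = [maps.values[ci, t] for t in sel]
            if not any(np.nanmax(m) > 0 for m in trial_maps if np.isfinite(m).any()):
                continue  # silent cell this day
            prof = align_session(trial_maps, contexts, cutoff=cutoff, keep_maps=True)
            details[(int(day), ci)] = prof
            rows.append(
                {
                    "cell_id": ci,
                    "day": int(day),
                    "context_similarity": prof.context_similarity,
                    "label": prof.label,
                    "within_mean": prof.within_mean,
                    "across_mean": prof.across_mean,
                }
            )
    return AlignmentOutput(profiles=pd.DataFrame(rows), details=details)


def _day_cells(alignment: AlignmentOutput, day: int, label: str | None):
    p = alignment.profiles
    sel = p["day"] == day
    if label is not None:
        sel &= p["label"] == label
    return p.loc[sel, "cell_id"].to_numpy(int)


def analyze_decoding(
    maps: MapsResult, alignment: AlignmentOutput, svm_c: float = 1.0
) -> pd.DataFrame:
    """Per-day heading, context and rate decoders for FI/FS cell groups."""
    rows = []
    for day in np.unique(maps.days):
        sel = np.flatnonzero(maps.days == day)
        digs = maps.digs[sel]
        contexts = maps.contexts[sel]
        for group in ("FI", "FS"):
            cells = _day_cells(alignment, int(day), group)
            if len(cells) == 0:
                continue
            seqs = [alignment.details[(int(day), c)].rotation_bits for c in cells]
            try:
                res = predict_heading(seqs, digs, trial_ids=sel, C=svm_c)
                acc, n = res.accuracy, res.n
            except ValueError as exc:
                acc, n = float("nan"), 0
                log.info("heading decoding skipped day %s %s: %s", day, group, exc)
            rows.append(
                dict(day=int(day), group=group, decoder="heading_rotation",
                     n_trials=n, accuracy=acc)
            )
            stack = np.stack(
                [
                    np.stack(alignment.details[(int(day), c)].aligned_maps)
                    for c in cells
                ]
            )
            res = predict_context_dotproduct(stack, contexts)
            rows.append(
                dict(day=int(day), group=group, decoder="context_dotproduct",
                     n_trials=res.n, accuracy=res.accuracy)
            )
        # rate decoders use all cells active that day
        cells = _day_cells(alignment, int(day), None)
        mfr = maps.mfr[np.ix_(sel, cells)]
        for decoder, label_type in (
            ("context_rate", "context"),
            ("heading_rate", "heading-side"),
        ):
            try:
                res = predict_from_rates(mfr, contexts, digs, label_type, C=svm_c)
                acc, n = res.accuracy, res.n
            except ValueError as exc:
                acc, n = float("nan"), 0
                log.info("rate decoding skipped day %s (%s): %s", day, decoder, exc)
            rows.append(
                dict(day=int(day), group="all", decoder=decoder,
                     n_trials=n, accuracy=acc)
            )
    return pd.DataFrame(rows)


def rate_matrix_summary(maps: MapsResult, alignment: AlignmentOutput) -> pd.DataFrame:
    """Within/across-context mean absolute rate differences per cell-day."""
    rows = []
    for day in np.unique(maps.days):
        sel = np.flatnonzero(maps.days == day)
        for ci in _day_cells(alignment, int(day), None):
            rm = rate_difference_matrix(maps.mfr[sel, ci], maps.contexts[sel])
            rows.append(
                dict(day=int(day), cell_id=int(ci),
                     within_mean=rm.within_mean, across_mean=rm.across_mean)
            )
    return pd.DataFrame(rows)


def analyze_population(maps: MapsResult, alignment: AlignmentOutput):
    """Population cosines, best-match rotations and center-out circular stats."""
    cosine_rows, center_rows, bm_rows = [], [], []
    circ = {}
    for day in np.unique(maps.days):
        day = int(day)
        sel = np.flatnonzero(maps.days == day)
        ctx = maps.contexts[sel]
        # center-out angles per (cell, trial) from feature-anchored raw maps
        for group in ("FI", "FS"):
            cells = _day_cells(alignment, day, group)
            if len(cells) == 0:
                continue
            stack_a = np.stack([alignment.details[(day, c)].avg_map_a for c in cells])
            stack_b = np.stack([alignment.details[(day, c)].avg_map_b for c in cells])
            sim = pixelwise_population_cosine(stack_a, stack_b)
            cosine_rows += [
                dict(day=day, group=group, pixel=int(p), cosine=float(c))
                for p, c in zip(sim.pixel_index, sim.cosines)
            ]
            diffs = []
            n_dropped = 0
            for c in cells:
                angles = np.full(len(sel), np.nan)
                for k, t in enumerate(sel):
                    try:
                        angles[k] = center_out_angle(maps.rate_map(c, t))
                    except ValueError:
                        pass
                for i in range(len(sel)):
                    for j in range(len(sel)):
                        if ctx[i] == "A" and ctx[j] == "B":
                            d = center_out_difference(angles[i], angles[j])
                            if np.isfinite(d):
                                diffs.append(d)
                            else:
                                n_dropped += 1
            if diffs:
                dist = difference_distribution(diffs)
                center_rows += [
                    dict(day=day, group=group, bin_center=float(b), probability=float(p))
                    for b, p in zip(dist.bin_centers, dist.probabilities)
                ]
                ray = rayleigh_test(double_angles(np.asarray(diffs) % 360.0))
                circ[f"day{day}_{group}"] = dict(
                    n=ray.n,
                    n_dropped=n_dropped,
                    resultant_length=ray.resultant_length,
                    statistic=ray.statistic,
                    pvalue=ray.pvalue,
                )
            # best-match rotation distribution (geometry alignment)
            trial_maps_by_cell = [
                [maps.values[c, t] for t in sel] for c in cells
            ]
            props = {0: [], 90: [], 180: [], 270: []}
            for tm in trial_maps_by_cell:
                try:
                    rd = rotation_distribution(tm)
                except ValueError:
                    continue
                for ang in props:
                    if np.isfinite(rd["proportions"][ang]):
                        props[ang].append(rd["proportions"][ang])
            for ang, vals in props.items():
                if vals:
                    bm_rows.append(
                        dict(day=day, group=group, angle=ang,
                             proportion=float(np.mean(vals)), n_cells=len(vals))
                    )
    return pd.DataFrame(cosine_rows), pd.DataFrame(center_rows), circ, pd.DataFrame(bm_rows)


def analyze_behavior(
    config: SessionConfig, seed: int, n_animals: int = 14
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dig summaries and Bayes factors for a cohort of simulated animals.

    Neural data are simulated for one animal; behavior is cheap, so a
    cohort of dig records is drawn from the same study conditions to
    exercise the group-level Bayes-factor analysis.
    """
    from .synth import generate_dig_outcomes

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBEE]))
    records = []
    for animal in range(n_animals):
        for day in range(config.n_days):
            orient = rng.integers(0, 2, size=config.trials_per_day)
            digs = generate_dig_outcomes(
                config.day_dig_probs(day), orient, config.coupling_rho, rng
            )
            for k, dig in enumerate(digs):
                records.append(
                    dict(animal=animal, day=day, dig=dig,
                         context="A" if k % 2 == 0 else "B")
                )
    records = pd.DataFrame(records)
    summary_rows = [bhv.dig_location_percentages(records).assign(kind="percent")]
    behavior_summary = pd.concat(summary_rows, ignore_index=True)

    bf_rows = []
    for model in (bhv.BayesFactorModel.c_model(), bhv.BayesFactorModel.cg_model()):
        zs = bhv.dig_summary(records, model)
        for day, grp in zs.groupby("day"):
            bfs = [
                bhv.bernoulli_bayes_factor(int(r.z), int(r.N), model)
                for r in grp.itertuples(index=False)
            ]
            res = bhv.group_bayes_factor(bfs)
            for animal, lb in zip(grp["animal"], res.log_bfs):
                bf_rows.append(
                    dict(model=model.variant, day=int(day), animal=int(animal),
                         log_bf=float(lb), group_log_bf=res.group_log_bf,
                         decision=res.decision)
                )
    return behavior_summary, pd.DataFrame(bf_rows)


# ---------------------------------------------------------------------------
# stage plumbing


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _stage_fresh(out: Path, name: str, key: str, outputs: list[Path]) -> bool:
    marker = out / f".stage_{name}.json"
    if marker.exists() and all(p.exists() for p in outputs):
        try:
            return json.loads(marker.read_text())["key"] == key
        except Exception:
            return False
    return False


def _mark_stage(out: Path, name: str, key: str):
    (out / f".stage_{name}.json").write_text(json.dumps({"key": key}))


def _write_maps_h5(maps: MapsResult, fname: Path):
    import h5py

    with h5py.File(fname, "w") as f:
        f.create_dataset("values", data=maps.values)
        f.create_dataset("mfr", data=maps.mfr)
        f.create_dataset("movement_time_s", data=maps.movement_time_s)
        f.attrs["bin_cm"] = maps.bin_cm


def _read_maps_h5(fname: Path, session: Session) -> MapsResult:
    import h5py

    meta = session.trials_frame()
    with h5py.File(fname, "r") as f:
        return MapsResult(
            values=f["values"][()],
            mfr=f["mfr"][()],
            movement_time_s=f["movement_time_s"][()],
            bin_cm=float(f.attrs["bin_cm"]),
            days=meta["day"].to_numpy(),
            contexts=meta["context"].to_numpy(),
            digs=meta["dig"].to_numpy(),
        )


STAGE_ORDER = ("simulate", "maps", "alignment", "population", "decoding", "behavior")


def run_pipeline(config: RunConfig, from_stage: str = "simulate") -> dict:
    """Run the pipeline (optionally from a later stage, using caches).

    ``from_stage`` reruns from that stage onward; upstream outputs must
    already exist in the output directory, otherwise a
    :class:`FileNotFoundError` names the stage to rerun.
    """
    if from_stage not in STAGE_ORDER:
        raise ValueError(f"unknown stage {from_stage!r}")
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": json.loads(config.model_dump_json()), "stages": {}}
    resume = STAGE_ORDER.index(from_stage)

    # --- simulate / load ---------------------------------------------------
    sess_cfg = config.session_config()
    sess_dir = Path(config.session_dir) if config.session_dir else out / "session"
    key = _hash(["session", json.loads(config.model_dump_json())["session"], config.seed])
    cached = _stage_fresh(out, "simulate", key, [sess_dir / "trials.csv"])
    if resume == 0 and config.session_dir is None and not cached:
        log.info("stage simulate: generating session (seed=%d)", config.seed)
        session = generate_session(sess_cfg)
        write_session(session, sess_dir, h5=False)
        _mark_stage(out, "simulate", key)
    else:
        if not (sess_dir / "trials.csv").exists():
            raise FileNotFoundError(
                f"upstream cache for stage 'simulate' missing at {sess_dir}; "
                "rerun from the simulate stage first"
            )
        log.info("stage simulate: loading session from %s", sess_dir)
        session = read_session(sess_dir)
    report["stages"]["simulate"] = {
        "n_trials": len(session.trials),
        "n_cells": session.config.n_cells,
    }

    # --- maps --------------------------------------------------------------
    params = config.ratemap_params()
    if resume > STAGE_ORDER.index("maps"):
        if not (out / "maps.h5").exists():
            raise FileNotFoundError(
                "upstream cache for stage 'maps' missing "
                f"({out / 'maps.h5'}); rerun from the maps stage first"
            )
        log.info("stage maps: loading cached maps.h5")
        maps = _read_maps_h5(out / "maps.h5", session)
    else:
        log.info("stage maps: computing rate maps")
        maps = compute_session_maps(session, params)
        if config.write_h5:
            _write_maps_h5(maps, out / "maps.h5")
    report["stages"]["maps"] = {
        "n_maps": int(maps.values.shape[0] * maps.values.shape[1]),
        "n_pixels": int(maps.values.shape[2] * maps.values.shape[3]),
    }

    # --- alignment ---------------------------------------------------------
    log.info("stage alignment: rotation sequences and FS/FI labels")
    alignment = analyze_alignment(maps, cutoff=config.fs_fi_cutoff)
    alignment.profiles.to_csv(out / "cell_profiles.csv", index=False)
    labeled = alignment.profiles[alignment.profiles["label"].isin(["FS", "FI"])]
    fs_prop = (
        float((labeled["label"] == "FS").mean()) if len(labeled) else float("nan")
    )
    gt_labels = session.ground_truth.labels
    match = [
        gt_labels[int(r.cell_id)] == r.label for r in labeled.itertuples(index=False)
    ]
    report["stages"]["alignment"] = {
        "n_profiles": int(len(alignment.profiles)),
        "n_undefined": int((alignment.profiles["label"] == "undefined").sum()),
        "fs_proportion": fs_prop,
        "label_accuracy_vs_ground_truth": float(np.mean(match)) if match else None,
    }

    # --- population & circular --------------------------------------------
    log.info("stage population: cosines, best-match and center-out stats")
    cosines, center_out, circ, best_match = analyze_population(maps, alignment)
    cosines.to_csv(out / "population_cosines.csv", index=False)
    center_out.to_csv(out / "center_out.csv", index=False)
    best_match.to_csv(out / "best_match_rotations.csv", index=False)
    (out / "circular_tests.json").write_text(json.dumps(circ, indent=2))
    report["stages"]["population"] = {
        "n_cosine_rows": int(len(cosines)),
        "n_center_out_rows": int(len(center_out)),
        "circular_tests": circ,
    }

    # --- decoding ----------------------------------------------------------
    log.info("stage decoding: LOO classifiers")
    decoding = analyze_decoding(maps, alignment, svm_c=config.svm_c)
    decoding.to_csv(out / "decoding_results.csv", index=False)
    rates = rate_matrix_summary(maps, alignment)
    rates.to_csv(out / "rate_matrices.csv", index=False)
    report["stages"]["decoding"] = {
        "n_rows": int(len(decoding)),
        "accuracies": {
            f"{r.decoder}_day{r.day}_{r.group}": (
                None if not np.isfinite(r.accuracy) else round(float(r.accuracy), 4)
            )
            for r in decoding.itertuples(index=False)
        },
    }

    # --- behavior ----------------------------------------------------------
    log.info("stage behavior: dig summaries and Bayes factors")
    behavior_summary, bayes = analyze_behavior(
        sess_cfg, config.seed, config.n_behavior_animals
    )
    behavior_summary.to_csv(out / "behavior_summary.csv", index=False)
    bayes.to_csv(out / "bayes_factors.csv", index=False)
    group_bfs = {
        f"{m}_day{d}": float(g["group_log_bf"].iloc[0])
        for (m, d), g in bayes.groupby(["model", "day"])
    }
    report["stages"]["behavior"] = {
        "n_summary_rows": int(len(behavior_summary)),
        "group_log_bf": group_bfs,
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
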