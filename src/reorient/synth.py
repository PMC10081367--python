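"""Synthetic multi-day two-context reorientation sessions with ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage is testable without recordings:

* a rectangular arena explored by a smooth random walk (mean-reverting
  Ornstein-Uhlenbeck velocity with wall reflection);
* a population of place cells with Gaussian field templates -- a
  feature-insensitive (FI) majority sharing one template across the two
  contexts and a feature-sensitive (FS) minority with independently
  placed templates per context;
* a per-trial latent map orientation bit (fair coin, mimicking
  disorientation in a two-fold-symmetric chamber) that rotates every
  cell's field 180 degrees about the arena center on that trial;
* multinomial first-dig outcomes over the four corner cups, with the dig
  side on geometric-axis (C/G) trials coupled to the latent orientation
  by a single parameter rho (P(match) = rho; rho = 0.5 is no coupling);
* across-context rate remapping as per-cell multiplicative gains whose
  log-difference grows over days.

Events are drawn from an inhomogeneous Poisson process along the
trajectory (thinning); calcium-like data use positive event weights
(inferred spiking likelihood), electrophysiology-like data unit weights,
so one code path serves both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaSpec

__all__ = [
    "TrajectoryParams",
    "SessionConfig",
    "CellTemplate",
    "GroundTruth",
    "Trial",
    "Session",
    "generate_trajectory",
    "generate_cell_population",
    "generate_trial_events",
    "generate_dig_outcomes",
    "generate_session",
    "write_session",
    "read_session",
]

_TEMPLATE_MARGIN_CM = 2.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TrajectoryParams:
    """Mean-reverting (Ornstein-Uhlenbeck) velocity random walk.

    ``speed_sd_cm_s`` is the stationary per-component velocity SD; the
    resulting speed distribution straddles the 2 cm/s movement filter
    (mean speed ~ 1.25 * sd, a realistic foraging gait).
    """

    dt_s: float = 1.0 / 30.0
    tau_s: float = 1.0
    speed_sd_cm_s: float = 8.0


@dataclass(frozen=True)
class SessionConfig:
    """Study conditions for one synthetic multi-day session (one animal)."""

    n_days: int = 3
    trials_per_day: int = 12
    n_cells: int = 200
    fs_fraction: float = 0.15
    coupling_rho: float = 0.8
    rate_remap_gain_by_day: tuple = (0.1, 0.25, 0.4)
    dig_probs_by_day: tuple = (
        (0.40, 0.38, 0.12, 0.10),
        (0.62, 0.16, 0.12, 0.10),
        (0.68, 0.12, 0.10, 0.10),
    )
    field_width_cm: float = 4.0
    peak_rate_hz: float = 12.0
    baseline_rate_hz: float = 0.1
    trial_duration_s: float = 180.0
    event_weight_mode: str = "unit"  # "unit" (spikes) | "gamma" (calcium ILSE)
    fs_min_separation_cm: float = 8.0
    base_rate_log_sd: float = 0.3
    p_active_per_day: float = 1.0
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 1 or self.n_cells < 1:
            raise ValueError("n_days and n_cells must be >= 1")
        if self.trials_per_day < 2 or self.trials_per_day % 2:
            raise ValueError(
                "trials_per_day must be even (equal trials per context)"
            )
        for name in ("fs_fraction", "coupling_rho", "p_active_per_day"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(g < 0 for g in self.rate_remap_gain_by_day):
            raise ValueError("rate remap gains must be non-negative")
        for probs in self.dig_probs_by_day:
            _check_probs(probs)
        if self.field_width_cm <= 0 or self.peak_rate_hz <= 0:
            raise ValueError("field_width_cm and peak_rate_hz must be positive")
        if self.event_weight_mode not in ("unit", "gamma"):
            raise ValueError("event_weight_mode must be 'unit' or 'gamma'")

    def day_gain(self, day: int) -> float:
        g = self.rate_remap_gain_by_day
        return float(g[min(day, len(g) - 1)])

    def day_dig_probs(self, day: int) -> tuple:
        p = self.dig_probs_by_day
        return p[min(day, len(p) - 1)]


def _check_probs(probs):
    probs = np.asarray(probs, float)
    if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("corner probabilities must be 4 non-negatives summing to 1")


@dataclass(frozen=True)
class CellTemplate:
    """Gaussian place-field template (rates in Hz, positions in cm)."""

    center: tuple
    sigma_cm: float
    peak_hz: float
    baseline_hz: float = 0.0

    def rate_at(self, x, y, arena: ArenaSpec, orientation_bit: int = 0):
        """Firing rate at (x, y); orientation 1 rotates the field 180
        degrees about the arena center."""
        cx, cy = self.center
        if orientation_bit:
            cx, cy = arena.rotate180((cx, cy))
        d2 = (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2
        return self.baseline_hz + self.peak_hz * np.exp(
            -d2 / (2.0 * self.sigma_cm**2)
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses try to recover."""

    labels: list  # "FS" | "FI" per cell
    centers_a: np.ndarray  # (n_cells, 2) template centers, context A
    centers_b: np.ndarray
    base_rate: np.ndarray  # per-cell peak-rate multiplier
    gain_sign: np.ndarray  # per-cell direction of context-B rate gain
    orientations: np.ndarray = field(default_factory=lambda: np.array([], int))
    digs: list = field(default_factory=list)
    active_by_day: np.ndarray | None = None  # (n_days, n_cells) bool

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "centers_a": self.centers_a.tolist(),
            "centers_b": self.centers_b.tolist(),
            "base_rate": self.base_rate.tolist(),
            "gain_sign": self.gain_sign.tolist(),
            "orientations": np.asarray(self.orientations).tolist(),
            "digs": list(self.digs),
            "active_by_day": (
                self.active_by_day.tolist() if self.active_by_day is not None else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            labels=d["labels"],
            centers_a=np.asarray(d["centers_a"], float),
            centers_b=np.asarray(d["centers_b"], float),
            base_rate=np.asarray(d["base_rate"], float),
            gain_sign=np.asarray(d["gain_sign"], float),
            orientations=np.asarray(d["orientations"], int),
            digs=d["digs"],
            active_by_day=(
                np.asarray(d["active_by_day"], bool)
                if d.get("active_by_day") is not None
                else None
            ),
        )


@dataclass
class Trial:
    trial_id: int
    day: int
    context: str
    dig: str
    chamber_rotation: int
    trajectory: pd.DataFrame
    events: pd.DataFrame  # columns cell_id, t, weight


@dataclass
class Session:
    config: SessionConfig
    arena: ArenaSpec
    trials: list
    ground_truth: GroundTruth

    def trials_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in self.trials],
                "day": [t.day for t in self.trials],
                "context": [t.context for t in self.trials],
                "dig": [t.dig for t in self.trials],
                "chamber_rotation": [t.chamber_rotation for t in self.trials],
            }
        )


def generate_trajectory(
    arena: ArenaSpec,
    duration_s: float,
    params: TrajectoryParams = TrajectoryParams(),
    seed=None,
) -> pd.DataFrame:
    """Smooth random-walk trajectory at a constant sampling rate.

    Velocity follows a discretized Ornstein-Uhlenbeck process; the path
    reflects off the walls (position folded back, velocity component
    negated), so every sample lies inside the arena.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _rng(seed)
    n = int(round(duration_s / params.dt_s))
    alpha = np.exp(-params.dt_s / params.tau_s)
    noise_sd = params.speed_sd_cm_s * np.sqrt(1.0 - alpha**2)
    w, h = arena.width_cm, arena.height_cm

    pos = np.empty((n, 2))
    pos[0] = rng.uniform([0, 0], [w, h])
    vel = rng.normal(0.0, params.speed_sd_cm_s, size=2)
    noise = rng.normal(0.0, 1.0, size=(n - 1, 2)) * noise_sd
    for k in range(1, n):
        vel = alpha * vel + noise[k - 1]
        p = pos[k - 1] + vel * params.dt_s
        for dim, lim in ((0, w), (1, h)):
            if p[dim] < 0:
                p[dim] = -p[dim]
                vel[dim] = -vel[dim]
            elif p[dim] > lim:
                p[dim] = 2 * lim - p[dim]
                vel[dim] = -vel[dim]
            p[dim] = min(max(p[dim], 0.0), lim)
        pos[k] = p
    return pd.DataFrame(
        {"t": np.arange(n) * params.dt_s, "x": pos[:, 0], "y": pos[:, 1]}
    )


def generate_cell_population(config: SessionConfig, seed=None) -> GroundTruth:
    """Draw templates and rate parameters for the cell population.

    ``round(fs_fraction * n_cells)`` cells are feature-sensitive; FI
    templates are identical across contexts, FS context-B templates are
    redrawn until at least ``fs_min_separation_cm`` from both the
    context-A center and its 180-degree image (so FS remapping is not
    confused with a geometric rotation).  Peak locations are uniform over
    the arena interior (2 cm wall margin).
    """
    if config.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _rng(seed if seed is not None else config.seed)
    arena = config.arena
    n = config.n_cells
    n_fs = int(np.rint(config.fs_fraction * n))
    labels = np.array(["FI"] * n, dtype=object)
    fs_idx = rng.choice(n, size=n_fs, replace=False)
    labels[fs_idx] = "FS"

    lo = np.array([_TEMPLATE_MARGIN_CM, _TEMPLATE_MARGIN_CM])
    hi = np.array(
        [arena.width_cm - _TEMPLATE_MARGIN_CM, arena.height_cm - _TEMPLATE_MARGIN_CM]
    )
    centers_a = rng.uniform(lo, hi, size=(n, 2))
    centers_b = centers_a.copy()
    sep = config.fs_min_separation_cm
    for i in np.sort(fs_idx):
        best, best_d = None, -1.0
        for _ in range(200):
            cand = rng.uniform(lo, hi)
            a = centers_a[i]
            a_rot = np.array(arena.rotate180(tuple(a)))
            d = min(np.linalg.norm(cand - a), np.linalg.norm(cand - a_rot))
            if d >= sep:
                best = cand
                break
            if d > best_d:
                best, best_d = cand, d
        centers_b[i] = best

    base_rate = np.exp(rng.normal(0.0, config.base_rate_log_sd, size=n))
    gain_sign = rng.choice([-1.0, 1.0], size=n)
    return GroundTruth(
        labels=list(labels),
        centers_a=centers_a,
        centers_b=centers_b,
        base_rate=base_rate,
        gain_sign=gain_sign,
    )


def generate_trial_events(
    template: CellTemplate,
    trajectory: pd.DataFrame,
    orientation_bit: int,
    gain: float,
    arena: ArenaSpec,
    seed=None,
    weight_mode: str = "unit",
) -> pd.DataFrame:
    """Inhomogeneous-Poisson event train along a trajectory (thinning).

    The instantaneous rate is ``gain * template.rate_at(x(t), y(t))``
    with the template rotated 180 degrees when ``orientation_bit`` is 1.
    ``weight_mode="gamma"`` draws calcium-like positive event weights
    (Gamma(2, 1/2), mean 1); "unit" gives spike-like unit weights.
    """
    if gain < 0:
        raise ValueError("gain must be non-negative")
    if trajectory is None or len(trajectory) == 0:
        raise ValueError("trajectory must be non-empty")
    rng = _rng(seed)
    empty = pd.DataFrame({"t": np.array([]), "weight": np.array([])})
    t = trajectory["t"].to_numpy(float)
    lam_max = gain * (template.baseline_hz + template.peak_hz)
    span = t[-1] - t[0]
    if lam_max <= 0 or span <= 0:
        return empty
    n_cand = rng.poisson(lam_max * span)
    if n_cand == 0:
        return empty
    cand_t = np.sort(rng.uniform(t[0], t[-1], size=n_cand))
    idx = np.clip(np.searchsorted(t, cand_t, side="right") - 1, 0, len(t) - 1)
    x = trajectory["x"].to_numpy(float)[idx]
    y = trajectory["y"].to_numpy(float)[idx]
    lam = gain * template.rate_at(x, y, arena, orientation_bit)
    accept = rng.uniform(0.0, 1.0, size=n_cand) < lam / lam_max
    ev_t = cand_t[accept]
    if weight_mode == "gamma":
        weights = rng.gamma(2.0, 0.5, size=ev_t.size)
    elif weight_mode == "unit":
        weights = np.ones(ev_t.size)
    else:
        raise ValueError("weight_mode must be 'unit' or 'gamma'")
    return pd.DataFrame({"t": ev_t, "weight": weights})


def generate_dig_outcomes(
    corner_probs, orientations, rho: float, seed=None
) -> list:
    """Per-trial first-dig labels in {C, G, N, F}.

    A base corner is drawn from ``corner_probs`` (order C, G, N, F).  On
    geometric-axis draws (C or G), with probability ``rho`` the trial's
    latent orientation dictates the dig side (orientation 0 -> C side,
    1 -> G side); otherwise the base draw stands.  ``rho`` therefore
    interpolates from no coupling (rho = 0: digs independent of the
    latent map orientation) to deterministic coupling (rho = 1); under
    fair orientations the match probability among C/G digs is
    ``(1 + rho) / 2``.
    """
    _check_probs(corner_probs)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = _rng(seed)
    labels = ("C", "G", "N", "F")
    orientations = np.asarray(orientations, int)
    digs = []
    for o in orientations:
        base = labels[rng.choice(4, p=np.asarray(corner_probs, float))]
        if base in ("C", "G") and rng.uniform() < rho:
            base = "C" if o == 0 else "G"
        digs.append(base)
    return digs


def _cell_gain(config: SessionConfig, gt: GroundTruth, cell: int, day: int, context: str):
    g = gt.base_rate[cell]
    if context == "B":
        g = g * np.exp(gt.gain_sign[cell] * config.day_gain(day))
    return float(g)


def generate_session(config: SessionConfig) -> Session:
    """Full multi-day dataset: trajectories, events, digs, ground truth.

    Trials alternate contexts A, B, A, B within each day.  All
    randomness derives from ``config.seed`` via spawned generator
    streams, so a fixed seed yields an identical dataset.
    """
    arena = config.arena
    root = np.random.SeedSequence(config.seed)
    ss_pop, ss_latent, ss_traj, ss_events = root.spawn(4)
    gt = generate_cell_population(config, np.random.default_rng(ss_pop))

    rng_latent = np.random.default_rng(ss_latent)
    n_trials = config.n_days * config.trials_per_day
    orientations = rng_latent.integers(0, 2, size=n_trials)
    chamber_rotations = rng_latent.integers(0, 2, size=n_trials) * 180
    digs = []
    for d in range(config.n_days):
        sl = slice(d * config.trials_per_day, (d + 1) * config.trials_per_day)
        digs.extend(
            generate_dig_outcomes(
                config.day_dig_probs(d),
                orientations[sl],
                config.coupling_rho,
                rng_latent,
            )
        )
    if config.p_active_per_day < 1.0:
        active = rng_latent.uniform(size=(config.n_days, config.n_cells)) < (
            config.p_active_per_day
        )
    else:
        active = np.ones((config.n_days, config.n_cells), dtype=bool)
    gt.orientations = np.asarray(orientations, int)
    gt.digs = digs
    gt.active_by_day = active

    traj_seeds = ss_traj.spawn(n_trials)
    event_seeds = ss_events.spawn(n_trials)
    sigma = config.field_width_cm
    trials = []
    for ti in range(n_trials):
        day = ti // config.trials_per_day
        context = "A" if ti % 2 == 0 else "B"
        traj = generate_trajectory(
            arena,
            config.trial_duration_s,
            config.trajectory,
            np.random.default_rng(traj_seeds[ti]),
        )
        ev_rng = np.random.default_rng(event_seeds[ti])
        centers = gt.centers_a if context == "A" else gt.centers_b
        parts = []
        for ci in range(config.n_cells):
            if not active[day, ci]:
                continue
            template = CellTemplate(
                center=tuple(centers[ci]),
                sigma_cm=sigma,
                peak_hz=config.peak_rate_hz,
                baseline_hz=config.baseline_rate_hz,
            )
            ev = generate_trial_events(
                template,
                traj,
                int(orientations[ti]),
                _cell_gain(config, gt, ci, day, context),
                arena,
                ev_rng,
                weight_mode=config.event_weight_mode,
            )
            if len(ev):
                ev.insert(0, "cell_id", ci)
                parts.append(ev)
        events = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame({"cell_id": [], "t": [], "weight": []})
        )
        trials.append(
            Trial(
                trial_id=ti,
                day=day,
                context=context,
                dig=digs[ti],
                chamber_rotation=int(chamber_rotations[ti]),
                trajectory=traj,
                events=events,
            )
        )
    return Session(config=config, arena=arena, trials=trials, ground_truth=gt)


def write_session(session: Session, path, h5: bool = False) -> Path:
    """Serialize a session directory (CSV tables + ground-truth JSON)."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
        traj = pd.concat(
            [t.trajectory.assign(trial_id=t.trial_id) for t in session.trials],
            ignore_index=True,
        )[["trial_id", "t", "x", "y"]]
        traj.to_csv(path / "trajectory.csv", index=False)
        events = pd.concat(
            [t.events.assign(trial_id=t.trial_id) for t in session.trials],
            ignore_index=True,
        )[["trial_id", "cell_id", "t", "weight"]]
        events.to_csv(path / "events.csv", index=False)
        session.trials_frame().to_csv(path / "trials.csv", index=False)
        (path / "ground_truth.json").write_text(
            json.dumps(session.ground_truth.to_dict())
        )
        cfg = asdict(session.config)
        cfg["arena"] = {
            "width_cm": session.arena.width_cm,
            "height_cm": session.arena.height_cm,
            "reward_corners": {
                k: list(v) for k, v in session.arena.reward_corners.items()
            },
        }
        (path / "config.json").write_text(json.dumps(cfg, default=list))
        if h5:
            _write_session_h5(session, path / "session.h5")
    except OSError as exc:
        raise OSError(f"failed writing session to {path}: {exc}") from exc
    return path


def _write_session_h5(session: Session, fname):
    import h5py

    with h5py.File(fname, "w") as f:
        for trial in session.trials:
            g = f.create_group(f"trial_{trial.trial_id:03d}")
            g.create_dataset("trajectory", data=trial.trajectory.to_numpy())
            g.create_dataset("events", data=trial.events.to_numpy())
            g.attrs.update(
                dict(
                    day=trial.day,
                    context=trial.context,
                    dig=trial.dig,
                    chamber_rotation=trial.chamber_rotation,
                )
            )


def read_session(path) -> Session:
    """Load a session directory written by :func:`write_session`."""
    path = Path(path)
    cfg = json.loads((path / "config.json").read_text())
    arena_d = cfg.pop("arena")
    arena = ArenaSpec(
        width_cm=arena_d["width_cm"],
        height_cm=arena_d["height_cm"],
        reward_corners={k: tuple(v) for k, v in arena_d["reward_corners"].items()},
    )
    traj_p = cfg.pop("trajectory")
    config = SessionConfig(
        arena=arena,
        trajectory=TrajectoryParams(**traj_p),
        **{
            k: (tuple(tuple(x) if isinstance(x, list) else x for x in v)
                if isinstance(v, list) else v)
            for k, v in cfg.items()
        },
    )
    gt = GroundTruth.from_dict(json.loads((path / "ground_truth.json").read_text()))
    traj_all = pd.read_csv(path / "trajectory.csv")
    ev_all = pd.read_csv(path / "events.csv")
    meta = pd.read_csv(path / "trials.csv")
    trials = []
    for row in meta.itertuples(index=False):
        trials.append(
            Trial(
                trial_id=int(row.trial_id),
                day=int(row.day),
                context=str(row.context),
                dig=str(row.dig),
                chamber_rotation=int(row.chamber_rotation),
                trajectory=traj_all.loc[
                    traj_all["trial_id"] == row.trial_id, ["t", "x", "y"]
                ].reset_index(drop=True),
                events=ev_all.loc[
                    ev_all["trial_id"] == row.trial_id, ["cell_id", "t", "weight"]
                ].reset_index(drop=True),
            )
        )
    return Session(config=config, arena=arena, trials=trials, ground_truth=gt)
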