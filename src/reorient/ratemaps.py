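"""Occupancy-normalized, smoothed place maps and trial firing-rate summaries.

The map construction follows the standard place-field recipe: the arena is
binned into ``bin_cm`` square pixels; an activity map (summed event weights
per pixel) is divided by a time map (occupancy seconds per pixel) and the
resulting raw rate is smoothed with an isometric Gaussian kernel.  Pixels
whose *smoothed* occupancy falls below ``min_occupancy_s`` are flagged
unsampled (NaN), never zero-filled.  Only epochs of movement faster than
``speed_threshold_cm_s`` enter the maps.

Smoothing over an irregular sampled support uses mask-normalized
convolution: the kernel is renormalized over the sampled pixels under it,
so unvisited regions and arena walls do not bleed zeros into the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .arena import ArenaSpec

__all__ = [
    "RateMapParams",
    "RateMap",
    "filter_by_speed",
    "compute_rate_map",
    "TrialMapBuilder",
    "mean_event_rate",
    "gaussian_kernel",
]


@dataclass(frozen=True)
class RateMapParams:
    bin_cm: float = 1.0
    smooth_sigma_cm: float = 3.0
    min_occupancy_s: float = 0.05
    speed_threshold_cm_s: float = 2.0

    def __post_init__(self):
        if self.bin_cm <= 0 or self.smooth_sigma_cm <= 0:
            raise ValueError("bin_cm and smooth_sigma_cm must be positive")
        if self.min_occupancy_s < 0 or self.speed_threshold_cm_s < 0:
            raise ValueError(
                "min_occupancy_s and speed_threshold_cm_s must be >= 0"
            )


@dataclass
class RateMap:
    """Smoothed firing-rate grid with a sampled-pixel mask.

    ``values`` is ``(n_rows, n_cols)`` with row 0 the bottom of the arena;
    entries are events/s on sampled pixels and NaN elsewhere.  ``mask`` is
    True where the smoothed occupancy reached ``min_occupancy_s``.
    """

    values: np.ndarray
    mask: np.ndarray
    bin_cm: float
    origin: tuple[float, float] = (0.0, 0.0)
    total_occupancy_s: float = 0.0
    occupancy: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_pixels(self) -> int:
        return int(self.values.size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        """Values with unsampled pixels as NaN (the canonical grid form)."""
        out = np.where(self.mask, self.values, np.nan)
        return out


def _speeds(t: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Forward-difference speed per sample; the last sample inherits the
    speed of its preceding interval."""
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("trajectory timestamps must be strictly increasing")
    v = np.hypot(np.diff(x), np.diff(y)) / dt
    return np.append(v, v[-1])


def filter_by_speed(
    trajectory: pd.DataFrame,
    events: pd.DataFrame | None,
    threshold_cm_s: float,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Keep trajectory samples moving faster than ``threshold_cm_s``.

    Events are assigned to the nearest preceding trajectory sample and are
    retained iff that sample is retained.  Events outside the trajectory
    time span are dropped.
    """
    if len(trajectory) < 2:
        raise ValueError("speed is undefined for fewer than 2 samples")
    t = trajectory["t"].to_numpy(float)
    speed = _speeds(t, trajectory["x"].to_numpy(float), trajectory["y"].to_numpy(float))
    keep = speed > threshold_cm_s
    traj_out = trajectory.loc[keep].reset_index(drop=True)
    if events is None:
        return traj_out, None
    ev_t = events["t"].to_numpy(float)
    idx = np.searchsorted(t, ev_t, side="right") - 1
    in_span = (idx >= 0) & (ev_t <= t[-1])
    ok = np.zeros(len(events), dtype=bool)
    ok[in_span] = keep[idx[in_span]]
    return traj_out, events.loc[ok].reset_index(drop=True)


def gaussian_kernel(sigma_bins: float, truncate: float = 4.0) -> np.ndarray:
    """Sampled, unit-sum isometric Gaussian kernel."""
    radius = int(np.ceil(truncate * sigma_bins))
    ax = np.arange(-radius, radius + 1)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma_bins**2))
    return g / g.sum()


def _masked_smooth(values: np.ndarray, support: np.ndarray, kernel: np.ndarray):
    """Mask-normalized convolution: kernel renormalized over ``support``."""
    num = ndimage.convolve(np.where(support, values, 0.0), kernel, mode="constant")
    den = ndimage.convolve(support.astype(float), kernel, mode="constant")
    out = np.full_like(num, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out, ok


class TrialMapBuilder:
    """Builds many cells' rate maps over one trial's trajectory.

    The time map, smoothed occupancy and kernel normalization depend only
    on the trajectory, so they are computed once and shared across cells.
    """

    def __init__(
        self,
        trajectory: pd.DataFrame,
        arena: ArenaSpec,
        params: RateMapParams = RateMapParams(),
    ):
        if trajectory is None or len(trajectory) == 0:
            raise ValueError("empty trajectory")
        self.params = params
        self.t = trajectory["t"].to_numpy(float)
        self.x = trajectory["x"].to_numpy(float)
        self.y = trajectory["y"].to_numpy(float)
        if not arena.contains(self.x, self.y):
            raise ValueError("trajectory leaves the arena bounds")
        n_cols = int(round(arena.width_cm / params.bin_cm))
        n_rows = int(round(arena.height_cm / params.bin_cm))
        self.x_edges = np.arange(n_cols + 1) * params.bin_cm
        self.y_edges = np.arange(n_rows + 1) * params.bin_cm
        self.dt = (
            float(np.median(np.diff(self.t))) if len(self.t) > 1 else 0.0
        )
        self.time_map, _, _ = np.histogram2d(
            self.y,
            self.x,
            bins=(self.y_edges, self.x_edges),
            weights=np.full(len(self.t), self.dt),
        )
        self.visited = self.time_map > 0
        self.kernel = gaussian_kernel(params.smooth_sigma_cm / params.bin_cm)
        self.occ_smooth = ndimage.convolve(
            self.time_map, self.kernel, mode="constant"
        )
        self._support_conv = ndimage.convolve(
            self.visited.astype(float), self.kernel, mode="constant"
        )
        self._defined = self._support_conv > 0
        self.mask = (self.occ_smooth >= params.min_occupancy_s) & self._defined

    def build(self, events: pd.DataFrame | None) -> RateMap:
        activity = np.zeros_like(self.time_map)
        if events is not None and len(events) > 0:
            ev_t = np.asarray(events["t"], float)
            w = (
                np.asarray(events["weight"], float)
                if "weight" in events
                else np.ones(len(ev_t))
            )
            idx = np.searchsorted(self.t, ev_t, side="right") - 1
            in_span = (idx >= 0) & (ev_t <= self.t[-1] + self.dt)
            if not np.all(in_span):
                warnings.warn(
                    f"dropping {int((~in_span).sum())} events outside the "
                    "trajectory time span"
                )
            idx = np.clip(idx[in_span], 0, len(self.t) - 1)
            activity, _, _ = np.histogram2d(
                self.y[idx],
                self.x[idx],
                bins=(self.y_edges, self.x_edges),
                weights=w[in_span],
            )
        raw_rate = np.zeros_like(self.time_map)
        raw_rate[self.visited] = activity[self.visited] / self.time_map[self.visited]
        num = ndimage.convolve(
            np.where(self.visited, raw_rate, 0.0), self.kernel, mode="constant"
        )
        rate_smooth = np.full_like(num, np.nan)
        rate_smooth[self._defined] = num[self._defined] / self._support_conv[self._defined]
        values = np.where(self.mask, rate_smooth, np.nan)
        return RateMap(
            values=values,
            mask=self.mask.copy(),
            bin_cm=self.params.bin_cm,
            origin=(0.0, 0.0),
            total_occupancy_s=float(self.time_map.sum()),
            occupancy=self.occ_smooth,
        )


def compute_rate_map(
    trajectory: pd.DataFrame,
    events: pd.DataFrame | None,
    arena: ArenaSpec,
    params: RateMapParams = RateMapParams(),
) -> RateMap:
    """Build one trial's place map from speed-filtered data.

    The activity map is divided by the time map pixel-by-pixel, the raw
    rate is smoothed by mask-normalized Gaussian convolution over the
    visited pixels, and the occupancy is smoothed by plain (mass-
    conserving) convolution; the sampled mask requires smoothed occupancy
    of at least ``params.min_occupancy_s``.
    """
    return TrialMapBuilder(trajectory, arena, params).build(events)


def mean_event_rate(events: pd.DataFrame | None, movement_time_s: float) -> float:
    """Mean firing rate: summed event weights per second of movement time."""
    if movement_time_s <= 0:
        raise ValueError("movement_time_s must be positive")
    if events is None or len(events) == 0:
        return 0.0
    w = (
        events["weight"].to_numpy(float)
        if "weight" in events
        else np.ones(len(events))
    )
    return float(w.sum() / movement_time_s)
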