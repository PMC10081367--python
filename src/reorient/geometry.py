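"""Rotation machinery for rectangular place maps.

Because the arena is a rectangle, only 0/180 degree rotations are
symmetries of the native grid; the four-rotation best-match analysis first
compresses each map to a square so that 90/270 can be evaluated as well.
Grids are 2-D float arrays with NaN marking unsampled pixels (the
canonical masked form produced by :meth:`RateMap.masked_values`).
Correlations are computed over jointly sampled pixels only -- zero-filling
unsampled pixels would manufacture spurious correlation at 180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ratemaps import RateMap

ROTATION_SET = (0, 90, 180, 270)

__all__ = [
    "ROTATION_SET",
    "BestMatchResult",
    "compress_to_square",
    "rotate_map",
    "map_correlation",
    "best_match_rotation",
    "rotation_distribution",
    "center_out_angle",
]


@dataclass(frozen=True)
class BestMatchResult:
    """Outcome of the four-rotation best-match comparison of one map pair."""

    best_angle: int
    correlations: dict
    pair: tuple | None = None


def rotate_map(grid: np.ndarray, angle: int) -> np.ndarray:
    """Rotate a grid by a multiple of 90 degrees (index permutation).

    The mapping for 90 degrees is ``r' = N-1-c, c' = r``; masks encoded as
    NaN rotate with the values.  90/270 require a square grid.
    """
    if angle not in ROTATION_SET:
        raise ValueError(f"angle must be one of {ROTATION_SET}, got {angle}")
    if angle in (90, 270) and grid.shape[0] != grid.shape[1]:
        raise ValueError("90/270 degree rotations require a square grid")
    return np.rot90(grid, k=angle // 90)


def map_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over jointly sampled (finite-in-both) pixels.

    Returns NaN (flagged, not zero) when fewer than two pixels are jointly
    sampled or either map has zero variance on the joint support.
    """
    if a.shape != b.shape:
        raise ValueError("maps must share geometry")
    joint = np.isfinite(a) & np.isfinite(b)
    if joint.sum() < 2:
        return float("nan")
    av, bv = a[joint], b[joint]
    sa, sb = av.std(), bv.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.corrcoef(av, bv)[0, 1])


def compress_to_square(
    grid: np.ndarray, side_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinearly resample a (possibly masked) grid to a square.

    Values are resampled with mask-weighted bilinear interpolation; the
    fractional mask is resampled the same way and a target pixel counts as
    sampled iff its resampled mask weight exceeds 0.5.  Returns
    ``(values, mask)`` with NaN outside the mask.
    """
    if side_bins < 2:
        raise ValueError("side_bins must be >= 2")
    mask = np.isfinite(grid)
    if not mask.any():
        raise ValueError("cannot compress an all-unsampled map")
    h, w = grid.shape
    rows = (np.arange(side_bins) + 0.5) * h / side_bins - 0.5
    cols = (np.arange(side_bins) + 0.5) * w / side_bins - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])

    wts = mask.astype(float)
    num = ndimage.map_coordinates(
        np.where(mask, grid, 0.0), coords, order=1, mode="nearest"
    )
    den = ndimage.map_coordinates(wts, coords, order=1, mode="nearest")
    out_mask = den > 0.5
    vals = np.full(side_bins * side_bins, np.nan)
    ok = out_mask & (den > 0)
    vals[ok] = num[ok] / den[ok]
    return vals.reshape(side_bins, side_bins), out_mask.reshape(side_bins, side_bins)


def best_match_rotation(
    a: np.ndarray, b: np.ndarray, pair: tuple | None = None
) -> BestMatchResult:
    """Best of the four rotations of ``a`` against non-rotated ``b``.

    Ties break toward the smallest angle (0 < 90 < 180 < 270), which is
    deterministic and conservative for alignment claims.
    """
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("best-match rotation requires same-size square maps")
    corrs = {ang: map_correlation(rotate_map(a, ang), b) for ang in ROTATION_SET}
    best, best_r = None, -np.inf
    for ang in ROTATION_SET:
        r = corrs[ang]
        if np.isfinite(r) and r > best_r:
            best, best_r = ang, r
    if best is None:
        raise ValueError("all rotation correlations undefined for this pair")
    return BestMatchResult(best_angle=best, correlations=corrs, pair=pair)


def rotation_distribution(maps: list[np.ndarray]) -> dict:
    """Proportion of unordered trial pairs best-matched at each rotation.

    Non-square maps are first compressed to a square whose side is the
    smaller map dimension.  Pairs for which every rotation correlation is
    undefined are dropped and counted.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 trial maps")
    squares = []
    for m in maps:
        if m.shape[0] != m.shape[1]:
            side = min(m.shape)
            v, _ = compress_to_square(m, side)
            squares.append(v)
        else:
            squares.append(m)
    counts = {ang: 0 for ang in ROTATION_SET}
    n_pairs = 0
    n_dropped = 0
    results = []
    for i in range(len(squares)):
        for j in range(i + 1, len(squares)):
            n_pairs += 1
            try:
                res = best_match_rotation(squares[i], squares[j], pair=(i, j))
            except ValueError:
                n_dropped += 1
                continue
            counts[res.best_angle] += 1
            results.append(res)
    n_ok = n_pairs - n_dropped
    props = {ang: (counts[ang] / n_ok if n_ok else float("nan")) for ang in ROTATION_SET}
    return {
        "proportions": props,
        "n_pairs": n_pairs,
        "n_dropped": n_dropped,
        "results": results,
    }


def center_out_angle(
    rate_map: RateMap, field_threshold: float | None = None
) -> float:
    """CCW angle (degrees, 0 = +x axis) from the arena center to the
    rate-weighted center of mass of the map.

    ``field_threshold`` optionally restricts the mass to pixels at or
    above that fraction of the peak rate (a crude field extraction); by
    default the full smoothed map is used.  Returns NaN (flagged) when the
    center of mass coincides with the arena center within 1e-9 cm.
    """
    vals = rate_map.masked_values()
    ok = np.isfinite(vals)
    weights = np.where(ok, vals, 0.0)
    if field_threshold is not None:
        peak = np.nanmax(vals)
        weights = np.where(weights >= field_threshold * peak, weights, 0.0)
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("map must have positive total rate")
    n_rows, n_cols = vals.shape
    xs = (np.arange(n_cols) + 0.5) * rate_map.bin_cm + rate_map.origin[0]
    ys = (np.arange(n_rows) + 0.5) * rate_map.bin_cm + rate_map.origin[1]
    com_x = float((weights.sum(axis=0) * xs).sum() / total)
    com_y = float((weights.sum(axis=1) * ys).sum() / total)
    cx = rate_map.origin[0] + n_cols * rate_map.bin_cm / 2.0
    cy = rate_map.origin[1] + n_rows * rate_map.bin_cm / 2.0
    dx, dy = com_x - cx, com_y - cy
    if np.hypot(dx, dy) < 1e-9:
        return float("nan")
    return float(np.degrees(np.arctan2(dy, dx)) % 360.0)
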