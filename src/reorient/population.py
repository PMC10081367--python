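"""Population-level context similarity and circular statistics.

Two families of analyses live here.  The first treats each spatial pixel
as a vector across cells (a population vector) and measures context
similarity as the normalized dot product (cosine) between the context-A
and context-B population vectors at each pixel.  The second summarizes
location remapping directionally: each map is reduced to its center-out
angle (arena center to rate-weighted center of mass), pairwise CCW angle
differences are histogrammed in 6-degree bins, and -- because the
rectangle's symmetry makes these distributions bimodal at 0/180 --
angles are doubled (theta -> 2*theta mod 360) before a Rayleigh test for
departure from circular uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSimilarity",
    "CircularDistribution",
    "RayleighResult",
    "pixelwise_population_cosine",
    "longitudinal_partition",
    "center_out_difference",
    "double_angles",
    "rayleigh_test",
    "difference_distribution",
]


@dataclass
class PopulationSimilarity:
    """Per-pixel cosine similarities between two context populations."""

    cosines: np.ndarray  # one value per defined pixel
    pixel_index: np.ndarray  # flat indices of the defined pixels
    n_excluded: int  # pixels with a zero/undefined vector on either side
    n_total: int


@dataclass
class CircularDistribution:
    """Probability distribution of angles over fixed-width circular bins.

    Bins are centered on multiples of ``bin_width`` (the first bin covers
    ``[-width/2, width/2)`` wrapped), so modes at the geometrically
    meaningful angles 0 and 180 are not split across bin edges.
    """

    probabilities: np.ndarray
    bin_centers: np.ndarray
    bin_width: float
    n: int


@dataclass
class RayleighResult:
    resultant_length: float
    statistic: float  # Z = n * Rbar^2
    pvalue: float
    n: int


def pixelwise_population_cosine(
    maps_a: np.ndarray, maps_b: np.ndarray
) -> PopulationSimilarity:
    """Cosine between across-cell rate vectors at each pixel.

    ``maps_a``/``maps_b`` are ``(n_cells, n_rows, n_cols)`` stacks of
    average aligned maps (NaN = unsampled).  At each pixel the vectors are
    built from cells sampled in both contexts; pixels where either vector
    is empty or has zero norm are excluded and counted.
    """
    maps_a = np.asarray(maps_a, float)
    maps_b = np.asarray(maps_b, float)
    if maps_a.shape != maps_b.shape:
        raise ValueError("both contexts need the same cell set and geometry")
    n_cells = maps_a.shape[0]
    A = maps_a.reshape(n_cells, -1)
    B = maps_b.reshape(n_cells, -1)
    n_pix = A.shape[1]
    cosines, idx = [], []
    n_excluded = 0
    for p in range(n_pix):
        ok = np.isfinite(A[:, p]) & np.isfinite(B[:, p])
        u, v = A[ok, p], B[ok, p]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if ok.sum() == 0 or nu == 0 or nv == 0:
            n_excluded += 1
            continue
        cosines.append(float(u @ v / (nu * nv)))
        idx.append(p)
    return PopulationSimilarity(
        cosines=np.array(cosines),
        pixel_index=np.array(idx, dtype=int),
        n_excluded=n_excluded,
        n_total=n_pix,
    )


def longitudinal_partition(registration: pd.DataFrame, roster_day1, roster_day3):
    """Partition cells into consistent / day1-only / day3-only classes.

    ``registration`` maps day-1 cell ids to day-3 cell ids (columns
    ``id_day1``, ``id_day3``); it must be injective in both directions.
    Cells active on both days (through the registration) are
    "consistent"; the rest are temporarily active on one day.
    """
    for col in ("id_day1", "id_day3"):
        if col not in registration:
            raise ValueError("registration needs id_day1 and id_day3 columns")
        if registration[col].duplicated().any():
            raise ValueError(f"duplicate registration targets in {col}")
    roster_day1, roster_day3 = set(roster_day1), set(roster_day3)
    fwd = dict(zip(registration["id_day1"], registration["id_day3"]))
    consistent_d1 = {
        c for c in roster_day1 if c in fwd and fwd[c] in roster_day3
    }
    consistent_d3 = {fwd[c] for c in consistent_d1}
    return {
        "consistent_day1_ids": consistent_d1,
        "consistent_day3_ids": consistent_d3,
        "day1_only": roster_day1 - consistent_d1,
        "day3_only": roster_day3 - consistent_d3,
        "counts": {
            "consistent": len(consistent_d1),
            "day1_only": len(roster_day1) - len(consistent_d1),
            "day3_only": len(roster_day3) - len(consistent_d3),
        },
    }


def center_out_difference(theta_first: float, theta_second: float) -> float:
    """CCW rotation (degrees) aligning the second map with the first.

    For across-context pairs the convention is that the second map is the
    context-B map.  NaN inputs propagate (the caller drops and counts
    such pairs).
    """
    if not (np.isfinite(theta_first) and np.isfinite(theta_second)):
        return float("nan")
    return float((theta_first - theta_second) % 360.0)


def double_angles(angles) -> np.ndarray:
    """Angle doubling: theta -> (2*theta) mod 360.

    Collapses 180-degree bimodality into a unimodal distribution suitable
    for the Rayleigh test.
    """
    angles = np.asarray(angles, float)
    if np.any((angles < 0) | (angles >= 360)):
        raise ValueError("angles must lie in [0, 360)")
    return (2.0 * angles) % 360.0


def rayleigh_test(angles) -> RayleighResult:
    """Rayleigh test of circular uniformity on angles in degrees.

    Uses the standard statistic Z = n * Rbar^2 with the small-sample
    corrected p-value approximation
    ``p = exp(-Z) * (1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2))``.
    """
    angles = np.asarray(angles, float)
    n = angles.size
    if n < 2:
        raise ValueError("Rayleigh test needs n >= 2")
    rad = np.deg2rad(angles)
    rbar = float(np.abs(np.exp(1j * rad).mean()))
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return RayleighResult(resultant_length=rbar, statistic=float(z), pvalue=p, n=n)


def difference_distribution(differences, bin_width: float = 6.0) -> CircularDistribution:
    """Histogram circular differences into bins centered on k*bin_width."""
    if bin_width <= 0 or 360.0 % bin_width != 0:
        raise ValueError("bin width must evenly divide 360 degrees")
    d = np.asarray(differences, float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no finite differences to bin")
    if np.any((d < 0) | (d >= 360)):
        raise ValueError("differences must lie in [0, 360)")
    n_bins = int(round(360.0 / bin_width))
    idx = np.floor(((d + bin_width / 2.0) % 360.0) / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return CircularDistribution(
        probabilities=counts / counts.sum(),
        bin_centers=np.arange(n_bins) * bin_width,
        bin_width=float(bin_width),
        n=int(d.size),
    )
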