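"""Within/across-context map alignment and feature-sensitivity labeling.

Disoriented animals carry their internal map in one of the two
orientations allowed by the rectangle, so a cell's trial maps within a
context are first brought into register by choosing, for each trial, a
0 or 180 degree rotation (a binary rotation sequence, 1 = rotated).  The
assignment maximizes the *global* sum of pairwise correlations among the
aligned maps -- pairwise comparisons cannot all be maximized
independently -- found by exact enumeration of the 2^(T-1) assignments
(first trial fixed unrotated) for sessions of up to 12 trials, with a
greedy bit-flip ascent beyond that.

The two contexts' average aligned maps are then registered to each other
(rotating context B's average 180 degrees if that correlates better, in
which case every bit of B's sequence flips), and the correlation between
the average aligned maps defines the cell's context similarity: below the
0.3 cutoff the cell is feature-sensitive (FS, remaps across contexts),
otherwise feature-insensitive (FI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .geometry import map_correlation, rotate_map

FS_FI_CUTOFF = 0.3
EXACT_ENUMERATION_LIMIT = 12

__all__ = [
    "FS_FI_CUTOFF",
    "CellContextProfile",
    "pairwise_rotation_correlations",
    "alignment_objective",
    "align_within_context",
    "average_aligned_map",
    "align_context_pair",
    "context_similarity_score",
    "classify_feature_sensitivity",
    "within_across_pairwise_correlations",
    "align_session",
]


@dataclass
class CellContextProfile:
    """Per-cell alignment summary across the two contexts."""

    context_similarity: float
    label: str  # "FS" | "FI" | "undefined"
    cutoff: float
    within_mean: float
    across_mean: float
    rotation_bits: np.ndarray  # one bit per trial, session order
    pair_table: pd.DataFrame | None = field(default=None, repr=False)
    avg_map_a: np.ndarray | None = field(default=None, repr=False)
    avg_map_b: np.ndarray | None = field(default=None, repr=False)
    aligned_maps: list | None = field(default=None, repr=False)


def pairwise_rotation_correlations(maps: list[np.ndarray]):
    """(c0, c1): correlations of map i with map j unrotated / rotated 180."""
    T = len(maps)
    rot = [rotate_map(m, 180) for m in maps]
    c0 = np.full((T, T), np.nan)
    c1 = np.full((T, T), np.nan)
    for i in range(T):
        for j in range(i + 1, T):
            c0[i, j] = c0[j, i] = map_correlation(maps[i], maps[j])
            c1[i, j] = c1[j, i] = map_correlation(maps[i], rot[j])
    return c0, c1


def alignment_objective(bits: np.ndarray, c0: np.ndarray, c1: np.ndarray) -> float:
    """Sum of pairwise correlations among maps aligned per ``bits``.

    Equal bits leave the pair's relative orientation unchanged (c0);
    unequal bits rotate one of them (c1).  Undefined correlations
    contribute zero.
    """
    T = len(bits)
    total = 0.0
    for i in range(T):
        for j in range(i + 1, T):
            r = c0[i, j] if bits[i] == bits[j] else c1[i, j]
            if np.isfinite(r):
                total += r
    return total


def greedy_align(c0: np.ndarray, c1: np.ndarray):
    """Single-bit-flip ascent on the alignment objective (fallback for
    sessions too long to enumerate; never better than enumeration)."""
    T = c0.shape[0]
    bits = np.zeros(T, dtype=int)
    obj = alignment_objective(bits, c0, c1)
    improved = True
    while improved:
        improved = False
        for k in range(1, T):
            cand = bits.copy()
            cand[k] ^= 1
            cand_obj = alignment_objective(cand, c0, c1)
            if cand_obj > obj:
                bits, obj, improved = cand, cand_obj, True
    return bits, float(obj)


def align_within_context(maps: list[np.ndarray]):
    """Optimal binary rotation sequence for one context's trial maps.

    Returns ``(bits, aligned_maps, objective)``; the first trial is fixed
    unrotated (the objective is invariant under a global flip).
    """
    T = len(maps)
    if T < 1:
        raise ValueError("need at least one trial map")
    if T == 1:
        return np.zeros(1, dtype=int), [maps[0]], 0.0
    c0, c1 = pairwise_rotation_correlations(maps)
    if T <= EXACT_ENUMERATION_LIMIT:
        best_bits, best_obj = None, -np.inf
        for tail in product((0, 1), repeat=T - 1):
            bits = np.array((0,) + tail)
            obj = alignment_objective(bits, c0, c1)
            if obj > best_obj:
                best_bits, best_obj = bits, obj
    else:
        best_bits, best_obj = greedy_align(c0, c1)
    aligned = [rotate_map(m, 180) if b else m for m, b in zip(maps, best_bits)]
    return best_bits, aligned, float(best_obj)


def average_aligned_map(aligned_maps: list[np.ndarray]):
    """Pixelwise mean over trials where sampled; mask is the union.

    Returns ``(mean_map, counts)`` with NaN where no trial sampled the
    pixel and the per-pixel number of contributing trials alongside.
    """
    if len(aligned_maps) < 1:
        raise ValueError("need at least one map")
    shapes = {m.shape for m in aligned_maps}
    if len(shapes) != 1:
        raise ValueError("maps must share geometry")
    stack = np.stack(aligned_maps)
    finite = np.isfinite(stack)
    counts = finite.sum(axis=0)
    total = np.where(finite, stack, 0.0).sum(axis=0)
    mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return mean, counts


def align_context_pair(avg_a: np.ndarray, avg_b: np.ndarray, bits_b: np.ndarray):
    """Register context B's average to context A's.

    B is rotated 180 degrees iff that strictly improves its correlation
    with A; if rotated, every bit of B's rotation sequence flips.
    Returns ``(angle, avg_b_aligned, bits_b_adjusted)``.
    """
    r0 = map_correlation(avg_a, avg_b)
    r180 = map_correlation(avg_a, rotate_map(avg_b, 180))
    if np.isfinite(r180) and (not np.isfinite(r0) or r180 > r0):
        return 180, rotate_map(avg_b, 180), 1 - np.asarray(bits_b)
    return 0, avg_b, np.asarray(bits_b).copy()


def context_similarity_score(avg_a: np.ndarray, avg_b_aligned: np.ndarray) -> float:
    """Pearson r between the two contexts' average aligned maps."""
    return map_correlation(avg_a, avg_b_aligned)


def classify_feature_sensitivity(score: float, cutoff: float = FS_FI_CUTOFF) -> str:
    """FS iff the across-context similarity falls strictly below the cutoff.

    A score exactly at the cutoff is FI (feature sensitivity is defined
    strictly as "< cutoff").  NaN scores are rejected; callers exclude
    such cells and report them separately.
    """
    if not np.isfinite(score) or not -1.0 <= score <= 1.0:
        raise ValueError(f"score must be a finite value in [-1, 1], got {score}")
    return "FS" if score < cutoff else "FI"


def within_across_pairwise_correlations(
    aligned_maps: list[np.ndarray], contexts: list[str]
):
    """All-pair correlations of aligned maps, split within/across context.

    Returns ``(within_mean, across_mean, table)`` where the table has one
    row per unordered trial pair.  Within and across comparisons are
    treated identically; with a single context the across mean is NaN.
    """
    T = len(aligned_maps)
    if T != len(contexts):
        raise ValueError("one context label per trial map required")
    rows = []
    for i in range(T):
        for j in range(i + 1, T):
            rows.append(
                {
                    "i": i,
                    "j": j,
                    "comparison": "within" if contexts[i] == contexts[j] else "across",
                    "r": map_correlation(aligned_maps[i], aligned_maps[j]),
                }
            )
    table = pd.DataFrame(rows)
    def _mean(kind):
        sel = table.loc[table["comparison"] == kind, "r"]
        sel = sel[np.isfinite(sel)]
        return float(sel.mean()) if len(sel) else float("nan")

    return _mean("within"), _mean("across"), table


def align_session(
    maps: list[np.ndarray],
    contexts: list[str],
    cutoff: float = FS_FI_CUTOFF,
    keep_maps: bool = False,
) -> CellContextProfile:
    """Full per-cell alignment pipeline over one session's trials.

    Aligns each context internally, registers context B's average (the
    second distinct context label in trial order) to context A's, merges
    the rotation bits back into session trial order, and scores/labels
    the cell.  Cells whose across-context correlation is undefined (e.g.
    silent in one context) get label ``"undefined"``.
    """
    contexts = list(contexts)
    if len(maps) != len(contexts):
        raise ValueError("one context label per trial map required")
    ctx_order = list(dict.fromkeys(contexts))
    if len(ctx_order) != 2:
        raise ValueError("exactly two contexts required")
    ca, cb = ctx_order
    idx_a = [i for i, c in enumerate(contexts) if c == ca]
    idx_b = [i for i, c in enumerate(contexts) if c == cb]

    bits_a, aligned_a, _ = align_within_context([maps[i] for i in idx_a])
    bits_b, aligned_b, _ = align_within_context([maps[i] for i in idx_b])
    avg_a, _ = average_aligned_map(aligned_a)
    avg_b, _ = average_aligned_map(aligned_b)
    angle, avg_b_aligned, bits_b_adj = align_context_pair(avg_a, avg_b, bits_b)
    if angle == 180:
        aligned_b = [rotate_map(m, 180) for m in aligned_b]

    bits = np.zeros(len(maps), dtype=int)
    bits[idx_a] = bits_a
    bits[idx_b] = bits_b_adj
    aligned_all: list = [None] * len(maps)
    for k, i in enumerate(idx_a):
        aligned_all[i] = aligned_a[k]
    for k, i in enumerate(idx_b):
        aligned_all[i] = aligned_b[k]

    score = context_similarity_score(avg_a, avg_b_aligned)
    label = (
        classify_feature_sensitivity(score, cutoff)
        if np.isfinite(score)
        else "undefined"
    )
    within_mean, across_mean, table = within_across_pairwise_correlations(
        aligned_all, contexts
    )
    return CellContextProfile(
        context_similarity=score,
        label=label,
        cutoff=cutoff,
        within_mean=within_mean,
        across_mean=across_mean,
        rotation_bits=bits,
        pair_table=table,
        avg_map_a=avg_a,
        avg_map_b=avg_b_aligned,
        aligned_maps=aligned_all if keep_maps else None,
    )
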