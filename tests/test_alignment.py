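"""Rotation-sequence alignment, average aligned maps, and FS/FI labels."""

import numpy as np
import pandas as pd
import pytest

from reorient.alignment import (
    align_context_pair,
    align_session,
    align_within_context,
    alignment_objective,
    average_aligned_map,
    classify_feature_sensitivity,
    greedy_align,
    pairwise_rotation_correlations,
    within_across_pairwise_correlations,
)
from reorient.geometry import rotate_map

from conftest import smooth_random_map


def planted_maps(rng, bits, base=None, noise=0.05, shape=(8, 8)):
    base = smooth_random_map(rng, shape) if base is None else base
    out = []
    for b in bits:
        m = base + noise * rng.standard_normal(shape)
        out.append(rotate_map(m, 180) if b else m)
    return out


class TestAlignWithinContext:
    def test_identical_maps_all_zero(self, rng):
        g = smooth_random_map(rng, (6, 6))
        bits, _, _ = align_within_context([g] * 4)
        assert np.array_equal(bits, [0, 0, 0, 0])

    def test_alternating_construct_and_recover(self, rng):
        maps = planted_maps(rng, [0, 1, 0, 1])
        bits, aligned, _ = align_within_context(maps)
        assert np.array_equal(bits, [0, 1, 0, 1])
        # aligned maps should all correlate highly with the first
        from reorient.geometry import map_correlation

        assert all(map_correlation(aligned[0], m) > 0.9 for m in aligned[1:])

    def test_enumeration_matches_exhaustive_oracle(self, rng):
        maps = planted_maps(rng, rng.integers(0, 2, size=6), noise=0.3)
        bits, _, obj = align_within_context(maps)
        c0, c1 = pairwise_rotation_correlations(maps)
        oracle_best = max(
            alignment_objective(np.array([(k >> i) & 1 for i in range(6)]), c0, c1)
            for k in range(64)
        )
        assert obj == pytest.approx(oracle_best, abs=1e-9)

    def test_single_map(self, rng):
        bits, aligned, obj = align_within_context([smooth_random_map(rng, (4, 4))])
        assert list(bits) == [0] and obj == 0.0

    def test_enumeration_beats_greedy(self, rng):
        """Global enumeration never scores below greedy bit-flip ascent."""
        for _ in range(200):
            T = int(rng.integers(3, 8))
            c0 = np.full((T, T), np.nan)
            c1 = np.full((T, T), np.nan)
            for i in range(T):
                for j in range(i + 1, T):
                    c0[i, j] = c0[j, i] = rng.uniform(-1, 1)
                    c1[i, j] = c1[j, i] = rng.uniform(-1, 1)
            _, greedy_obj = greedy_align(c0, c1)
            from itertools import product

            enum_obj = max(
                alignment_objective(np.array((0,) + tail), c0, c1)
                for tail in product((0, 1), repeat=T - 1)
            )
            assert enum_obj >= greedy_obj - 1e-12


class TestAverageAlignedMap:
    def test_single_map_is_itself(self, rng):
        g = smooth_random_map(rng, (4, 4))
        mean, counts = average_aligned_map([g])
        assert np.allclose(mean, g)
        assert counts.min() == 1

    def test_two_identical(self, rng):
        g = smooth_random_map(rng, (4, 4))
        mean, _ = average_aligned_map([g, g])
        assert np.allclose(mean, g)

    def test_pixel_mean(self):
        a = np.array([[0.0, 2.0]])
        b = np.array([[2.0, 0.0]])
        mean, counts = average_aligned_map([a, b])
        assert np.allclose(mean, [[1.0, 1.0]])
        assert np.array_equal(counts, [[2, 2]])

    def test_union_mask_with_counts(self):
        a = np.array([[1.0, np.nan]])
        b = np.array([[3.0, 5.0]])
        mean, counts = average_aligned_map([a, b])
        assert np.allclose(mean, [[2.0, 5.0]])
        assert np.array_equal(counts, [[2, 1]])

    def test_geometry_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            average_aligned_map([np.zeros((2, 2)), np.zeros((2, 3))])


class TestAlignContextPair:
    def test_identical_averages_unchanged(self, rng):
        g = smooth_random_map(rng, (6, 6))
        bits = np.array([0, 1, 0])
        angle, _, out_bits = align_context_pair(g, g, bits)
        assert angle == 0
        assert np.array_equal(out_bits, bits)

    def test_rotated_average_flips_sequence(self, rng):
        g = smooth_random_map(rng, (6, 6))
        bits_b = np.array([0, 1, 0, 0, 0, 1])
        angle, aligned_b, out_bits = align_context_pair(g, rotate_map(g, 180), bits_b)
        assert angle == 180
        assert np.array_equal(out_bits, [1, 0, 1, 1, 1, 0])
        assert np.allclose(aligned_b, g)

    def test_flip_involution(self, rng):
        g = smooth_random_map(rng, (6, 6))
        bits = np.array([0, 1, 1, 0])
        _, b1, bits1 = align_context_pair(g, rotate_map(g, 180), bits)
        _, _, bits2 = align_context_pair(g, rotate_map(b1, 180), bits1)
        assert np.array_equal(bits2, bits)


class TestClassify:
    @pytest.mark.parametrize(
        "score, label",
        [(0.654, "FI"), (0.160, "FS"), (0.3, "FI"), (-0.5, "FS"), (0.31, "FI")],
    )
    def test_labels(self, score, label):
        assert classify_feature_sensitivity(score) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_feature_sensitivity(1.5)
        with pytest.raises(ValueError):
            classify_feature_sensitivity(float("nan"))


class TestWithinAcross:
    def test_identical_maps_give_unity(self, rng):
        g = smooth_random_map(rng, (5, 5))
        w, a, table = within_across_pairwise_correlations(
            [g] * 4, ["A", "B", "A", "B"]
        )
        assert w == pytest.approx(1.0) and a == pytest.approx(1.0)

    def test_twelve_trials_give_66_rows(self, rng):
        maps = [smooth_random_map(rng, (4, 4)) for _ in range(12)]
        _, _, table = within_across_pairwise_correlations(maps, ["A", "B"] * 6)
        assert len(table) == 66

    def test_single_context_across_undefined(self, rng):
        maps = [smooth_random_map(rng, (4, 4)) for _ in range(3)]
        _, across, _ = within_across_pairwise_correlations(maps, ["A"] * 3)
        assert np.isnan(across)

    def test_planted_fs_cell_across_below_within(self, rng):
        a = smooth_random_map(rng, (8, 8))
        b = smooth_random_map(rng, (8, 8))
        maps = [a, b, a, b]  # different map per context
        w, ac, _ = within_across_pairwise_correlations(maps, ["A", "B", "A", "B"])
        assert ac < w


class TestAlignSession:
    def test_fi_like_cell_recovers_orientations_and_label(self, rng):
        base = smooth_random_map(rng, (8, 8))
        bits_true = np.array([0, 1, 1, 0, 0, 1])
        maps = planted_maps(rng, bits_true, base=base)
        prof = align_session(maps, ["A", "B"] * 3)
        assert prof.label == "FI"
        # recovered bits equal the planted ones up to a global flip
        assert (
            np.array_equal(prof.rotation_bits, bits_true)
            or np.array_equal(prof.rotation_bits, 1 - bits_true)
        )

    def test_label_invariant_to_context_swap(self, rng):
        maps = planted_maps(rng, [0, 1, 0, 1], noise=0.1)
        p1 = align_session(maps, ["A", "B", "A", "B"])
        p2 = align_session(maps, ["B", "A", "B", "A"])
        assert p1.label == p2.label
        assert p1.context_similarity == pytest.approx(
            p2.context_similarity, abs=1e-9
        )
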