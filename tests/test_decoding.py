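"""Leave-one-out decoding of heading and context, and rate matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reorient.decoding import (
    TrialFeatureMatrix,
    build_rotation_features,
    loo_linear_classifier,
    predict_context_dotproduct,
    predict_from_rates,
    predict_heading,
    rate_difference_matrix,
)


class TestBuildFeatures:
    def test_single_cell_shape(self):
        f = build_rotation_features([[0, 1, 0, 1]], ["C", "G", "C", "G"])
        assert f.X.shape == (4, 1)

    def test_constant_columns_retained(self):
        f = build_rotation_features(
            [[0, 0, 0, 0], [0, 1, 0, 1]], ["C", "G", "C", "G"]
        )
        assert f.X.shape == (4, 2)
        assert np.all(f.X[:, 0] == 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_rotation_features([[0, 1], [0, 1, 0]], ["C", "G"])


class TestLOOClassifier:
    def test_perfectly_separable(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0], [0.05], [0.95]])
        y = np.array(["C", "C", "G", "G", "C", "G"])
        res = loo_linear_classifier(TrialFeatureMatrix(X, y, np.arange(6)))
        assert res.accuracy == 1.0

    def test_matches_threshold_search_oracle(self):
        """1-D toy problem: per-fold predictions equal an exhaustive
        search over separating thresholds (max-margin midpoint)."""
        x = np.array([0.0, 0.2, 0.8, 1.0, 0.1, 0.9, 0.3, 0.7])
        y = np.array(["C", "C", "G", "G", "C", "G", "C", "G"])
        res = loo_linear_classifier(
            TrialFeatureMatrix(x[:, None], y, np.arange(len(x)))
        )
        for i in range(len(x)):
            keep = np.arange(len(x)) != i
            xc = x[keep][y[keep] == "C"]
            xg = x[keep][y[keep] == "G"]
            # separable training folds: max-margin threshold midpoint
            thr = (xc.max() + xg.min()) / 2.0
            oracle = "C" if x[i] < thr else "G"
            assert res.predictions[i] == oracle
        assert res.accuracy == 1.0

    def test_chance_on_label_independent_features(self, rng):
        """Random features, balanced classes: no optimistic bias.

        Leave-one-out with balanced classes is *pessimistically* biased
        under the null (removing the held-out trial makes its class the
        training minority, and the empirical prior then leans the other
        way), so the mean accuracy over 200 null sessions must sit at or
        below chance -- never above it.
        """
        accs = []
        for _ in range(200):
            X = rng.standard_normal((8, 3))
            y = np.array(["C"] * 4 + ["G"] * 4)
            rng.shuffle(y)
            accs.append(
                loo_linear_classifier(
                    TrialFeatureMatrix(X, y, np.arange(8))
                ).accuracy
            )
        assert np.mean(accs) <= 0.5 + 0.05
        assert np.mean(accs) > 0.2  # still in the chance regime

    def test_determinism(self, rng):
        X = rng.standard_normal((10, 4))
        y = np.array(["C", "G"] * 5)
        f = TrialFeatureMatrix(X, y, np.arange(10))
        r1 = loo_linear_classifier(f)
        r2 = loo_linear_classifier(f)
        assert np.array_equal(r1.predictions, r2.predictions)

    def test_insufficient_class_counts_rejected(self):
        with pytest.raises(ValueError):
            loo_linear_classifier(
                TrialFeatureMatrix(
                    np.zeros((3, 1)), np.array(["C", "C", "G"]), np.arange(3)
                )
            )


class TestPredictHeading:
    def test_planted_bits_equal_labels(self):
        digs = np.array(["C", "G", "C", "G", "N", "C", "G"])
        bits = (digs == "G").astype(int)
        res = predict_heading([bits, bits], digs)
        assert res.accuracy == 1.0
        assert res.n == 6  # the N trial is excluded

    def test_no_cg_trials_rejected(self):
        with pytest.raises(ValueError):
            predict_heading([[0, 1]], np.array(["N", "F"]))


class TestPredictContextDotProduct:
    def _toy_maps(self, rng, fs=True, n_trials=8):
        """Two cells; FS cells place activity at context-specific pixels."""
        contexts = np.array(["A", "B"] * (n_trials // 2))
        maps = np.zeros((2, n_trials, 2, 2))
        for t, ctx in enumerate(contexts):
            for c in range(2):
                if fs:
                    pix = (0, c) if ctx == "A" else (1, c)
                    maps[c, t][pix] = 1.0 + 0.1 * rng.random()
                else:
                    maps[c, t][(0, c)] = 1.0  # identical in both contexts
        return maps, contexts

    def test_fs_population_decodes_context(self, rng):
        maps, contexts = self._toy_maps(rng, fs=True)
        res = predict_context_dotproduct(maps, contexts)
        assert res.accuracy == 1.0

    def test_fi_population_at_chance(self, rng):
        maps, contexts = self._toy_maps(rng, fs=False)
        res = predict_context_dotproduct(maps, contexts)
        # identical maps in both contexts: every score ties, the
        # deterministic tie-break predicts A, and accuracy is chance
        assert res.accuracy == pytest.approx(0.5)
        assert len(res.flagged_trials) == len(contexts)

    def test_singleton_context_trial_skipped(self, rng):
        maps = rng.random((2, 3, 2, 2))
        res = predict_context_dotproduct(maps, np.array(["A", "A", "B"]))
        assert res.skipped_trials == [2]


class TestRateMatrix:
    def test_constant_rates_zero_matrix(self):
        rm = rate_difference_matrix([2.0, 2.0, 2.0])
        assert np.allclose(rm.matrix, 0.0)

    def test_hand_computation(self):
        rm = rate_difference_matrix([1.0, 3.0, 6.0])
        triu = rm.matrix[np.triu_indices(3, k=1)]
        assert sorted(triu) == [2.0, 3.0, 5.0]

    def test_within_across_means(self):
        rm = rate_difference_matrix([1.0, 2.0, 5.0, 6.0], ["A", "B", "A", "B"])
        # within pairs: (1,5)->4, (2,6)->4; across: (1,2),(1,6),(2,5),(5,6)
        assert rm.within_mean == pytest.approx(4.0)
        assert rm.across_mean == pytest.approx((1 + 5 + 3 + 1) / 4)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            rate_difference_matrix([1.0])

    @given(
        st.lists(st.floats(min_value=0, max_value=50), min_size=3, max_size=12)
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_triangle_inequality(self, rates):
        m = rate_difference_matrix(rates).matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)
        n = len(rates)
        for a in range(n):
            for b in range(n):
                for c in range(n):
                    assert m[a, c] <= m[a, b] + m[b, c] + 1e-9


class TestPredictFromRates:
    def test_single_cell_ordered_rates(self):
        mfr = np.array([[0.1], [0.2], [5.0], [6.0], [0.15], [5.5]])
        contexts = np.array(["A", "A", "B", "B", "A", "B"])
        digs = np.array(["C"] * 6)
        res = predict_from_rates(mfr, contexts, digs, "context")
        assert res.accuracy == 1.0

    def test_heading_side_uses_cg_only(self):
        mfr = np.array([[0.0], [1.0], [0.1], [0.9], [0.5], [0.05], [0.95]])
        digs = np.array(["C", "G", "C", "G", "N", "C", "G"])
        contexts = np.array(["A"] * 7)
        res = predict_from_rates(mfr, contexts, digs, "heading-side")
        assert res.n == 6

    def test_unknown_label_type_rejected(self):
        with pytest.raises(ValueError):
            predict_from_rates(np.zeros((4, 1)), ["A"] * 4, ["C"] * 4, "bogus")
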