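"""Layer specificity scores, ANOVA + Tukey post hoc, and lamina assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from laminamap import (
    LAYERS,
    assign_layer,
    layer_anova,
    layer_specificity_score,
    normalize_gene_intensities,
    score_subtype,
)


class TestNormalize:
    def test_min_max_by_hand(self):
        out = normalize_gene_intensities(np.array([[10.0, 35.0, 5.0, 20.0]]))
        np.testing.assert_allclose(out[0], [1 / 6, 1.0, 0.0, 0.5], atol=1e-12)

    def test_constant_row_becomes_zeros(self):
        out = normalize_gene_intensities(np.array([[4.0, 4.0, 4.0, 4.0]]))
        np.testing.assert_array_equal(out, 0.0)

    def test_unique_extremes_give_one_zero_one_one(self, rng):
        X = rng.random((20, 4)) * 50
        out = normalize_gene_intensities(X)
        for row in out:
            assert (row == 0).sum() == 1 and (row == 1).sum() == 1

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            normalize_gene_intensities(np.array([[-1.0, 0.0, 1.0, 2.0]]))


class TestScores:
    def test_log_of_mean_plus_epsilon(self):
        norm = np.array([[0.9, 0.2, 0.1, 0.05], [0.9, 0.2, 0.1, 0.05]])
        scores = layer_specificity_score(norm, epsilon=1e-3)
        np.testing.assert_allclose(
            scores, np.log([0.901, 0.201, 0.101, 0.051]), atol=1e-12
        )

    def test_equal_means_equal_scores(self):
        scores = layer_specificity_score(np.full((3, 4), 0.25))
        assert np.ptp(scores) == 0.0

    def test_permutation_equivariance(self, rng):
        X = rng.random((6, 4))
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(
            layer_specificity_score(X[:, perm]), layer_specificity_score(X)[perm]
        )

    def test_ordering_matches_means(self, rng):
        X = rng.random((10, 4))
        scores = layer_specificity_score(X)
        assert list(np.argsort(scores)) == list(np.argsort(X.mean(axis=0)))


class TestAnova:
    def test_identical_rows_give_f_zero_p_one(self):
        F, p, posthoc = layer_anova(np.tile([0.3, 0.3, 0.3, 0.3], (5, 1)))
        assert F == 0.0 and p == 1.0
        np.testing.assert_array_equal(posthoc, 1.0)

    def test_closed_form_two_gene_example(self):
        # columns {1,2},{5,6},{1,2},{1,2}: SSB=24 (df 3), SSW=2 (df 4) -> F=16
        X = np.array([[1.0, 5.0, 1.0, 1.0], [2.0, 6.0, 2.0, 2.0]])
        F, p, _ = layer_anova(X)
        assert F == pytest.approx(16.0, abs=1e-10)
        assert p == pytest.approx(stats.f.sf(16.0, 3, 4), abs=1e-12)

    def test_matches_scipy_f_oneway(self, rng):
        X = rng.random((12, 4))
        F, p, _ = layer_anova(X)
        ref = stats.f_oneway(*(X[:, j] for j in range(4)))
        assert F == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_tukey_matches_studentized_range(self, rng):
        # independent route: q = |diff| / sqrt(MSE/n), p = sf of the studentized range
        X = rng.random((10, 4)) + np.array([0.0, 0.3, 0.0, 0.1])
        _, _, posthoc = layer_anova(X)
        n, k = X.shape
        mse = ((X - X.mean(axis=0)) ** 2).sum() / (k * n - k)
        for i in range(k):
            for j in range(i + 1, k):
                q = abs(X[:, i].mean() - X[:, j].mean()) / np.sqrt(mse / n)
                ref = stats.studentized_range.sf(q, k, k * n - k)
                assert posthoc[i, j] == pytest.approx(ref, abs=1e-8)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            layer_anova(np.array([[0.1, 0.2, 0.3, 0.4]]))


class TestAssignment:
    def test_nonsignificant_anova_unassigned(self):
        posthoc = np.full((4, 4), 1e-6)
        np.fill_diagonal(posthoc, 1.0)
        assert assign_layer([3, 1, 0, 0], 0.5, posthoc) == "unassigned"

    def test_clear_winner_assigned(self):
        posthoc = np.full((4, 4), 1e-5)
        np.fill_diagonal(posthoc, 1.0)
        assert assign_layer([0.1, 2.0, 0.3, 0.1], 1e-5, posthoc) == "Op"

    def test_close_runner_up_unassigned(self):
        posthoc = np.full((4, 4), 1e-5)
        np.fill_diagonal(posthoc, 1.0)
        posthoc[1, 2] = posthoc[2, 1] = 0.2  # winner vs runner-up not separated
        assert assign_layer([0.1, 2.0, 1.9, 0.1], 1e-5, posthoc) == "unassigned"

    def test_never_assigns_a_non_maximal_layer(self, rng):
        for _ in range(200):
            scores = rng.normal(size=4)
            posthoc = rng.random((4, 4))
            posthoc = (posthoc + posthoc.T) / 2
            np.fill_diagonal(posthoc, 1.0)
            label = assign_layer(scores, rng.random(), posthoc)
            if label != "unassigned":
                assert label == LAYERS[int(np.argmax(scores))]


class TestScoreSubtype:
    def test_dominant_layer_assigned(self, rng):
        intensity = pd.DataFrame(
            rng.random((10, 4)) * 2, columns=list(LAYERS),
            index=[f"g{i}" for i in range(10)],
        )
        intensity["Op"] += 30
        res = score_subtype("ST", intensity)
        assert res.assigned_layer == "Op"
        assert res.anova_p < 1e-6
        assert res.normalized.shape == (10, 4)

    def test_gene_order_and_duplication_invariance(self, rng):
        intensity = pd.DataFrame(
            rng.random((8, 4)) * 10 + np.array([20, 0, 0, 0]),
            columns=list(LAYERS), index=[f"g{i}" for i in range(8)],
        )
        res1 = score_subtype("ST", intensity)
        shuffled = intensity.iloc[::-1]
        res2 = score_subtype("ST", shuffled)
        np.testing.assert_allclose(res1.layer_scores, res2.layer_scores)
        doubled = pd.concat([intensity, intensity.set_axis([f"h{i}" for i in range(8)])])
        res3 = score_subtype("ST", doubled)
        np.testing.assert_allclose(res1.layer_scores, res3.layer_scores)
        assert res1.assigned_layer == res3.assigned_layer
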