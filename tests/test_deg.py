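"""One-vs-rest Wilcoxon and ROC differential expression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from laminamap import roc_deg, wilcoxon_deg
from laminamap.expression import (
    _exact_ranksum_p,
    _midranks,
    _ranksum_z_p,
    _tie_terms,
    make_expression_matrix,
)


def _adata_from_values(values, labels):
    """AnnData whose lognorm layer is set directly to ``values`` (cells x genes)."""
    values = np.asarray(values, dtype=float)
    adata = make_expression_matrix(
        np.ones(values.shape, dtype=int).T,
        [f"g{i}" for i in range(values.shape[1])],
        [f"c{i}" for i in range(values.shape[0])],
        clusters=labels,
    )
    adata.layers["lognorm"] = values
    return adata


class TestWilcoxon:
    def test_exact_p_three_vs_three(self):
        # in {4,5,6} vs out {1,2,3}: 2 of the C(6,3)=20 rank splits are as extreme
        values = np.array([[1, 2, 3, 4, 5, 6]], dtype=float).T
        adata = _adata_from_values(values, ["out"] * 3 + ["in"] * 3)
        table = wilcoxon_deg(adata)
        p_in = table.set_index("subtype").loc["in", "p_raw"]
        assert p_in == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        values = np.array([[1, 2, 3, 1, 2, 3]], dtype=float).T
        adata = _adata_from_values(values, ["a"] * 3 + ["b"] * 3)
        table = wilcoxon_deg(adata)
        assert (table["p_raw"] == 1.0).all()

    @pytest.mark.parametrize("n,n1", [(n, n1) for n in range(4, 9) for n1 in range(2, n - 1)])
    def test_exact_path_matches_scipy_enumeration(self, n, n1, rng):
        for _ in range(5):
            x, y = rng.normal(size=n1), rng.normal(size=n - n1)
            ours = _exact_ranksum_p(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_asymptotic_path_matches_scipy_with_ties(self, rng):
        for _ in range(25):
            x = rng.integers(0, 5, 18).astype(float)
            y = rng.integers(0, 5, 22).astype(float)
            pooled = np.concatenate([x, y])[None, :]
            ranks = _midranks(pooled)
            tie = _tie_terms(ranks, pooled)
            ours = _ranksum_z_p(np.array([ranks[0, :18].sum()]), tie, 18, 22)[0]
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_bh_adjustment_step_up_example(self, rng):
        # raw (0.01, 0.02, 0.03, 0.04) over 4 tests all adjust to 0.04
        values = rng.normal(size=(12, 4))
        adata = _adata_from_values(values, ["a"] * 6 + ["b"] * 6)
        table = wilcoxon_deg(adata)
        sub = table[table.subtype == "a"]
        raw = np.array([0.01, 0.02, 0.03, 0.04])
        adj = _bh_reference(raw)
        np.testing.assert_allclose(adj, [0.04] * 4)
        # and our table's adjustment matches the step-up oracle on its own p
        np.testing.assert_allclose(
            np.sort(sub["p_adj"]), np.sort(_bh_reference(sub["p_raw"].to_numpy())), atol=1e-12
        )

    def test_bh_monotone_and_dominates_raw(self, bundle):
        from laminamap.expression import log_normalize

        adata = bundle.adata[:, :300].copy()
        log_normalize(adata)
        table = wilcoxon_deg(adata)
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()
        for _, sub in table.groupby("subtype"):
            order_raw = sub.sort_values(["p_raw", "gene"])["p_adj"].to_numpy()
            assert np.all(np.diff(order_raw) >= -1e-12)

    def test_small_subtype_skipped_with_warning(self):
        values = np.arange(10, dtype=float)[:, None]
        labels = ["a"] * 8 + ["b", "c"]
        adata = _adata_from_values(values, labels)
        with pytest.warns(UserWarning, match="fewer than 2"):
            table = wilcoxon_deg(adata)
        assert set(table["subtype"]) == {"a"}


class TestROC:
    def test_interleaved_groups_power_half(self):
        # in {1,3} vs out {2,4}: 1 of 4 pairs wins -> AUC 0.25, power 0.5
        values = np.array([[1, 3, 2, 4]], dtype=float).T
        adata = _adata_from_values(values, ["in", "in", "out", "out"])
        row = roc_deg(adata).set_index("subtype").loc["in"]
        assert row["auc"] == pytest.approx(0.25)
        assert row["power"] == pytest.approx(0.5)

    def test_perfect_separation(self):
        values = np.array([[5, 6, 7, 1, 2, 3]], dtype=float).T
        adata = _adata_from_values(values, ["in"] * 3 + ["out"] * 3)
        row = roc_deg(adata).set_index("subtype").loc["in"]
        assert row["auc"] == 1.0 and row["power"] == 1.0
        assert bool(row["is_deg"])

    def test_identical_groups_power_zero(self):
        values = np.array([[1, 2, 1, 2]], dtype=float).T
        adata = _adata_from_values(values, ["a", "a", "b", "b"])
        table = roc_deg(adata)
        assert (table["power"] == 0.0).all()
        assert not table["is_deg"].any()

    def test_auc_ties_count_half(self):
        values = np.array([[2, 2, 2, 2]], dtype=float).T
        adata = _adata_from_values(values, ["a", "a", "b", "b"])
        assert (roc_deg(adata)["auc"] == 0.5).all()


def _bh_reference(p):
    """Benjamini-Hochberg step-up computed literally from its definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj
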