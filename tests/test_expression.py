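"""Low-expression filter, fold changes, DE classification, rescue, BH."""

import numpy as np
import pandas as pd
import pytest

from regulonkit.expression import (
    ExpressionMatrix,
    bh_adjust,
    classify_de,
    consistency_rescue,
    de_table,
    fold_change,
    internal_de_test,
    low_expression_filter,
)


def matrix(wt_rows, mut_rows, genes=None):
    genes = genes or [f"g{i}" for i in range(len(wt_rows))]
    cols = [f"rep{i + 1}" for i in range(len(wt_rows[0]))]
    return ExpressionMatrix(
        wt=pd.DataFrame(wt_rows, index=genes, columns=cols),
        mut=pd.DataFrame(mut_rows, index=genes, columns=cols),
    )


class TestLowExpressionFilter:
    def test_low_in_both_strains_filtered(self):
        m = matrix([[0.5, 0.8, 1.2]], [[0.2, 0.3, 0.4]])
        assert low_expression_filter(m).iloc[0]

    def test_low_in_one_strain_kept(self):
        m = matrix([[5, 6, 7]], [[0.1, 0.2, 0.3]])
        assert not low_expression_filter(m).iloc[0]

    def test_all_expressed_kept(self):
        m = matrix([[1, 2, 3]], [[4, 5, 6]])
        assert not low_expression_filter(m).iloc[0]


class TestFoldChange:
    def test_arithmetic(self):
        m = matrix([[1, 1, 1]], [[7, 7, 7]])
        assert fold_change(m).iloc[0] == pytest.approx(2.0)

    def test_equal_means_zero(self):
        m = matrix([[2, 4, 6]], [[6, 4, 2]])
        assert fold_change(m).iloc[0] == pytest.approx(0.0)

    def test_small_pseudocount_limit(self):
        m = matrix([[2, 2, 2]], [[8, 8, 8]])
        assert fold_change(m, pseudocount=1e-9).iloc[0] == pytest.approx(2.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(15)
        wt = rng.uniform(0, 50, size=(30, 3))
        mut = rng.uniform(0, 50, size=(30, 3))
        fwd = fold_change(matrix(wt, mut))
        rev = fold_change(matrix(mut, wt))
        assert np.allclose(fwd.values, -rev.values)


class TestClassifyDE:
    @pytest.mark.parametrize(
        "lfc,padj,expected",
        [
            (2.0, 0.01, "up"),
            (1.0, 0.05, "up"),  # thresholds inclusive
            (-0.5, 0.001, "unchanged"),
            (-1.0, 0.05, "down"),
            (3.0, 0.06, "unchanged"),
        ],
    )
    def test_threshold_logic(self, lfc, padj, expected):
        records = pd.DataFrame({"log2fc": [lfc], "padj": [padj]})
        assert classify_de(records).iloc[0] == expected

    def test_bad_padj_rejected(self):
        with pytest.raises(ValueError):
            classify_de(pd.DataFrame({"log2fc": [0.0], "padj": [1.5]}))


class TestConsistencyRescue:
    def make(self, ratios, padj):
        # wt all 10; mut chosen to produce the requested per-pair log2 ratios
        wt = [[10.0, 10.0, 10.0]]
        mut = [[(10.0 + 1.0) * 2**r - 1.0 for r in ratios]]
        m = matrix(wt, mut)
        records = pd.DataFrame(
            {"log2fc": [np.mean(ratios)], "padj": [padj], "status": ["unchanged"]},
            index=m.genes,
        )
        return m, records

    def test_consistent_trend_rescued(self):
        m, rec = self.make([1.2, 1.4, 1.1], padj=0.08)
        assert consistency_rescue(m, rec).iloc[0] == "rescued_up"

    def test_sign_flip_not_rescued(self):
        m, rec = self.make([2.0, 2.2, -0.3], padj=0.08)
        assert consistency_rescue(m, rec).iloc[0] == "unchanged"

    def test_significant_gene_untouched(self):
        m, rec = self.make([1.2, 1.4, 1.1], padj=0.01)
        rec["status"] = ["up"]
        assert consistency_rescue(m, rec).iloc[0] == "up"

    def test_downward_trend(self):
        m, rec = self.make([-1.3, -1.1, -1.6], padj=0.2)
        assert consistency_rescue(m, rec).iloc[0] == "rescued_down"


def bh_oracle(p):
    """Textbook step-up definition, computed directly."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_textbook_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(16)
        for _ in range(200):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_monotone_in_input_order(self):
        rng = np.random.default_rng(17)
        p = np.sort(rng.uniform(0, 1, size=50))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, -0.1])


class TestInternalDE:
    def test_identical_values_null(self):
        m = matrix([[5, 6, 7]], [[5, 6, 7]])
        res = internal_de_test(m)
        assert res["log2fc"].iloc[0] == pytest.approx(0.0)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_constant_difference(self):
        m = matrix([[2, 2, 2]], [[8, 8, 8]])
        res = internal_de_test(m)
        assert res["pvalue"].iloc[0] == 0.0

    def test_power_on_planted_fourfold_effects(self):
        """4-fold planted effects at CV 0.2, r=3 are almost always called up."""
        rng = np.random.default_rng(18)
        n = 500
        base = np.exp(rng.normal(3, 1, size=(n, 1))).clip(min=2.0)
        sigma = np.sqrt(np.log1p(0.2**2))

        def reps(mean):
            return mean * np.exp(rng.normal(0, sigma, size=(n, 3)) - sigma**2 / 2)

        m = matrix(reps(base), reps(4 * base))
        res = internal_de_test(m)
        status = classify_de(res)
        assert (status == "up").mean() >= 0.95

    def test_null_size_does_not_exceed_nominal(self):
        """Welch at r=3 is conservative; size must stay at or below alpha."""
        rng = np.random.default_rng(19)
        n = 20_000
        base = np.exp(rng.normal(3, 1, size=(n, 1)))
        sigma = np.sqrt(np.log1p(0.2**2))

        def reps():
            return base * np.exp(rng.normal(0, sigma, size=(n, 3)) - sigma**2 / 2)

        res = internal_de_test(matrix(reps(), reps()))
        rate = (res["pvalue"] <= 0.05).mean()
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


def test_de_table_statuses_partition_genes():
    rng = np.random.default_rng(20)
    n = 300
    wt = rng.uniform(0, 20, size=(n, 3))
    mut = rng.uniform(0, 20, size=(n, 3))
    m = matrix(wt, mut)
    records = de_table(m)
    assert len(records) == n
    assert records["status"].isin(
        ["up", "down", "unchanged", "filtered", "rescued_up", "rescued_down"]
    ).all()
    # filtered genes carry no direction label by construction
    assert (records["status"].value_counts().sum()) == n
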