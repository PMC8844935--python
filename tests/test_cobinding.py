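"""Two-factor summit distances, threshold calibration, cobound labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regulonkit.cobinding import (
    calibrate_threshold,
    classify_cobound,
    cobound_counts,
    cumulative_distance_curve,
    occupancy_change_correlation,
    summit_distance_distribution,
)
from regulonkit.peaks import PromoterAssignment, ReconciledPeak, Summit
from regulonkit.simulate import SimulationConfig, simulate_cobinding


def assignments(gene_positions, sample="f"):
    out = []
    for gene, positions in gene_positions.items():
        for p in positions:
            s = Summit("chr1", p, 1.0, sample)
            out.append(
                PromoterAssignment(gene, ReconciledPeak("chr1", p, (s,), frozenset({sample})), 0)
            )
    return out


class TestDistanceDistribution:
    def test_single_pair(self):
        d = summit_distance_distribution(
            assignments({"g": [5000]}), assignments({"g": [5030]})
        )
        assert d["distance"].tolist() == [30]

    def test_minimum_over_pairs(self):
        d = summit_distance_distribution(
            assignments({"g": [5000, 5400]}), assignments({"g": [5390]})
        )
        assert d["distance"].tolist() == [10]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a = {f"g{i}": list(rng.integers(0, 10_000, rng.integers(1, 5))) for i in range(10)}
            b = {f"g{i}": list(rng.integers(0, 10_000, rng.integers(1, 5))) for i in range(10)}
            got = summit_distance_distribution(assignments(a), assignments(b))
            for _, row in got.iterrows():
                gene = row["gene_id"]
                oracle = min(abs(x - y) for x in a[gene] for y in b[gene])
                assert row["distance"] == oracle

    def test_only_shared_promoters_reported(self):
        d = summit_distance_distribution(
            assignments({"g1": [100]}), assignments({"g2": [200]})
        )
        assert len(d) == 0


class TestCalibration:
    def test_tight_reference(self):
        cal = calibrate_threshold([5, 8, 10, 3])
        assert cal.threshold == 10
        assert cal.coverage == 1.0

    def test_stated_quantile_case(self):
        cal = calibrate_threshold([10, 20, 30, 40, 200], coverage_target=0.8)
        assert cal.threshold == 40
        assert cal.coverage == pytest.approx(0.8)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([])

    def test_smallest_multiple_property(self):
        rng = np.random.default_rng(24)
        for _ in range(20):
            d = rng.exponential(40, size=50)
            cal = calibrate_threshold(d, coverage_target=0.8, granularity=10)
            assert cal.threshold % 10 == 0
            assert (d <= cal.threshold).mean() >= 0.8
            if cal.threshold > 10:
                assert (d <= cal.threshold - 10).mean() < 0.8


class TestClassify:
    @pytest.mark.parametrize("distance,label", [(30, "cobound"), (50, "cobound"), (51, "distinct")])
    def test_threshold_inclusive_at_50(self, distance, label):
        df = pd.DataFrame({"gene_id": ["g"], "distance": [distance]})
        assert classify_cobound(df)["label"].iloc[0] == label

    def test_extreme_thresholds(self):
        df = pd.DataFrame({"gene_id": list("abc"), "distance": [0, 10, 500]})
        assert (classify_cobound(df, threshold=10**9)["label"] == "cobound").all()
        zero = classify_cobound(df, threshold=0)
        assert zero["label"].tolist() == ["cobound", "distinct", "distinct"]

    def test_counts_sum_to_shared_promoters(self):
        rng = np.random.default_rng(25)
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(100)], "distance": rng.integers(0, 300, 100)}
        )
        counts = cobound_counts(classify_cobound(df))
        assert counts["cobound"] + counts["distinct"] == 100


class TestCorrelation:
    def test_proportional_is_one(self):
        a = [1.0, 2.0, 5.0, 3.0]
        assert occupancy_change_correlation(a, [2 * x for x in a]).r == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        a = [1.0, 2.0, 5.0]
        assert occupancy_change_correlation(a, [-x for x in a]).r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        res = occupancy_change_correlation([1, 2, 3], [1, 3, 2])
        assert res.r == pytest.approx(0.5)

    def test_zero_variance_flagged(self):
        res = occupancy_change_correlation([1, 1, 1], [1, 2, 3])
        assert res.degenerate and np.isnan(res.r)


class TestECDF:
    def test_three_values(self):
        curve = cumulative_distance_curve([10, 20, 30])
        assert curve["distance"].tolist() == [10, 20, 30]
        assert curve["cumulative_fraction"].tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_single_value(self):
        curve = cumulative_distance_curve([42])
        assert curve["cumulative_fraction"].tolist() == [1.0]

    def test_nondecreasing_and_ends_at_one(self):
        rng = np.random.default_rng(26)
        curve = cumulative_distance_curve(rng.integers(0, 500, 200))
        frac = curve["cumulative_fraction"].values
        assert (np.diff(frac) > 0).all()
        assert frac[-1] == 1.0


class TestSimulatedRecovery:
    def test_heterodimer_ecdf_matches_analytic(self):
        """ECDF at 50 bp agrees with P(|N(0, sd*sqrt(2))| <= 50) to 3 SE."""
        cfg = SimulationConfig(seed=27, heterodimer_sd=15.0, heterodimer_n=500)
        sim = simulate_cobinding(cfg)
        at50 = (sim.reference_distances <= 50).mean()
        p = 2 * stats.norm.cdf(50.5 / (15 * np.sqrt(2))) - 1  # +0.5 for rounding
        se = np.sqrt(p * (1 - p) / 500)
        assert abs(at50 - p) <= 3 * se

    def test_planted_cobound_fraction_recovered(self):
        cfg = SimulationConfig(seed=28, cobound_fraction=0.5, cobind_n_promoters=400)
        sim = simulate_cobinding(cfg)
        dist = summit_distance_distribution(sim.factor_a, sim.factor_b)
        labeled = classify_cobound(dist, threshold=50)
        observed = (labeled["label"] == "cobound").mean()
        # Monte-Carlo expectation of the observed rate under the 50 bp rule
        rng = np.random.default_rng(0)
        draws = np.abs(np.round(rng.normal(0, 15 * np.sqrt(2), 200_000)))
        p_correct = (draws <= 50).mean()
        expected = 0.5 * p_correct  # distinct promoters are always > 100 bp
        se = np.sqrt(expected * (1 - expected) / 400)
        assert abs(observed - expected) <= 3 * se
        # labels agree with truth wherever distances are conclusive
        merged = labeled.merge(sim.truth, on="gene_id", suffixes=("_called", "_true"))
        distinct_true = merged[merged["label_true"] == "distinct"]
        assert (distinct_true["label_called"] == "distinct").all()
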