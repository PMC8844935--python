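"""Replicate reconciliation, peak-set union, and promoter assignment."""

import numpy as np
import pytest

from regulonkit.errors import InputFormatError
from regulonkit.genome import GeneModel, GenomeAnnotation, promoter_window
from regulonkit.peaks import (
    ReconciledPeak,
    Summit,
    assign_summits_to_genes,
    count_sites_per_promoter,
    merge_peak_sets,
    read_summits_narrowpeak,
    reconcile_replicates,
)


def summits(positions, sample="s", chrom="chr1"):
    return [Summit(chrom, p, 1.0, sample) for p in positions]


def peaks(positions, chrom="chr1", source="x"):
    return [
        ReconciledPeak(chrom, p, (Summit(chrom, p, 1.0, source),), frozenset({source}))
        for p in positions
    ]


class TestReconcile:
    def test_within_threshold_merges_at_midpoint(self):
        res = reconcile_replicates(summits([1000], "a"), summits([1080], "b"))
        assert [p.pos for p in res.peaks] == [1040]
        assert res.peaks[0].provenance == {"a", "b"}

    def test_beyond_threshold_rejected(self):
        res = reconcile_replicates(summits([1000], "a"), summits([1120], "b"))
        assert res.peaks == []
        assert len(res.unmatched_a) == 1 and len(res.unmatched_b) == 1

    def test_greedy_prefers_nearest(self):
        # B:1050 is 10 bp from A:1060 but 50 bp from A:1000
        res = reconcile_replicates(summits([1000, 1060], "a"), summits([1050], "b"))
        assert len(res.peaks) == 1
        assert {m.pos for m in res.peaks[0].members} == {1060, 1050}

    def test_duplicate_summits_rejected(self):
        with pytest.raises(InputFormatError):
            reconcile_replicates(summits([1000, 1000], "a"), summits([1100], "b"))

    def test_symmetry_and_size_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = summits(sorted(rng.choice(10_000, size=30, replace=False)), "a")
            b = summits(sorted(rng.choice(10_000, size=40, replace=False)), "b")
            ab = reconcile_replicates(a, b)
            ba = reconcile_replicates(b, a)
            assert sorted(p.pos for p in ab.peaks) == sorted(p.pos for p in ba.peaks)
            assert len(ab.peaks) <= min(len(a), len(b))


class TestMerge:
    def test_close_pair_merges_with_both_provenance(self):
        res = merge_peak_sets(peaks([5000]), peaks([5040]))
        assert len(res.peaks) == 1
        assert res.peaks[0].sources == {"setA", "setB"}
        assert res.shared_fraction == 1.0

    def test_far_pair_stays_separate(self):
        res = merge_peak_sets(peaks([5000]), peaks([5500]))
        assert len(res.peaks) == 2
        assert res.shared_fraction == 0.0

    def test_mixed_sets(self):
        res = merge_peak_sets(peaks([1000, 2000, 3000]), peaks([1010, 5000]))
        assert len(res.peaks) == 4
        assert res.shared == 1
        assert res.shared_fraction == pytest.approx(0.5)

    def test_output_size_identity_random(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = peaks(sorted(rng.choice(50_000, size=25, replace=False)), source="A")
            b = peaks(sorted(rng.choice(50_000, size=35, replace=False)), source="B")
            res = merge_peak_sets(a, b)
            assert len(res.peaks) == len(a) + len(b) - res.shared


def random_annotation(rng, n_genes=200, chrom_len=2_000_000):
    genes = []
    pos = 3000
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(1000, 2500))
        atg = pos if strand == "+" else pos + length - 1
        genes.append(GeneModel(f"g{i}", "chr1", strand, pos, pos + length, atg))
        pos += length + int(rng.integers(3000, 9000))
        if pos > chrom_len - 10_000:
            break
    return GenomeAnnotation(genes, {"chr1": chrom_len})


def brute_force_assign(ps, annotation, upstream=2000, downstream=200):
    """O(n*m) all-pairs containment scan — the assignment oracle."""
    out = set()
    for p in ps:
        for g in annotation.genes:
            w = promoter_window(g, upstream, downstream, chrom_len=annotation.chrom_sizes[g.chrom])
            if g.chrom == p.chrom and w.contains(p.pos):
                out.add((g.gene_id, p.chrom, p.pos))
    return out


class TestAssignment:
    def test_bidirectional_promoter_counts_for_both_genes(self):
        g1 = GeneModel("left", "chr1", "-", 10_000, 12_000, 11_999)
        g2 = GeneModel("right", "chr1", "+", 14_000, 16_000, 14_000)
        ann = GenomeAnnotation([g1, g2], {"chr1": 100_000})
        res = assign_summits_to_genes(peaks([13_000]), ann)
        assert sorted(a.gene_id for a in res.assignments) == ["left", "right"]

    def test_summit_past_downstream_bound_unassigned(self):
        g = GeneModel("g", "chr1", "+", 10_000, 12_000, 10_000)
        ann = GenomeAnnotation([g], {"chr1": 100_000})
        res = assign_summits_to_genes(peaks([10_300]), ann)
        assert res.assignments == []
        assert res.unassigned[0][1] == "gene_body"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ann = random_annotation(rng)
            ps = peaks(sorted(rng.choice(2_000_000, size=300, replace=False)))
            fast = assign_summits_to_genes(ps, ann)
            got = {(a.gene_id, a.peak.chrom, a.peak.pos) for a in fast.assignments}
            assert got == brute_force_assign(ps, ann)

    def test_distances_within_window(self):
        rng = np.random.default_rng(6)
        ann = random_annotation(rng)
        ps = peaks(sorted(rng.choice(2_000_000, size=500, replace=False)))
        res = assign_summits_to_genes(ps, ann)
        assert all(-2000 <= a.distance <= 200 for a in res.assignments)


class TestSiteCounts:
    def test_examples(self):
        g = GeneModel("g", "chr1", "+", 10_000, 12_000, 10_000)
        ann = GenomeAnnotation([g], {"chr1": 100_000})
        res = assign_summits_to_genes(peaks([8200, 9700]), ann)
        counts = count_sites_per_promoter(res.assignments)
        assert counts.loc["g", "n_sites"] == 2
        assert bool(counts.loc["g", "multi_site"])
        single = count_sites_per_promoter(
            assign_summits_to_genes(peaks([9700]), ann).assignments
        )
        assert single.loc["g", "n_sites"] == 1
        assert not bool(single.loc["g", "multi_site"])

    def test_noiseless_fixture_counts_equal_truth(self, noiseless_sim):
        """Planted 1..max-site promoters are recovered exactly without noise."""
        sim, regulon = noiseless_sim
        from regulonkit.peaks import reconcile_replicates, merge_peak_sets

        rec_ha = reconcile_replicates(
            regulon.summits["HA_rep1"], regulon.summits["HA_rep2"]
        )
        rec_gfp = reconcile_replicates(
            regulon.summits["GFP_rep1"], regulon.summits["GFP_rep2"]
        )
        merged = merge_peak_sets(rec_ha.peaks, rec_gfp.peaks).peaks
        res = assign_summits_to_genes(merged, sim.annotation)
        counts = count_sites_per_promoter(res.assignments)
        truth = regulon.truth.genes
        bound = truth[truth["bound"]]
        assert set(counts.index) == set(bound.index)
        for gid, row in bound.iterrows():
            assert counts.loc[gid, "n_sites"] == row["n_sites"]


def test_narrowpeak_summit_offset(tmp_path):
    p = tmp_path / "peaks.narrowPeak"
    p.write_text("chr1\t100\t400\tpeak1\t0\t.\t5.5\t4.2\t3.1\t120\n")
    s = read_summits_narrowpeak(p)
    assert s[0].pos == 220 and s[0].height == pytest.approx(5.5)
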