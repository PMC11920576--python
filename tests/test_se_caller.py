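import numpy as np
import pytest

from secircuit.io import GeneModel, Peak
from secircuit.se_caller import (RankedEnhancerTable, assign_nearest_gene,
                                 classify_super_enhancers, find_se_cutoff,
                                 rank_enhancers, stitch_enhancers)

from _oracles import brute_cutoff, brute_nearest_gene, brute_stitch


def _peak(chrom, start, end, sample=1.0, inp=0.0, name=None):
    return Peak(chrom, start, end, name or f"p{start}", sample, inp)


def _gene(gid, chrom, tss, is_tf=False):
    return GeneModel(gid, chrom, "+", tss, is_tf)


class TestStitching:
    def test_gap_at_12500_merges(self):
        peaks = [_peak("chr1", 1000, 2000), _peak("chr1", 14000, 15000)]
        (r,) = stitch_enhancers(peaks, [])
        assert (r.start, r.end, len(r.constituents)) == (1000, 15000, 2)

    def test_gap_above_12500_splits(self):
        peaks = [_peak("chr1", 1000, 2000), _peak("chr1", 14600, 15600)]
        regions = stitch_enhancers(peaks, [])
        assert [len(r.constituents) for r in regions] == [1, 1]

    def test_tss_proximal_peak_is_standalone(self):
        peaks = [_peak("chr1", 900, 1100), _peak("chr1", 5000, 6000)]
        regions = stitch_enhancers(peaks, [_gene("g", "chr1", 1000)])
        flagged = [r for r in regions if r.excluded_from_stitching]
        assert len(flagged) == 1
        assert (flagged[0].start, flagged[0].end) == (900, 1100)

    def test_negative_stitch_distance_rejected(self):
        with pytest.raises(ValueError):
            stitch_enhancers([], [], stitch_distance=-1)

    def test_matches_transitive_closure_oracle(self):
        """1,000 random peak sets (n <= 50) with random TSS layouts equal a
        brute-force transitive merge with the same gap and exclusion rules."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 51))
            chroms = rng.choice(["chr1", "chr2"], size=n)
            starts = rng.integers(0, 200_000, size=n)
            peaks, seen = [], set()
            for c, s in zip(chroms, starts):
                key = (c, int(s))
                if key in seen:
                    continue
                seen.add(key)
                peaks.append(_peak(str(c), int(s), int(s) + int(rng.integers(1, 3000))))
            genes = [_gene(f"g{i}", str(rng.choice(["chr1", "chr2"])),
                           int(rng.integers(0, 200_000)))
                     for i in range(int(rng.integers(0, 4)))]
            stitch = int(rng.choice([12_500, 3_000]))
            got = stitch_enhancers(peaks, genes, stitch_distance=stitch)
            got_merged = sorted(
                (r.chrom, r.start, r.end,
                 tuple((p.chrom, p.start, p.end) for p in r.constituents))
                for r in got if not r.excluded_from_stitching)
            got_excl = sorted(
                (r.chrom, r.start, r.end,
                 tuple((p.chrom, p.start, p.end) for p in r.constituents))
                for r in got if r.excluded_from_stitching)
            exp_merged, exp_excl = brute_stitch(
                [(p.chrom, p.start, p.end) for p in peaks],
                [(g.chrom, g.tss) for g in genes], stitch, 2_500)
            assert got_merged == sorted(exp_merged)
            assert got_excl == sorted(exp_excl)


class TestRanking:
    def test_score_is_clamped_input_subtracted_sum(self):
        regions = stitch_enhancers(
            [_peak("chr1", 0, 1000, 10, 2), _peak("chr1", 2000, 3000, 5, 1)], [])
        table = rank_enhancers(regions)
        assert table.scores[0] == pytest.approx(12.0)
        (neg,) = stitch_enhancers([_peak("chr1", 0, 1000, 1, 5)], [])
        assert neg.score() == 0.0

    def test_ties_broken_by_start_coordinate(self):
        a = stitch_enhancers([_peak("chr1", 50_000, 51_000, 12, 0)], [])
        b = stitch_enhancers([_peak("chr1", 1_000, 2_000, 12, 0)], [])
        table = rank_enhancers(a + b)
        assert [e.start for e in table.entries] == [1_000, 50_000]


class TestCutoff:
    def test_linear_scores_give_zero_supers(self):
        cut = find_se_cutoff(np.arange(1.0, 11.0))
        assert cut.n_super == 0 and not cut.degenerate

    def test_constant_scores_degenerate(self):
        cut = find_se_cutoff(np.array([5.0, 5.0, 5.0]))
        assert cut.n_super == 0 and cut.degenerate

    def test_short_input_degenerate(self):
        cut = find_se_cutoff(np.array([1.0, 9.0]))
        assert cut.n_super == 0 and cut.degenerate

    def test_matches_exhaustive_argmin_oracle(self):
        """The discrete tangent equals exhaustive argmin(y - x) on 1,000
        random log-normal score vectors."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(3, 200))
            s = np.exp(rng.normal(1, 1, size=n))
            cut = find_se_cutoff(s)
            idx, score, n_super = brute_cutoff(list(s))
            assert cut.cutoff_index == idx
            assert cut.cutoff_score == pytest.approx(score)
            assert cut.n_super == n_super

    def test_convex_power_curve_tangent_position(self):
        """For s_i = x_i^k the cutoff converges to the analytic slope-1
        tangent x* = (1/k)^(1/(k-1))."""
        for k in (2.0, 3.0, 5.0):
            n = 1_001
            x = np.arange(n) / (n - 1)
            cut = find_se_cutoff(x ** k)
            x_star = (1 / k) ** (1 / (k - 1))
            assert abs(cut.cutoff_index / (n - 1) - x_star) <= 2 / (n - 1)


class TestClassification:
    def _table(self, scores):
        regions = [
            stitch_enhancers([_peak("chr1", 10_000 * i, 10_000 * i + 500,
                                    float(s), 0.0)], [])[0]
            for i, s in enumerate(scores)
        ]
        return rank_enhancers(regions)

    def test_flag_count_and_monotonicity(self):
        rng = np.random.default_rng(3)
        table = self._table(np.exp(rng.normal(1, 1, 60)))
        cut = find_se_cutoff(table)
        df = classify_super_enhancers(table, cut)
        assert int(df["is_super"].sum()) == cut.n_super
        # every flagged row outranks every unflagged row
        if cut.n_super:
            assert df["is_super"].iloc[:cut.n_super].all()
            assert not df["is_super"].iloc[cut.n_super:].any()

    def test_scale_invariance_of_flags(self):
        """Multiplying every score by a constant leaves the flags unchanged
        (the cutoff geometry is scale-free); 100 random vectors."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            s = np.exp(rng.normal(0, 1.5, size=int(rng.integers(3, 50))))
            t1 = self._table(s)
            t2 = self._table(s * 3.7)
            f1 = classify_super_enhancers(t1, find_se_cutoff(t1))["is_super"]
            f2 = classify_super_enhancers(t2, find_se_cutoff(t2))["is_super"]
            assert (f1.values == f2.values).all()

    def test_mismatched_cutoff_rejected(self):
        t1 = self._table([1, 2, 30])
        t2 = self._table([1, 2, 3, 4])
        with pytest.raises(ValueError, match="mismatch"):
            classify_super_enhancers(t1, find_se_cutoff(t2))


class TestNearestGene:
    def test_midpoint_distance(self):
        (r,) = stitch_enhancers([_peak("chr1", 100, 200)], [])
        genes = [_gene("near", "chr1", 150), _gene("far", "chr1", 1000)]
        out = assign_nearest_gene([r], genes)
        a = out["chr1:100-200"]
        assert (a.gene_id, a.distance) == ("near", 0)

    def test_unannotated_chromosome_unassigned(self):
        (r,) = stitch_enhancers([_peak("chrUn", 0, 100)], [])
        out = assign_nearest_gene([r], [_gene("g", "chr1", 50)])
        assert out["chrUn:0-100"].gene_id is None

    def test_matches_exhaustive_oracle(self):
        """500 random SE/gene layouts agree with brute-force nearest-TSS."""
        rng = np.random.default_rng(5)
        for _ in range(500):
            (r,) = stitch_enhancers(
                [_peak("chr1", int(rng.integers(0, 90_000)),
                       int(rng.integers(90_001, 100_000)))], [])
            genes = [_gene(f"g{i}", "chr1", int(rng.integers(0, 100_000)))
                     for i in range(int(rng.integers(1, 20)))]
            got = assign_nearest_gene([r], genes)[f"chr1:{r.start}-{r.end}"]
            exp = brute_nearest_gene(r.midpoint,
                                     [(g.gene_id, g.tss) for g in genes])
            assert got.gene_id == exp
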