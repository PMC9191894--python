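import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbp_engage.annotation import (
    NONCODING,
    GeneModel,
    GenomeAnnotation,
    SplicingEventSet,
    assign_peak_feature,
    feature_distribution,
    hypergeometric_overlap,
    match_splicing_events,
    metagene_profile,
    relative_distance,
)
from rbp_engage.simulate import EclipSimConfig, simulate_eclip

from conftest import (
    brute_force_assign,
    brute_force_reldist,
    hypergeom_tail_enumeration,
    per_base_metagene,
)


class TestGeneModel:
    def test_segments_partition_plus_strand(self, toy_annotation):
        g = toy_annotation.genes[0]  # geneA
        assert g.utr5_segments() == [(0, 200)]
        assert g.utr3_segments() == [(2800, 3000)]
        assert g.intron_segments() == [(1200, 2200)]
        segs = g.feature_segments(500)
        covered = sum(e - s for lst in segs.values() for s, e in lst)
        assert covered == g.length

    def test_segments_minus_strand_utrs_flip(self, toy_annotation):
        g = toy_annotation.genes[1]  # geneB on '-'
        assert g.utr3_segments() == [(4000, 4300)]
        assert g.utr5_segments() == [(8600, 9000)]
        segs = g.feature_segments(500)
        assert (6000, 7000) in segs["distal_intron"]

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", "+", 100, 50, [(100, 50)], 100, 50)
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", "*", 0, 100, [(0, 100)], 0, 100)
        with pytest.raises(ValueError):  # overlapping exons
            GeneModel("g", "chr1", "+", 0, 100, [(0, 60), (50, 100)], 0, 100)


class TestAssignPeakFeature:
    def test_containment_in_3utr(self, toy_annotation):
        assert assign_peak_feature("chr1", 2850, 2900, "+", toy_annotation) == "3UTR"

    def test_proximal_intron_within_window(self, toy_annotation):
        # 300 nt into geneA's intron from the splice site
        assert assign_peak_feature("chr1", 1480, 1520, "+", toy_annotation) == "proximal_intron"

    def test_distal_intron(self, toy_annotation):
        assert assign_peak_feature("chr1", 6400, 6500, "-", toy_annotation) == "distal_intron"

    def test_noncoding(self, toy_annotation):
        assert assign_peak_feature("chr1", 3200, 3400, "+", toy_annotation) == NONCODING

    def test_strand_awareness(self, toy_annotation):
        assert assign_peak_feature("chr1", 2850, 2900, "-", toy_annotation) == NONCODING

    def test_malformed_interval(self, toy_annotation):
        with pytest.raises(ValueError):
            assign_peak_feature("chr1", 50, 50, "+", toy_annotation)

    def test_brute_force_oracle_random_peaks(self, toy_annotation):
        rng = np.random.default_rng(8)
        for _ in range(300):
            start = int(rng.integers(0, 9500))
            end = start + int(rng.integers(1, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            got = assign_peak_feature("chr1", start, end, strand, toy_annotation)
            want = brute_force_assign("chr1", start, end, strand, toy_annotation)
            assert got == want, (start, end, strand)


class TestFeatureDistribution:
    def test_single_category(self, toy_annotation):
        peaks = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [2810, 2850, 2900],
                              "end": [2840, 2880, 2950], "strand": ["+"] * 3})
        dist = feature_distribution(peaks, toy_annotation)
        assert dist.set_index("category").loc["3UTR", "fraction"] == 1.0

    def test_fractions_sum_to_one(self, toy_annotation):
        rng = np.random.default_rng(2)
        starts = rng.integers(0, 9000, 50)
        peaks = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 40,
                              "strand": np.where(rng.random(50) < 0.5, "+", "-")})
        dist = feature_distribution(peaks, toy_annotation)
        assert dist["fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert dist["count"].sum() == 50

    def test_empty_raises(self, toy_annotation):
        with pytest.raises(ValueError):
            feature_distribution(pd.DataFrame(columns=["chrom", "start", "end", "strand"]),
                                 toy_annotation)

    def test_planted_bias_recovered(self):
        # true sites loaded 4:1 toward the 3'UTR must show up in the
        # distribution of true-site categories
        cfg = EclipSimConfig(n_genes=30, n_true_sites=200, seed=3,
                            feature_bias={"3UTR": 4.0})
        annotation, peakset, truth = simulate_eclip(cfg)
        frac_utr3 = (truth["category"] == "3UTR").mean()
        # expected placement probability from the planted weights
        cats = [
            assign_peak_feature(r["chrom"], r["start"], r["end"], r["strand"], annotation)
            for _, r in peakset.peaks.iterrows()
        ]
        w = np.array([4.0 if c == "3UTR" else 1.0 for c in cats])
        p_expected = w[np.array(cats) == "3UTR"].sum() / w.sum()
        se = np.sqrt(p_expected * (1 - p_expected) / len(truth))
        assert abs(frac_utr3 - p_expected) <= 3 * se + 0.02


class TestMetageneProfile:
    def test_uniform_coverage(self):
        ann = GenomeAnnotation([GeneModel("g", "chr1", "+", 0, 1000, [(0, 1000)], 0, 1000)])
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        prof = metagene_profile(peaks, ann, n_bins=10)
        np.testing.assert_allclose(prof, 0.1, rtol=1e-9)

    def test_minus_strand_five_prime_in_bin_zero(self):
        ann = GenomeAnnotation([GeneModel("g", "chr1", "-", 0, 1000, [(0, 1000)], 0, 1000)])
        # 5'-most 1% of a minus-strand gene is the genomic right end
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [990], "end": [1000]})
        prof = metagene_profile(peaks, ann, n_bins=100)
        assert prof[0] == pytest.approx(1.0)
        assert prof[99] == 0.0

    def test_brute_force_oracle(self, toy_annotation):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 9000, 40)
        peaks = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + rng.integers(10, 300, 40)})
        got = metagene_profile(peaks, toy_annotation, n_bins=20)
        want = per_base_metagene(peaks, toy_annotation, n_bins=20)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_profile_sums_to_one(self, toy_annotation):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [700]})
        prof = metagene_profile(peaks, toy_annotation, n_bins=100)
        assert prof.sum() == pytest.approx(1.0)

    def test_strand_reversal_flips_profile(self):
        plus = GenomeAnnotation([GeneModel("g", "chr1", "+", 0, 1000, [(0, 1000)], 0, 1000)])
        minus = GenomeAnnotation([GeneModel("g", "chr1", "-", 0, 1000, [(0, 1000)], 0, 1000)])
        peaks = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 250], "end": [100, 300]})
        p_plus = metagene_profile(peaks, plus, n_bins=10)
        p_minus = metagene_profile(peaks, minus, n_bins=10)
        np.testing.assert_allclose(p_minus, p_plus[::-1], atol=1e-12)

    def test_mixture_property(self, toy_annotation):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [300]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [2500], "end": [2900]})
        pa = metagene_profile(a, toy_annotation, n_bins=10)
        pb = metagene_profile(b, toy_annotation, n_bins=10)
        pu = metagene_profile(pd.concat([a, b], ignore_index=True), toy_annotation, n_bins=10)
        wa, wb = 200, 400  # base-overlap masses
        np.testing.assert_allclose(pu, (wa * pa + wb * pb) / (wa + wb), atol=1e-9)

    def test_zero_length_gene_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", "+", 5, 5, [(5, 5)], 5, 5)


class TestRelativeDistance:
    def _df(self, chrom, mids):
        return pd.DataFrame({"chrom": chrom, "start": [m - 1 for m in mids],
                             "end": [m + 1 for m in mids]})

    def test_coincident_midpoints_zero(self):
        ref = self._df("chr1", [100, 200, 300])
        d, hist, skipped = relative_distance(self._df("chr1", [200]), ref)
        assert d.tolist() == [0.0]
        assert skipped == 0

    def test_halfway_gives_half(self):
        ref = self._df("chr1", [100, 300])
        d, _, _ = relative_distance(self._df("chr1", [200]), ref)
        assert d.tolist() == [0.5]

    def test_outside_span_skipped(self):
        ref = self._df("chr1", [100, 300])
        d, _, skipped = relative_distance(self._df("chr1", [50, 400, 200]), ref)
        assert skipped == 2 and len(d) == 1

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            relative_distance(self._df("chr1", [1]), self._df("chr1", []).iloc[:0])

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            ref_mid = np.sort(rng.choice(np.arange(10, 5000, 2), size=8, replace=False))
            q_mid = rng.integers(0, 5200, size=20)
            ref = self._df("chr1", list(ref_mid))
            q = self._df("chr1", list(q_mid))
            d_got, _, sk_got = relative_distance(q, ref)
            d_want, sk_want = brute_force_reldist(q, ref)
            assert sk_got == sk_want
            np.testing.assert_allclose(np.sort(d_got), np.sort(d_want), atol=1e-12)

    def test_uniform_null_mean_quarter(self):
        rng = np.random.default_rng(99)
        ref_mid = np.arange(0, 101_000, 1000)
        ref = self._df("chr1", list(ref_mid))
        q_mid = rng.integers(0, 100_000, size=10_000)
        d, hist, _ = relative_distance(self._df("chr1", list(q_mid)), ref)
        assert abs(d.mean() - 0.25) < 0.01
        assert hist["count"].sum() == len(d)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        ref = self._df("chr1", list(np.sort(rng.integers(100, 9000, 10))))
        q = self._df("chr1", list(rng.integers(0, 9500, 30)))
        d0, _, s0 = relative_distance(q, ref)
        shift = 12345
        d1, _, s1 = relative_distance(
            q.assign(start=q["start"] + shift, end=q["end"] + shift),
            ref.assign(start=ref["start"] + shift, end=ref["end"] + shift),
        )
        assert s0 == s1
        np.testing.assert_allclose(d0, d1, atol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_values_in_range(self, seed):
        rng = np.random.default_rng(seed)
        ref = self._df("chr1", list(np.sort(rng.integers(10, 1000, 5))))
        q = self._df("chr1", list(rng.integers(0, 1100, 10)))
        d, _, _ = relative_distance(q, ref)
        assert ((d >= 0) & (d <= 0.5)).all()


class TestMatchSplicingEvents:
    def _events(self, rows):
        return SplicingEventSet(pd.DataFrame(
            rows, columns=["chrom", "strand", "intron_start", "intron_end",
                           "cluster_id", "dPSI", "fdr"]))

    def test_identical_sets_jaccard_one(self):
        ev = self._events([("chr1", "+", 100, 500, "c1", 0.3, 0.01),
                           ("chr2", "-", 900, 1500, "c2", -0.2, 0.02)])
        matched, jac = match_splicing_events(ev, ev)
        assert jac == 1.0 and len(matched) == 2

    def test_disjoint_chromosomes_jaccard_zero(self):
        a = self._events([("chr1", "+", 100, 500, "c1", 0.3, 0.01)])
        b = self._events([("chr2", "+", 100, 500, "c1", 0.3, 0.01)])
        matched, jac = match_splicing_events(a, b)
        assert jac == 0.0 and len(matched) == 0

    def test_jittered_within_tolerance_all_matched(self):
        rng = np.random.default_rng(17)
        rows = [("chr1", "+", int(s), int(s + 400), f"c{i}", 0.1, 0.01)
                for i, s in enumerate(np.arange(0, 20_000, 1000))]
        a = self._events(rows)
        jit = [(c, st_, s + int(rng.integers(-5, 6)), e + int(rng.integers(-5, 6)), cid, d, f)
               for c, st_, s, e, cid, d, f in rows]
        b = self._events(jit)
        matched, jac = match_splicing_events(a, b, tolerance=10)
        assert jac == 1.0
        # brute-force check: every a-event has exactly one in-tolerance partner
        for ia, ra in a.events.iterrows():
            hits = [
                ib for ib, rb in b.events.iterrows()
                if abs(ra["intron_start"] - rb["intron_start"]) <= 10
                and abs(ra["intron_end"] - rb["intron_end"]) <= 10
            ]
            assert hits == [matched.loc[matched["index_a"] == ia, "index_b"].item()]

    def test_one_to_one_matching(self):
        a = self._events([("chr1", "+", 100, 500, "c1", 0.1, 0.01)])
        b = self._events([("chr1", "+", 100, 500, "x", 0.1, 0.01),
                          ("chr1", "+", 101, 501, "y", 0.1, 0.01)])
        matched, jac = match_splicing_events(a, b, tolerance=5)
        assert len(matched) == 1
        assert matched.iloc[0]["index_b"] == 0  # closest boundary wins

    def test_validation(self):
        with pytest.raises(ValueError):
            self._events([("chr1", "+", 500, 100, "c1", 0.1, 0.01)])
        with pytest.raises(ValueError):
            self._events([("chr1", "+", 100, 500, "c1", 1.5, 0.01)])


class TestHypergeometricOverlap:
    def test_zero_overlap_gives_one(self):
        assert hypergeometric_overlap(0, 5, 5, 20) == 1.0

    def test_closed_form_full_overlap(self):
        assert hypergeometric_overlap(5, 5, 5, 20) == pytest.approx(1 / 15504, rel=1e-10)

    def test_enumeration_small_universes(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            n = int(rng.integers(5, 31))
            a = int(rng.integers(1, n + 1))
            b = int(rng.integers(1, n + 1))
            k = int(rng.integers(0, min(a, b) + 1))
            got = hypergeometric_overlap(k, a, b, n)
            want = hypergeom_tail_enumeration(k, a, b, n)
            assert got == pytest.approx(min(want, 1.0), rel=1e-10, abs=1e-300)

    def test_symmetry_in_set_sizes(self):
        assert hypergeometric_overlap(3, 7, 12, 40) == pytest.approx(
            hypergeometric_overlap(3, 12, 7, 40), rel=1e-12
        )

    def test_monotone_nonincreasing_in_k(self):
        ps = [hypergeometric_overlap(k, 10, 12, 50) for k in range(0, 11)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_inconsistent_sizes_raise(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(3, 25, 5, 20)
        with pytest.raises(ValueError):
            hypergeometric_overlap(6, 5, 10, 20)
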