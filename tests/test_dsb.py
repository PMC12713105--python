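import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from breakscape.dsb import (
    BinnedTrack,
    ChromStateSegment,
    bins_with_state,
    call_enrichment_regions,
    classify_enhancer_proximity,
    compare_ratio_by_feature,
    count_reads_per_bin,
    coverage_fraction,
    dsb_ratio,
    element_fraction_by_class,
    hypergeom_bin_test,
    multiscale_median_smooth,
    repeat_subtype_correlation,
    split_ratio_classes,
    tss_distance_profile,
    tss_meta_profile,
)
from breakscape.genome import GeneRecord, GenomicInterval, make_bins
from breakscape.simulate import SimulationParams, generate_dsb_counts, generate_genome


def _track(binning, values):
    return BinnedTrack(binning, np.asarray(values, dtype=float))


def _ratio(binning, treated, control, pseudocount=0.5):
    return dsb_ratio(_track(binning, treated), _track(binning, control), pseudocount)


class TestCountReadsPerBin:
    def test_boundary_assignment(self):
        binning = make_bins({"chr1": 10_000}, 5000)
        sites = [GenomicInterval("chr1", p, p + 1) for p in (0, 4999, 5000)]
        track, skipped = count_reads_per_bin(sites, binning)
        assert track.values.tolist() == [2.0, 1.0]
        assert skipped == 0

    def test_empty_input_gives_zero_track(self):
        binning = make_bins({"chr1": 10_000}, 5000)
        track, _ = count_reads_per_bin([], binning)
        assert not track.values.any()

    def test_total_conserved_and_off_chromosome_skipped(self):
        binning = make_bins({"chr1": 100_000}, 5000)
        rng = np.random.default_rng(0)
        sites = [
            GenomicInterval("chr1", int(p), int(p) + 1)
            for p in rng.integers(0, 100_000, size=10_000)
        ]
        sites.append(GenomicInterval("chrM", 0, 1))
        track, skipped = count_reads_per_bin(sites, binning)
        assert track.values.sum() == 10_000
        assert skipped == 1

    def test_minus_strand_uses_five_prime_end(self):
        binning = make_bins({"chr1": 10_000}, 5000)
        # a minus-strand read spanning the boundary breaks at end-1 = 5000
        track, _ = count_reads_per_bin(
            [GenomicInterval("chr1", 4000, 5001, "-")], binning
        )
        assert track.values.tolist() == [0.0, 1.0]


class TestDsbRatio:
    def test_identical_samples_give_unit_ratio(self):
        binning = make_bins({"chr1": 20_000}, 5000)
        r = _ratio(binning, [3, 1, 4, 1], [3, 1, 4, 1])
        assert np.allclose(r.ratio, 1.0)

    def test_cpm_formula(self):
        binning = make_bins({"chr1": 10_000}, 5000)
        r = _ratio(binning, [10, 5], [5, 5], pseudocount=0.0)
        assert r.ratio[0] == pytest.approx((10 / 15) / (5 / 10))

    def test_invariance_to_library_scaling(self):
        binning = make_bins({"chr1": 20_000}, 5000)
        t = np.array([10, 0, 7, 3])
        c = np.array([4, 2, 2, 2])
        r1 = _ratio(binning, t, c)
        r2 = _ratio(binning, 2 * t, c)
        assert np.array_equal(r1.ratio, r2.ratio)

    def test_monotone_in_treated_count(self):
        binning = make_bins({"chr1": 10_000}, 5000)
        lo = _ratio(binning, [5, 10], [5, 5]).ratio[0]
        # raise bin-0 treated count, keep the library total fixed
        hi = _ratio(binning, [9, 6], [5, 5]).ratio[0]
        assert hi > lo

    def test_mismatched_binning_rejected(self):
        b1 = make_bins({"chr1": 10_000}, 5000)
        b2 = make_bins({"chr1": 10_000}, 2500)
        with pytest.raises(ValueError):
            dsb_ratio(_track(b1, [1, 1]), _track(b2, [1, 1, 1, 1]))


def _hypergeom_oracle(k, n, K, N):
    """Exhaustive upper-tail pmf summation from binomial coefficients."""
    total = 0.0
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestHypergeomBinTest:
    def test_worked_example(self):
        assert hypergeom_bin_test(4, 4, 5, 10) == pytest.approx(5 / 210)

    def test_zero_successes_is_certain(self):
        assert hypergeom_bin_test(0, 6, 10, 20) == 1.0

    def test_matches_enumeration(self):
        assert hypergeom_bin_test(5, 6, 10, 20) == pytest.approx(
            _hypergeom_oracle(5, 6, 10, 20)
        )

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_bin_test(5, 4, 10, 20)  # k > n


class TestCallEnrichmentRegions:
    def _toy(self, n=20):
        binning = make_bins({"chr1": n * 5000}, 5000)
        return binning

    def test_no_significant_bin_gives_empty_list(self):
        binning = self._toy()
        r = _ratio(binning, np.ones(20), np.ones(20))
        assert call_enrichment_regions(r, np.ones(20)) == []

    def test_adjacent_bins_merge_into_maximal_regions(self):
        binning = self._toy()
        treated = np.ones(20)
        treated[[3, 4, 5, 7]] = 50
        r = _ratio(binning, treated, np.ones(20))
        pvals = np.ones(20)
        pvals[[3, 4, 5, 7]] = 1e-9
        regions = call_enrichment_regions(r, pvals)
        spans = [(reg.interval.start, reg.interval.end) for reg in regions]
        assert spans == [(15_000, 30_000), (35_000, 40_000)]

    def test_regions_do_not_cross_chromosomes(self):
        binning = make_bins({"chr1": 10_000, "chr2": 10_000}, 5000)
        treated = np.array([10.0, 1, 1, 10])
        control = np.array([1.0, 10, 10, 1])
        r = _ratio(binning, treated, control)
        regions = call_enrichment_regions(r, np.array([1e-9, 1, 1, 1e-9]))
        assert [reg.interval.chrom for reg in regions] == ["chr1", "chr2"]

    def test_matches_brute_force_merge_oracle(self):
        rng = np.random.default_rng(42)
        binning = self._toy()
        treated = rng.integers(1, 100, 20).astype(float)
        control = np.ones(20)
        r = _ratio(binning, treated, control)
        pvals = rng.uniform(size=20) ** 3
        regions = call_enrichment_regions(r, pvals, 0.05, 2.0)
        q = stats.false_discovery_control(pvals, method="bh")
        sig = (q < 0.05) & (r.ratio >= 2.0)
        # brute force: walk the bins, open/close runs
        expected = []
        run = None
        for i, s in enumerate(sig):
            if s and run is None:
                run = i
            if not s and run is not None:
                expected.append((run, i - 1))
                run = None
        if run is not None:
            expected.append((run, 19))
        got = [
            (reg.interval.start // 5000, (reg.interval.end - 1) // 5000)
            for reg in regions
        ]
        assert got == expected


class TestMultiscaleMedianSmooth:
    def test_constant_track_constant_at_every_scale(self):
        binning = make_bins({"chr1": 100_000}, 5000)
        out = multiscale_median_smooth(
            _track(binning, np.full(20, 3.0)), [5000, 10_000, 50_000]
        )
        for track in out.values():
            assert np.allclose(track.values, 3.0)

    def test_even_window_uses_mean_of_central_pair(self):
        binning = make_bins({"chr1": 20_000}, 5000)
        out = multiscale_median_smooth(_track(binning, [1, 9, 2, 8]), [10_000])
        assert out[10_000].values.tolist() == [5.0, 5.0]

    def test_base_scale_is_identity(self):
        binning = make_bins({"chr1": 50_000}, 5000)
        vals = np.arange(10, dtype=float)
        out = multiscale_median_smooth(_track(binning, vals), [5000])
        assert np.array_equal(out[5000].values, vals)

    def test_matches_naive_window_median(self):
        rng = np.random.default_rng(1)
        binning = make_bins({"chr1": 515_000}, 5000)  # trailing partial window
        vals = rng.normal(size=binning.n_bins)
        out = multiscale_median_smooth(_track(binning, vals), [25_000])
        k = 5
        for w, got in enumerate(out[25_000].values):
            assert got == pytest.approx(np.median(vals[w * k : (w + 1) * k]))

    def test_non_multiple_scale_rejected(self):
        binning = make_bins({"chr1": 50_000}, 5000)
        with pytest.raises(ValueError):
            multiscale_median_smooth(_track(binning, np.zeros(10)), [7000])


class TestSplitRatioClasses:
    def test_equal_partition(self):
        binning = make_bins({"chr1": 500_000}, 5000)
        r = _ratio(binning, np.arange(100) + 1.0, np.ones(100))
        classes = split_ratio_classes(r, 10)
        assert sorted(np.bincount(classes)[1:]) == [10] * 10

    def test_remainder_goes_to_leading_classes(self):
        binning = make_bins({"chr1": 505_000}, 5000)
        r = _ratio(binning, np.arange(101) + 1.0, np.ones(101))
        sizes = np.bincount(split_ratio_classes(r, 10))[1:]
        assert sizes.tolist() == [11] + [10] * 9

    def test_class_one_holds_highest_ratios(self):
        binning = make_bins({"chr1": 100_000}, 5000)
        treated = np.zeros(20)
        treated[7] = 100
        r = _ratio(binning, treated, np.ones(20))
        classes = split_ratio_classes(r, 10)
        assert classes[7] == 1

    def test_ties_fall_back_to_genomic_order(self):
        binning = make_bins({"chr1": 100_000}, 5000)
        r = _ratio(binning, np.ones(20), np.ones(20))  # all ratios equal
        classes = split_ratio_classes(r, 10)
        assert classes.tolist() == sorted(classes.tolist())

    def test_too_few_bins_rejected(self):
        binning = make_bins({"chr1": 20_000}, 5000)
        r = _ratio(binning, np.ones(4), np.ones(4))
        with pytest.raises(ValueError):
            split_ratio_classes(r, 10)


class TestTssDistanceProfile:
    def test_identity_binning_returns_raw_values(self):
        binning = make_bins({"chr1": 100_000}, 5000)
        rng = np.random.default_rng(2)
        treated = rng.integers(1, 50, 20).astype(float)
        r = _ratio(binning, treated, np.ones(20))
        genes = [GeneRecord("g", GenomicInterval("chr1", 50_000, 60_000, "+"))]
        prof = tss_distance_profile(r, genes, n_bins=20)
        assert np.allclose(sorted(prof.mean_ratio, reverse=True), prof.mean_ratio)
        assert set(np.round(prof.mean_ratio, 9)) == set(np.round(r.ratio, 9))

    def test_planted_decay_recovered(self, default_sim, default_ratio):
        prof = tss_distance_profile(default_ratio, default_sim.genes, 500)
        assert prof.spearman_rho < -0.5

    def test_null_decay_uncorrelated(self):
        rhos = []
        for seed in range(20):
            p = SimulationParams(seed=seed, tss_decay=float("inf"),
                                 treatment_fold=1.0)
            ann = generate_genome(p)
            control, treated, _ = generate_dsb_counts(ann, p)
            r = dsb_ratio(treated, control)
            rhos.append(abs(tss_distance_profile(r, ann.genes, 500).spearman_rho))
        assert np.median(rhos) < 0.15


class TestElementFractionByClass:
    def test_no_tssa_gives_zero_fractions(self):
        binning = make_bins({"chr1": 100_000}, 5000)
        r = _ratio(binning, np.arange(20) + 1.0, np.ones(20))
        classes = split_ratio_classes(r, 10)
        states = [ChromStateSegment(GenomicInterval("chr1", 0, 100_000), "Quies")]
        fr = element_fraction_by_class(classes, r, states)
        assert not fr.tssa_fraction.any() and not fr.enha_fraction.any()

    def test_fractions_bounded(self, default_sim, default_ratio):
        classes = split_ratio_classes(default_ratio, 10)
        fr = element_fraction_by_class(
            classes, default_ratio, default_sim.annotation.states
        )
        for arr in (fr.tssa_fraction, fr.enha_fraction):
            assert ((0 <= arr) & (arr <= 1)).all()

    def test_planted_boost_makes_tssa_fraction_decreasing(
        self, default_sim, default_ratio
    ):
        classes = split_ratio_classes(default_ratio, 10)
        fr = element_fraction_by_class(
            classes, default_ratio, default_sim.annotation.states
        )
        inversions = sum(
            1 for a, b in zip(fr.tssa_fraction, fr.tssa_fraction[1:]) if b > a
        )
        assert inversions <= 2
        assert fr.tssa_fraction[0] > fr.tssa_fraction[-1]


class TestClassifyEnhancerProximity:
    def _seg(self, start, end, state):
        return ChromStateSegment(GenomicInterval("chr1", start, end), state)

    @pytest.mark.parametrize(
        "tssa_span,expected",
        [
            ((30_000, 30_500), "proximal"),  # gap 19 500
            ((29_000, 29_999), "distal"),  # gap 20 001 upstream
            ((71_001, 72_000), "distal"),  # gap 20 001 downstream
            ((50_500, 51_500), "proximal"),  # overlap -> gap 0
        ],
    )
    def test_20kb_rule(self, tssa_span, expected):
        segs = [
            self._seg(50_000, 51_000, "EnhA1"),
            self._seg(*tssa_span, "TssA"),
        ]
        out = classify_enhancer_proximity(segs, window=20_000)
        enh = next(s for s in out if s.state == "EnhA1")
        assert enh.proximity == expected

    def test_exact_boundary_is_proximal(self):
        segs = [
            self._seg(50_000, 51_000, "EnhA2"),
            self._seg(71_000, 72_000, "TssA"),  # gap exactly 20 000
        ]
        out = classify_enhancer_proximity(segs, window=20_000)
        assert out[0].proximity == "proximal"

    def test_no_tssa_on_chromosome_means_distal(self):
        out = classify_enhancer_proximity([self._seg(0, 1000, "EnhA1")])
        assert out[0].proximity == "distal"

    def test_non_enhancer_states_untouched(self):
        out = classify_enhancer_proximity([self._seg(0, 1000, "Quies")])
        assert out[0].proximity == "n/a"


class TestCompareRatioByFeature:
    def test_identical_distributions_not_significant(self):
        binning = make_bins({"chr1": 100_000}, 5000)
        sample = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 4.0, 9.0, 2.0, 7.0, 6.0])
        vals = np.concatenate([sample, sample])  # permuted labels of one sample
        r = _ratio(binning, vals, np.ones(20), pseudocount=0.0)
        res = compare_ratio_by_feature(r, set(range(10)))
        assert res.p_value >= 0.5

    def test_separated_groups_match_exact_enumeration(self):
        binning = make_bins({"chr1": 30_000}, 5000)
        r = _ratio(binning, [1, 2, 3, 10, 11, 12], np.ones(6), pseudocount=0.0)
        res = compare_ratio_by_feature(r, {0, 1, 2})
        # U = 0; two-sided exact p = 2 * 1/C(6,3)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / math.comb(6, 3))

    def test_planted_enhancer_boost_significant(self, default_sim, default_ratio):
        enha = bins_with_state(
            default_sim.annotation.states, default_ratio.binning, ["EnhA1", "EnhA2"]
        )
        res = compare_ratio_by_feature(default_ratio, np.flatnonzero(enha))
        assert res.p_value < 0.01
        assert res.median_a > res.median_b

    def test_null_rejection_rate_controlled(self):
        # feature bins vs rest under a fold-1 null, nominal 5%
        rejections = 0
        n_seeds = 400
        for seed in range(n_seeds):
            p = SimulationParams(seed=seed, n_chrom=1, chrom_len=5_000_000,
                                 n_genes=40, n_enhancers=40, treatment_fold=1.0)
            ann = generate_genome(p)
            control, treated, truth = generate_dsb_counts(ann, p)
            r = dsb_ratio(treated, control)
            res = compare_ratio_by_feature(
                r, np.flatnonzero(truth.regulatory_mask)
            )
            rejections += res.p_value < 0.05
        assert rejections / n_seeds <= 0.075

    def test_empty_group_rejected(self):
        binning = make_bins({"chr1": 20_000}, 5000)
        r = _ratio(binning, np.ones(4), np.ones(4))
        with pytest.raises(ValueError):
            compare_ratio_by_feature(r, set())


class TestRepeatSubtypeCorrelation:
    def test_subtype_on_high_ratio_bins_correlates_positively(self):
        binning = make_bins({"chr1": 100_000}, 5000)
        treated = np.ones(20)
        treated[10:] = 30.0
        r = _ratio(binning, treated, np.ones(20))
        repeats = [
            (GenomicInterval("chr1", 50_000 + i * 5000 + 100,
                             50_000 + i * 5000 + 1100), "L2")
            for i in range(10)
        ]
        rho, p = repeat_subtype_correlation(r, repeats)["L2"]
        assert rho > 0

    def test_constant_coverage_is_undefined(self):
        binning = make_bins({"chr1": 20_000}, 5000)
        r = _ratio(binning, [1, 2, 3, 4], np.ones(4))
        out = repeat_subtype_correlation(r, [(GenomicInterval("chr1", 0, 20_000), "L1")])
        assert np.isnan(out["L1"][0])

    def test_null_coverage_uncorrelated(self):
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            binning = make_bins({"chr1": 1_000_000}, 5000)
            treated = rng.integers(1, 40, binning.n_bins).astype(float)
            r = _ratio(binning, treated, np.ones(binning.n_bins))
            starts = rng.integers(0, 999_000, size=100)
            repeats = [
                (GenomicInterval("chr1", int(s), int(s) + 500), "B1") for s in starts
            ]
            rhos.append(abs(repeat_subtype_correlation(r, repeats)["B1"][0]))
        assert np.median(rhos) < 0.1

    def test_coverage_fraction_bounded(self):
        binning = make_bins({"chr1": 50_000}, 5000)
        rng = np.random.default_rng(3)
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + 800)
            for s in rng.integers(0, 49_000, 50)
        ]
        cov = coverage_fraction(ivs, binning)
        assert ((0 <= cov) & (cov <= 1)).all()


class TestTssMetaProfile:
    def _genes(self, tss, strand="+"):
        return [
            GeneRecord(
                "g",
                GenomicInterval("chr1", tss, tss + 2000, "+")
                if strand == "+"
                else GenomicInterval("chr1", tss - 1999, tss + 1, "-"),
            )
        ]

    def test_uniform_signal_gives_flat_profile(self):
        sizes = {"chr1": 100_000}
        sites = [GenomicInterval("chr1", p, p + 1) for p in range(0, 100_000, 100)]
        prof = tss_meta_profile(sites, self._genes(50_000), sizes)
        assert np.allclose(prof, prof[0])

    def test_symmetric_signal_gives_symmetric_profile(self):
        sizes = {"chr1": 100_000}
        sites = []
        for off in (200, 1200, 3300):
            sites.append(GenomicInterval("chr1", 50_000 - off, 50_000 - off + 1))
            sites.append(GenomicInterval("chr1", 50_000 + off - 1, 50_000 + off))
        prof = tss_meta_profile(sites, self._genes(50_000), sizes)
        assert np.allclose(prof, prof[::-1])

    def test_minus_strand_orientation_flip(self):
        sizes = {"chr1": 100_000}
        # downstream of a minus-strand TSS means smaller coordinates
        sites = [GenomicInterval("chr1", 49_000, 49_001)]
        prof = tss_meta_profile(sites, self._genes(50_000, "-"), sizes)
        assert prof[59] > 0  # (50_000-5000..50_000+5000), flip puts it at bin 59
        assert prof.sum() == prof[59]

    def test_edge_genes_excluded(self):
        sizes = {"chr1": 100_000}
        sites = [GenomicInterval("chr1", 500, 501)]
        with pytest.raises(ValueError, match="eligible"):
            tss_meta_profile(sites, self._genes(1000), sizes)
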