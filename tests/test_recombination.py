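"""Four-gamete statistics: informative sites, compatibility, decay curve,
baseline, exponential fit, spacing estimators, regions and permutation test."""

from itertools import combinations

import numpy as np
import pytest

from strepdiv import recombination as rc
from strepdiv.recombination import DecayCurve, DecayFit, InformativeSite

from conftest import (
    ALL_PAIR_PATTERNS,
    STRAINS5,
    make_matrix,
    make_sites,
    uniform_pattern_sites,
)


class TestInformativeSites:
    def test_singletons_excluded_two_sets_included(self):
        m = make_matrix(
            [10, 20, 30],
            ["GAAAA",   # singleton: minority {S1}
             "TTAAA",   # 2-set {S1,S2}
             "CCCAA"],  # 2-set {S4,S5} (minority is smaller class)
        )
        sites = rc.call_informative_sites(m)
        assert [s.position for s in sites] == [20, 30]
        assert sites[0].minority_set == {"S1", "S2"}
        assert sites[1].minority_set == {"S4", "S5"}

    def test_toy_six_site_matrix_hand_enumeration(self):
        m = make_matrix(
            [5, 15, 25, 35, 45, 55],
            ["AAAAC",  # singleton
             "GGTTT",  # minority {S1,S2}
             "ACACA",  # {S2,S4} (ties broken to non-reference class)
             "TATTT",  # singleton
             "CCGGC",  # {S3,S4}
             "AAAAT"],  # singleton
        )
        sites = rc.call_informative_sites(m)
        assert [s.position for s in sites] == [15, 25, 45]
        assert [s.minority_set for s in sites] == [
            {"S1", "S2"}, {"S2", "S4"}, {"S3", "S4"}
        ]

    def test_non_biallelic_site_is_internal_error(self):
        m = make_matrix([1], ["ACG" + "AA"])
        with pytest.raises(ValueError, match="not biallelic"):
            rc.call_informative_sites(m)


class TestFourGamete:
    def test_closed_form_equals_brute_force_on_all_pattern_pairs(self):
        """For five strains with 2-of-5 minority sets, compatibility reduces
        to equal-or-disjoint; verify against haplotype enumeration for all
        100 ordered pattern pairs."""
        for pa in ALL_PAIR_PATTERNS:
            for pb in ALL_PAIR_PATTERNS:
                a = InformativeSite(0, pa, STRAINS5)
                b = InformativeSite(100, pb, STRAINS5)
                haplotypes = {(s in pa, s in pb) for s in STRAINS5}
                expected = len(haplotypes) < 4
                closed_form = pa == pb or not (pa & pb)
                assert rc.four_gamete_compatible(a, b) is expected
                assert closed_form is expected

    def test_symmetry_and_reflexivity(self):
        a = InformativeSite(0, frozenset({"S1", "S2"}), STRAINS5)
        b = InformativeSite(9, frozenset({"S1", "S3"}), STRAINS5)
        assert rc.four_gamete_compatible(a, a)
        assert rc.four_gamete_compatible(a, b) == rc.four_gamete_compatible(b, a)

    def test_mismatched_strain_universe_raises(self):
        a = InformativeSite(0, frozenset({"S1", "S2"}), STRAINS5)
        b = InformativeSite(1, frozenset({"X1", "X2"}),
                            ("X1", "X2", "X3", "X4", "X5"))
        with pytest.raises(ValueError, match="mismatched"):
            rc.four_gamete_compatible(a, b)


class TestPairwiseCounts:
    def test_singleton_only_matrix_gives_zero_table(self):
        m = make_matrix([1, 2], ["CAAAA", "ATTTT"])
        counts = rc.pairwise_informative_counts(m)
        assert counts.to_numpy().sum() == 0

    def test_single_informative_site_fills_one_cell(self):
        m = make_matrix([1], ["TTAAA"])
        counts = rc.pairwise_informative_counts(m)
        assert counts.loc["S1", "S2"] == 1 and counts.loc["S2", "S1"] == 1
        assert counts.to_numpy().sum() == 2

    def test_clonal_simulation_supports_only_true_clades(self, clonal_dataset):
        """Clonal descent on the ((S1,S2),(S3,S4),S5) tree puts informative
        SNPs only in the two true clades; recombination populates all ten
        strain pairs."""
        _, _, matrix, _ = clonal_dataset
        counts = rc.pairwise_informative_counts(matrix)
        assert counts.loc["S1", "S2"] > 0 and counts.loc["S3", "S4"] > 0
        off = [counts.loc[a, b] for a, b in
               (("S1", "S3"), ("S1", "S4"), ("S2", "S3"), ("S2", "S5"))]
        assert all(v == 0 for v in off)

    def test_recombined_simulation_supports_all_patterns(self, recombined_dataset):
        _, _, matrix, _ = recombined_dataset
        counts = rc.pairwise_informative_counts(matrix)
        for a, b in combinations(STRAINS5, 2):
            assert counts.loc[a, b] > 0


class TestSignalCurveAndBaseline:
    def test_all_compatible_gives_unit_signal(self):
        sites = make_sites(range(0, 5000, 100), [{"S1", "S2"}, {"S3", "S4"}] * 25)
        curve = rc.phylogenetic_signal_curve(sites, baseline=0.4)
        occ = curve.occupied()
        assert occ.any()
        assert np.allclose(curve.y[occ], 1.0)
        assert np.allclose(curve.c[occ], 1.0)

    def test_uniform_pattern_baseline_approaches_two_fifths(self):
        """40 of the 100 ordered 2-of-5 pattern pairs are equal-or-disjoint,
        so shuffling uniform patterns drives c_rand to 0.4."""
        enumerated = sum(
            1 for a in ALL_PAIR_PATTERNS for b in ALL_PAIR_PATTERNS
            if a == b or not (a & b)
        ) / 100
        assert enumerated == 0.4
        sites = uniform_pattern_sites(5000, 4_000_000, seed=5)
        c_rand = rc.shuffled_baseline(sites, 20, seed=1)
        assert abs(c_rand - 0.4) < 0.01

    def test_degenerate_single_pattern_baseline_is_one(self):
        sites = make_sites(range(0, 1000, 50), [{"S1", "S2"}] * 20)
        assert rc.shuffled_baseline(sites, 5, seed=0) == 1.0
        with pytest.raises(ValueError, match="c_rand = 1"):
            rc.phylogenetic_signal_curve(sites, baseline=1.0)

    def test_baseline_determinism(self):
        sites = uniform_pattern_sites(500, 300_000, seed=2)
        assert rc.shuffled_baseline(sites, 5, seed=9) == \
            rc.shuffled_baseline(sites, 5, seed=9)

    def test_pair_binning_counts(self):
        # three sites, distances 150, 250, 400 -> bins 1, 2, 3 (100 bp bins)
        sites = make_sites([0, 150, 400], [{"S1", "S2"}] * 3)
        curve = rc.phylogenetic_signal_curve(sites, max_pair_distance=1000,
                                             bin_size=100, baseline=0.0)
        assert int(curve.n_pairs.sum()) == 3
        assert list(np.flatnonzero(curve.n_pairs)) == [1, 2, 3]


class TestExponentialFit:
    def test_flat_unit_signal_fits_zero(self):
        curve = DecayCurve(
            bin_mid=np.arange(50, 20000, 100.0),
            n_pairs=np.full(200, 10),
            c=np.ones(200),
            c_rand=0.4,
            y=np.ones(200),
        )
        assert rc.fit_exponential_decay(curve).b == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("b_true", [1e-3, 2.071e-4, 5e-5])
    def test_noiseless_round_trip(self, b_true):
        x = np.arange(50, 20000, 100.0)
        curve = DecayCurve(
            bin_mid=x, n_pairs=np.full(x.size, 100),
            c=np.exp(-b_true * x), c_rand=0.0, y=np.exp(-b_true * x),
        )
        fit = rc.fit_exponential_decay(curve)
        assert fit.b == pytest.approx(b_true, rel=1e-6)
        assert fit.sse < 1e-12

    def test_too_few_bins_raise(self):
        curve = DecayCurve(
            bin_mid=np.array([50.0, 150.0]), n_pairs=np.array([5, 5]),
            c=np.array([1.0, 0.9]), c_rand=0.0, y=np.array([1.0, 0.9]),
        )
        with pytest.raises(ValueError, match="occupied bins"):
            rc.fit_exponential_decay(curve)


class TestIncompatibleSpacing:
    def test_adjacent_mode_simple(self):
        sites = make_sites([100, 200], [{"S1", "S2"}, {"S1", "S3"}])
        assert rc.mean_incompatible_distance(sites, "adjacent") == 100.0

    def test_adjacent_mode_alternating(self):
        # incompatible adjacent pairs at fixed 500 bp spacing
        pats = [{"S1", "S2"}, {"S1", "S3"}] * 4
        sites = make_sites(range(0, 4000, 500), pats)
        assert rc.mean_incompatible_distance(sites, "adjacent") == 500.0

    def test_no_incompatibilities_raise(self):
        sites = make_sites([0, 100], [{"S1", "S2"}, {"S1", "S2"}])
        with pytest.raises(ValueError, match="undefined"):
            rc.mean_incompatible_distance(sites, "adjacent")

    def test_hudson_kaplan_against_exhaustive_oracle(self):
        """The greedy interval pruning returns a maximum set of disjoint
        incompatible intervals; compare with brute force over subsets."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = 10
            pos = np.sort(rng.choice(5000, size=n, replace=False))
            sites = [
                InformativeSite(int(p), ALL_PAIR_PATTERNS[rng.integers(10)], STRAINS5)
                for p in pos
            ]
            intervals = []
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = sites[i], sites[j]
                    if not (a.minority_set == b.minority_set
                            or not (a.minority_set & b.minority_set)):
                        intervals.append((sites[i].position, sites[j].position))
            if not intervals:
                continue

            # exact recursion: max set of pairwise-disjoint open intervals
            def max_disjoint(ivs):
                if not ivs:
                    return 0
                first, rest = ivs[0], ivs[1:]
                without = max_disjoint(rest)
                with_first = 1 + max_disjoint(
                    [iv for iv in rest if iv[0] >= first[1] or iv[1] <= first[0]]
                )
                return max(without, with_first)

            best = max_disjoint(sorted(set(intervals)))
            assert len(rc.hudson_kaplan_intervals(sites)) == best


class TestCompatibleRegions:
    def test_fully_compatible_dataset_is_one_region(self):
        sites = make_sites(range(0, 3000, 100), [{"S1", "S2"}, {"S3", "S4"}] * 15)
        regions = rc.find_compatible_regions(sites, 20_000)
        assert len(regions) == 1
        assert regions[0].start == 0 and regions[0].end == 2900
        assert regions[0].n_sites == 30

    def test_mid_run_incompatibility_splits(self):
        pats = [{"S1", "S2"}] * 10 + [{"S1", "S3"}] + [{"S1", "S2"}] * 10
        sites = make_sites(range(0, 2100, 100), pats)
        regions = rc.find_compatible_regions(sites, 20_000)
        # the {S1,S3} site conflicts with every {S1,S2} site: it splits the
        # run and stands alone as a single-site region
        assert [(r.start, r.end) for r in regions] == [
            (0, 900), (1000, 1000), (1100, 2000)
        ]

    def test_engineered_suppressed_tract_recovered(self):
        """A 20 kb recombination-free tract in a recombining simulation is
        recovered as the longest compatible region, overlapping truth."""
        from strepdiv.simulate import (
            SimulationConfig,
            apply_recombination,
            simulate_clonal_genomes,
        )

        L = 600_000
        span = (250_000, 20_134)
        cfg = SimulationConfig(genome_length=L, recomb_rate=100 * L / 1e6,
                               suppressed_region_specs=(span,), seed=5)
        _, matrix, _ = apply_recombination(*simulate_clonal_genomes(cfg), cfg)
        sites = rc.call_informative_sites(matrix)
        regions = rc.find_compatible_regions(sites, 20_000, min_length=8_000)
        longest = max(regions, key=lambda r: r.length)
        lo, hi = span[0], span[0] + span[1]
        overlap = max(0, min(longest.end, hi) - max(longest.start, lo))
        assert overlap > 0.6 * span[1]


class TestPermutationTest:
    def test_rank_logic_and_determinism(self):
        sites = uniform_pattern_sites(300, 200_000, seed=3)
        fit = DecayFit(b=2.071e-4, sse=0.0)
        regions = rc.find_compatible_regions(sites, 20_000)
        out1 = rc.permutation_test_regions(regions, sites, fit, 0.4, 50, seed=11)
        out2 = rc.permutation_test_regions(regions, sites, fit, 0.4, 50, seed=11)
        assert [r.p_value for r in out1] == [r.p_value for r in out2]
        # a short (sub-median) region must be non-significant
        shortest = min(out1, key=lambda r: r.length)
        assert shortest.p_value > 0.5
        assert all(0 < r.p_value <= 1 for r in out1)

    def test_invalid_replicate_count_raises(self):
        sites = uniform_pattern_sites(50, 10_000, seed=1)
        with pytest.raises(ValueError, match="n_permutations"):
            rc.null_span_distribution(sites, DecayFit(1e-4, 0.0), 0.4, 0, seed=0)
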