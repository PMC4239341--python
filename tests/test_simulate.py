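"""Synthetic-data generator: clonal descent, recombination overlay,
islands, co-evolving pairs, and determinism."""

import numpy as np
import pytest

from strepdiv.content import find_islands
from strepdiv.coevolution import coevolution_test
from strepdiv.datatypes import gc_fraction
from strepdiv.recombination import call_informative_sites, four_gamete_compatible
from strepdiv.simulate import (
    SimulationConfig,
    apply_recombination,
    build_true_ortholog_table,
    default_tree,
    inject_strain_islands,
    simulate_clonal_genomes,
    simulate_dataset,
    simulate_paired_locus_alignments,
    study_config,
)


def brute_force_compatible(a, b):
    """Four-gamete oracle: enumerate the haplotype classes directly."""
    combos = {
        (s in a.minority_set, s in b.minority_set) for s in a.strains
    }
    return len(combos) < 4


class TestClonalSimulation:
    def test_zero_mutation_rate_gives_identical_genomes(self):
        cfg = SimulationConfig(genome_length=10_000, mutation_scale=0.0, seed=1)
        genomes, matrix, _ = simulate_clonal_genomes(cfg)
        assert matrix.n_sites == 0
        ref = genomes["S1"]
        for s in genomes.strains:
            assert np.array_equal(genomes[s], ref)

    def test_variant_count_within_poisson_band(self):
        cfg = SimulationConfig(genome_length=1_000_000, seed=5)
        _, matrix, _ = simulate_clonal_genomes(cfg)
        mean = 0.009 * cfg.genome_length  # total tree length x L
        assert abs(matrix.n_sites - mean) < 3 * np.sqrt(mean)

    def test_base_composition_matches_gc_target(self):
        cfg = SimulationConfig(genome_length=150_000, seed=2)
        genomes, _, _ = simulate_clonal_genomes(cfg)
        for s in genomes.strains:
            assert abs(gc_fraction(genomes[s]) - 0.71) < 0.01

    def test_infinite_sites_infeasible_raises(self):
        tree = "((S1:0.5,S2:0.5):0.25,(S3:0.5,S4:0.5):0.25,S5:0.5);"
        cfg = SimulationConfig(genome_length=1_000, tree=tree, seed=1)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_clonal_genomes(cfg)

    def test_clonal_informative_pairs_all_compatible(self, clonal_dataset):
        """Infinite-sites clonal descent admits no four-gamete violation
        (checked against brute-force haplotype enumeration)."""
        _, _, matrix, _ = clonal_dataset
        sites = call_informative_sites(matrix)
        assert len(sites) > 100
        # exhaustive over adjacent windows, oracle-checked
        for i in range(len(sites) - 1):
            for j in range(i + 1, min(i + 20, len(sites))):
                assert brute_force_compatible(sites[i], sites[j])
                assert four_gamete_compatible(sites[i], sites[j])

    def test_matrix_consistent_with_sequences(self, clonal_dataset):
        _, genomes, matrix, _ = clonal_dataset
        for k, strain in enumerate(matrix.strains):
            assert np.array_equal(
                genomes[strain][matrix.positions], matrix.alleles[:, k]
            )

    def test_finite_sites_model_runs_and_is_biallelic(self):
        cfg = SimulationConfig(
            genome_length=100_000, mutation_model="finite_sites_JC", seed=3
        )
        _, matrix, _ = simulate_clonal_genomes(cfg)
        assert matrix.n_sites > 0
        matrix.validate()

    def test_determinism(self):
        a = simulate_clonal_genomes(SimulationConfig(genome_length=50_000, seed=9))
        b = simulate_clonal_genomes(SimulationConfig(genome_length=50_000, seed=9))
        assert a[0] == b[0] and a[1] == b[1]


class TestRecombination:
    def test_zero_rate_is_identity(self, clonal_dataset):
        cfg, genomes, matrix, truth = clonal_dataset
        g2, m2, t2 = apply_recombination(genomes, matrix, truth, cfg)
        assert g2 == genomes and m2 == matrix
        assert t2.recomb_tracts == []

    def test_tract_copy_semantics(self):
        """Inside each tract of the first recombining strain, recipient
        alleles equal the donor's at every SNP position."""
        L = 200_000
        cfg = SimulationConfig(genome_length=L, recomb_rate=2.0, seed=4)
        genomes, matrix, truth = simulate_clonal_genomes(cfg)
        g2, m2, t2 = apply_recombination(genomes, matrix, truth, cfg)
        assert t2.recomb_tracts, "expected at least one tract at this rate"
        first = t2.recomb_tracts[0]
        r = g2[first.recipient][first.start:first.end]
        d = g2[first.donor][first.start:first.end]
        assert np.array_equal(r, d)

    def test_sequences_stay_consistent_with_matrix(self, recombined_dataset):
        _, genomes, matrix, _ = recombined_dataset
        for k, strain in enumerate(matrix.strains):
            assert np.array_equal(
                genomes[strain][matrix.positions], matrix.alleles[:, k]
            )

    def test_recombination_creates_incompatibilities(self, recombined_dataset):
        _, _, matrix, _ = recombined_dataset
        sites = call_informative_sites(matrix)
        n_incompat = sum(
            not four_gamete_compatible(sites[i], sites[i + 1])
            for i in range(len(sites) - 1)
        )
        assert n_incompat > 10

    def test_suppressed_region_excludes_tracts(self):
        L = 400_000
        region = (150_000, 20_000)
        cfg = SimulationConfig(
            genome_length=L, recomb_rate=100 * L / 1e6,
            suppressed_region_specs=(region,), seed=6,
        )
        genomes, matrix, truth = simulate_clonal_genomes(cfg)
        _, _, t2 = apply_recombination(genomes, matrix, truth, cfg)
        s, e = region[0], region[0] + region[1]
        for tract in t2.recomb_tracts:
            assert not (s <= tract.start < e)
            assert not (tract.start < e and tract.end > s) or tract.end <= s

    def test_suppressed_region_out_of_bounds_raises(self):
        cfg = SimulationConfig(genome_length=10_000, recomb_rate=1.0,
                               suppressed_region_specs=((9_000, 5_000),), seed=1)
        genomes, matrix, truth = simulate_clonal_genomes(cfg)
        with pytest.raises(ValueError, match="outside genome bounds"):
            apply_recombination(genomes, matrix, truth, cfg)

    def test_incompatible_fraction_monotone_in_rate(self):
        """More gene-conversion tracts produce a larger fraction of
        incompatible informative-site pairs (3-point grid, same seeds)."""
        from strepdiv.recombination import _compatible_masks, _pair_index, _site_arrays

        fractions = []
        L = 300_000
        for rate_per_mb in (10, 50, 250):
            cfg = SimulationConfig(genome_length=L, recomb_rate=rate_per_mb * L / 1e6,
                                   seed=13)
            out = apply_recombination(*simulate_clonal_genomes(cfg), cfg)
            sites = call_informative_sites(out[1])
            pos, masks, U = _site_arrays(sites)
            i, j = _pair_index(pos, 20_000)
            fractions.append(float((~_compatible_masks(masks[i], masks[j], U)).mean()))
        assert fractions[0] <= fractions[1] <= fractions[2]


class TestIslands:
    def test_empty_spec_is_identity(self, toy_table):
        from strepdiv.datatypes import GenomeSet, TruthSet

        genomes = GenomeSet({s: "A" * 3000 for s in toy_table.strains})
        truth = TruthSet(genome_length=3000)
        _, table2, _ = inject_strain_islands(genomes, toy_table, truth, (), seed=0)
        assert table2 == toy_table

    def test_island_roundtrip_and_detection_floor(self):
        """A 12 kb injected island is recovered by the scanner; an 8 kb
        island is recorded in truth but stays below the 10 kb floor."""
        from strepdiv.datatypes import GenomeSet, TruthSet

        cfg = SimulationConfig(genome_length=200_000, seed=8)
        table = build_true_ortholog_table(
            SimulationConfig(genome_length=200_000, core_fraction=1.0, seed=8)
        )
        genomes = GenomeSet({s: "A" * 200_000 for s in cfg.strains})
        truth = TruthSet(genome_length=200_000)
        _, table2, truth = inject_strain_islands(
            genomes, table, truth,
            [("S1", 12_000, 10, 50_000), ("S1", 8_000, 6, 120_000)], seed=0,
        )
        assert ("S1", 50_000, 62_000) in truth.islands
        assert ("S1", 120_000, 128_000) in truth.islands
        found = find_islands(table2, "S1", 10_000, 0.5)
        spans = [(r.start, r.end) for r in found]
        assert any(abs(s - 50_000) <= 1100 and abs(e - 62_000) <= 1100
                   for s, e in spans)
        assert not any(115_000 < s < 130_000 for s, _ in spans)

    def test_overlapping_explicit_islands_raise(self):
        from strepdiv.datatypes import GenomeSet, TruthSet

        table = build_true_ortholog_table(
            SimulationConfig(genome_length=100_000, seed=1)
        )
        genomes = GenomeSet({s: "A" * 100_000 for s in table.strains})
        truth = TruthSet(genome_length=100_000)
        specs = [("S1", 12_000, 8, 10_000), ("S1", 12_000, 8, 15_000)]
        with pytest.raises(ValueError, match="overlaps"):
            inject_strain_islands(genomes, table, truth, specs, seed=0)


class TestPairedLoci:
    def test_zero_coupling_gives_null_correlation(self):
        rhos = [
            coevolution_test(
                simulate_paired_locus_alignments(200, 76, 274, 0.0, seed=s)
            ).rho
            for s in range(10)
        ]
        assert abs(np.mean(rhos)) < 0.05
        assert max(abs(r) for r in rhos) < 0.3

    def test_full_coupling_noiseless_is_rank_perfect(self):
        pairs = simulate_paired_locus_alignments(
            12, 400, 800, 1.0, seed=3, noise="none"
        )
        res = coevolution_test(pairs)
        assert res.rho == pytest.approx(1.0)

    def test_bad_lengths_raise(self):
        with pytest.raises(ValueError, match="lengths"):
            simulate_paired_locus_alignments(3, 0, 10, 0.5, seed=1)

    def test_tuned_coupling_detection_power(self):
        """With coupling tuned up to 0.8, fifteen loci give a significant
        positive correlation in the majority of replicates."""
        hits = 0
        for seed in range(60):
            pairs = simulate_paired_locus_alignments(15, 76, 274, 0.8, seed=seed)
            res = coevolution_test(pairs)
            hits += res.rho > 0 and res.p_value < 0.05
        assert hits > 30


class TestFullDataset:
    def test_study_dataset_structure(self):
        cfg = study_config(genome_length=400_000, seed=2,
                           island_specs=(("S1", 15_000, 12),),
                           suppressed_region_specs=((100_000, 20_000),))
        ds = simulate_dataset(cfg)
        assert ds.snp_matrix.n_sites > 1000
        ds.snp_matrix.validate()
        assert len(ds.pairs) == 15
        assert len(ds.truth.islands) == 1
        presence = ds.ortholog_table.presence_matrix()
        core_frac = (presence.all(axis=1)).mean()
        assert 0.7 < core_frac < 0.95

    def test_dataset_determinism(self, tmp_path):
        from strepdiv.simulate import write_dataset

        kw = dict(genome_length=100_000, seed=17, suppressed_region_specs=(),
                  island_specs=(("S1", 11_000, 9),))
        d1 = simulate_dataset(study_config(**kw))
        d2 = simulate_dataset(study_config(**kw))
        write_dataset(d1, tmp_path / "a")
        write_dataset(d2, tmp_path / "b")
        for p1 in sorted((tmp_path / "a").rglob("*")):
            if p1.is_file():
                p2 = tmp_path / "b" / p1.relative_to(tmp_path / "a")
                assert p1.read_bytes() == p2.read_bytes()
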