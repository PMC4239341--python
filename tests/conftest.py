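"""Shared fixtures: tiny hand-built tables and matrices, plus small
simulated datasets (generated at test time; nothing is stored on disk)."""

from itertools import combinations

import numpy as np
import pytest

from strepdiv.datatypes import GeneEntry, OrthologGroup, OrthologTable, SnpMatrix
from strepdiv.recombination import InformativeSite

STRAINS5 = ("S1", "S2", "S3", "S4", "S5")
ALL_PAIR_PATTERNS = [frozenset(c) for c in combinations(STRAINS5, 2)]


def make_matrix(positions, rows, strains=STRAINS5, ref=None):
    """SnpMatrix from string rows like 'AACCA' (one char per strain)."""
    alleles = np.array([list(r) for r in rows], dtype="S1")
    if ref is None:
        ref = [r[0] for r in rows]
    return SnpMatrix(np.asarray(positions), np.array(ref, dtype="S1"), alleles, strains)


def make_sites(positions, minority_sets, strains=STRAINS5):
    return [
        InformativeSite(int(p), frozenset(ms), tuple(strains))
        for p, ms in zip(positions, minority_sets)
    ]


def uniform_pattern_sites(n, genome_length, seed, strains=STRAINS5):
    """Shuffle-equilibrium sites: uniform 2-of-5 patterns at random positions."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(genome_length, size=n, replace=False))
    return [
        InformativeSite(int(p), ALL_PAIR_PATTERNS[rng.integers(10)], strains)
        for p in pos
    ]


@pytest.fixture
def toy_table():
    """Three strains: g1 in all, g2 only in A, g3 only in B."""
    return OrthologTable(
        ("A", "B", "C"),
        [
            OrthologGroup("g1", (GeneEntry("A_1", 0, 900), GeneEntry("B_1", 0, 900),
                                 GeneEntry("C_1", 0, 900))),
            OrthologGroup("g2", (GeneEntry("A_2", 1000, 1900), None, None)),
            OrthologGroup("g3", (None, GeneEntry("B_3", 2000, 2900), None)),
        ],
    )


@pytest.fixture(scope="session")
def clonal_dataset():
    """A 300 kb clonal (recombination-free) five-genome simulation."""
    from strepdiv.simulate import SimulationConfig, simulate_clonal_genomes

    cfg = SimulationConfig(genome_length=300_000, seed=11)
    genomes, matrix, truth = simulate_clonal_genomes(cfg)
    return cfg, genomes, matrix, truth


@pytest.fixture(scope="session")
def recombined_dataset():
    """A 500 kb study-regime simulation (mosaic recombination, no islands)."""
    from strepdiv.simulate import (
        SimulationConfig,
        apply_recombination,
        simulate_clonal_genomes,
    )

    L = 500_000
    cfg = SimulationConfig(genome_length=L, recomb_rate=100 * L / 1e6, seed=11)
    genomes, matrix, truth = simulate_clonal_genomes(cfg)
    genomes, matrix, truth = apply_recombination(genomes, matrix, truth, cfg)
    return cfg, genomes, matrix, truth
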