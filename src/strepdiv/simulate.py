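"""Five-strain synthetic genome datasets with known truth.

The generator emulates the structure of a clonal bacterial species sample
whose chromosomes have been homogenised by intraspecies homologous
recombination: five collinear ~7.5 Mb chromosomes at 71% G+C, ~6,700 genes
of which ~86% are core, strain-specific islands, a SNP density around
0.009/bp, mosaic gene-conversion tracts, engineered recombination-free
regions, and co-evolving gene pairs (a BldB/Hpb-like toxin-antitoxin
family).  Every stochastic stage draws from a sub-generator derived
deterministically from one master seed, so identical configurations give
byte-identical datasets and any single stage can be replayed.

Mutation uses an infinite-sites model by default: each variant position
mutates exactly once in the whole history, so four-gamete incompatibilities
can arise *only* from recombination.  A finite-sites Jukes-Cantor mode is
available to study homoplasy.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Phylo

from .datatypes import (
    GeneEntry,
    GenomeSet,
    OrthologGroup,
    OrthologTable,
    PairedLocusAlignments,
    RecombTract,
    SnpMatrix,
    TruthSet,
    seq_to_array,
)

BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")

# Fixed per-stage sub-seed keys; all randomness flows from one master seed.
_STAGE_KEYS = {
    "ancestor": 1,
    "mutations": 2,
    "recombination": 3,
    "islands": 4,
    "pairs": 5,
    "layout": 6,
}

#: Gene-conversion tract initiations per strain per Mb that, with the default
#: 5 kb mean tract length, reproduce the observed recombination regime: a
#: fitted signal-decay coefficient near 2.07e-4 per bp, incompatible sites
#: every ~1.2 kb, and near-uniform use of all ten 2-of-5 strain-pair
#: patterns (see docs/methods.md, "Calibration").  The decay length tracks
#: the mean tract length; the rate sets how far the shuffled baseline falls
#: below 1.
TRACTS_PER_STRAIN_PER_MB = 100.0


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_KEYS[stage],))
    )


def default_tree(n_strains: int = 5, total_length: float = 0.009) -> str:
    """A fixed balanced rooted tree in newick, branch lengths in subs/site.

    The default five-leaf shape ((S1,S2),(S3,S4),S5) carries terminal
    branches of 5/6 of the total length and two internal branches for the
    remaining 1/6, so most mutations are singletons -- mirroring a sample
    with little resolvable intraspecies structure.
    """
    if n_strains != 5:
        raise ValueError("the built-in default tree has exactly 5 leaves")
    t = total_length / 9.0  # 5 terminal + 2 internal branches, internal = t/2... see below
    # terminal branches: 1.5t each (x5), internal: 0.75t each (x2) => 9t total
    term = 1.5 * t
    internal = 0.75 * t
    return (
        f"((S1:{term:.10f},S2:{term:.10f}):{internal:.10f},"
        f"(S3:{term:.10f},S4:{term:.10f}):{internal:.10f},S5:{term:.10f});"
    )


def _parse_tree(newick: str) -> tuple[tuple[str, ...], list[tuple[frozenset, float]]]:
    """Return sorted leaf names and (leaf-set, branch length) per non-root edge."""
    tree = Phylo.read(_io.StringIO(newick), "newick")
    leaves = tuple(sorted(t.name for t in tree.get_terminals()))
    if len(set(leaves)) != len(leaves):
        raise ValueError("tree has duplicate leaf names")
    branches = []
    for clade in tree.find_clades():
        if clade is tree.root:
            continue
        below = frozenset(t.name for t in clade.get_terminals())
        branches.append((below, float(clade.branch_length or 0.0)))
    return leaves, branches


@dataclass
class SimulationConfig:
    """Parameters of one synthetic five-genome dataset.

    ``recomb_rate`` is the expected number of gene-conversion tract
    initiations per strain over the whole chromosome; tract lengths are
    geometric with mean ``tract_length_mean``.  ``island_specs`` entries are
    ``(strain, length_bp, n_genes)`` or ``(strain, length_bp, n_genes,
    start)``; ``suppressed_region_specs`` entries are ``(start,
    length_bp)``.  ``coupling`` is the target rank correlation of per-locus
    variability between the two partners of each co-evolving gene pair.
    """

    n_strains: int = 5
    genome_length: int = 7_500_000
    gc_content: float = 0.71
    tree: Optional[str] = None
    mutation_model: str = "infinite_sites"
    mutation_scale: float = 1.0
    recomb_rate: float = 0.0
    tract_length_mean: float = 5_000.0
    island_specs: tuple = ()
    suppressed_region_specs: tuple = ()
    n_gene_pairs: int = 15
    coupling: float = 0.61
    pair_length_A: int = 76
    pair_length_B: int = 274
    core_fraction: float = 0.859
    gene_length: int = 1_000
    gene_spacer: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.mutation_model not in ("infinite_sites", "finite_sites_JC"):
            raise ValueError(f"unknown mutation model {self.mutation_model!r}")
        for name in ("mutation_scale", "recomb_rate", "tract_length_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tree is None:
            self.tree = default_tree(self.n_strains)
        leaves, _ = _parse_tree(self.tree)
        if len(leaves) != self.n_strains:
            raise ValueError(
                f"tree has {len(leaves)} leaves but n_strains={self.n_strains}"
            )
        regions = sorted((int(s), int(s) + int(l)) for s, l in self.suppressed_region_specs)
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            if s2 < e1:
                raise ValueError("suppressed regions overlap")

    @property
    def strains(self) -> tuple[str, ...]:
        leaves, _ = _parse_tree(self.tree)
        return leaves


def study_config(**overrides) -> SimulationConfig:
    """The full study-emulation configuration: 7.5 Mb, mosaic recombination,
    eleven reference-strain islands totalling ~376.5 kb, two engineered
    recombination-suppressed regions (20,134 and 15,696 bp), and fifteen
    co-evolving gene pairs.

    At a reduced ``genome_length`` the suppressed regions keep their
    absolute lengths (they are the observables) but move to the same
    relative chromosome positions, and island lengths shrink
    proportionally, dropping islands that fall below a detectable 12 kb.
    """
    L = int(overrides.pop("genome_length", 7_500_000))
    factor = L / 7_500_000
    island_lengths = (60_000, 50_000, 45_000, 40_000, 36_505, 30_000,
                      28_000, 25_000, 22_000, 20_000, 20_000)
    islands = tuple(
        ("S1", round(l * factor), max(2, round(l * factor / 1100)))
        for l in island_lengths
        if l * factor >= 12_000
    )
    cfg = dict(
        genome_length=L,
        recomb_rate=TRACTS_PER_STRAIN_PER_MB * L / 1e6,
        island_specs=islands,
        suppressed_region_specs=(
            (round(3_000_000 * factor), 20_134),
            (round(5_500_000 * factor), 15_696),
        ),
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def simulate_clonal_genomes(
    config: SimulationConfig,
) -> tuple[GenomeSet, SnpMatrix, TruthSet]:
    """Evolve one ancestor along the strain tree with no recombination.

    Under ``infinite_sites`` every variant position mutates exactly once,
    so all informative-site pairs are four-gamete compatible.  Raises
    ``ValueError`` when the expected (or realized) mutation count exceeds
    the genome length, rather than silently recycling positions.
    """
    L = config.genome_length
    leaves, branches = _parse_tree(config.tree)
    col = {name: i for i, name in enumerate(leaves)}

    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    rng_anc = stage_rng(config.seed, "ancestor")
    ancestor = rng_anc.choice(BASES, size=L, p=probs)

    rng = stage_rng(config.seed, "mutations")
    bls = np.array([bl for _, bl in branches]) * config.mutation_scale
    total = float(bls.sum())

    if config.mutation_model == "infinite_sites":
        expected = total * L
        if expected > L:
            raise ValueError(
                f"infinite-sites model infeasible: expected mutation count "
                f"{expected:.0f} exceeds genome length {L}"
            )
        n_mut = int(rng.poisson(expected))
        if n_mut > L:
            raise ValueError(
                f"infinite-sites model infeasible: drew {n_mut} mutations "
                f"for genome length {L}"
            )
        positions = np.sort(rng.choice(L, size=n_mut, replace=False))
        if total > 0:
            branch_idx = rng.choice(len(branches), size=n_mut, p=bls / total)
        else:
            branch_idx = np.empty(0, dtype=int)
        anc_base = ancestor[positions]
        # derived base: uniform among the other three
        shift = rng.integers(1, 4, size=n_mut)
        anc_code = np.searchsorted(BASES, anc_base)
        derived = BASES[(anc_code + shift) % 4]

        alleles = np.tile(anc_base[:, None], (1, len(leaves)))
        for b, (leafset, _) in enumerate(branches):
            rows = np.flatnonzero(branch_idx == b)
            if rows.size == 0:
                continue
            cols = [col[name] for name in leafset]
            for c in cols:
                alleles[rows, c] = derived[rows]
        genomes = {}
        for name in leaves:
            seq = ancestor.copy()
            seq[positions] = alleles[:, col[name]]
            genomes[name] = seq
        matrix = SnpMatrix(positions, anc_base, alleles, leaves)
    else:  # finite_sites_JC
        tree = Phylo.read(_io.StringIO(config.tree), "newick")
        seqs: dict[str, np.ndarray] = {}

        def descend(clade, seq):
            for child in clade.clades:
                bl = float(child.branch_length or 0.0) * config.mutation_scale
                child_seq = seq.copy()
                n_events = rng.poisson(bl * L)
                pos = rng.integers(0, L, size=n_events)
                shift = rng.integers(1, 4, size=n_events)
                for p, s in zip(pos, shift):
                    code = int(np.searchsorted(BASES, child_seq[p]))
                    child_seq[p] = BASES[(code + s) % 4]
                if child.is_terminal():
                    seqs[child.name] = child_seq
                else:
                    descend(child, child_seq)

        descend(tree.root, ancestor)
        genomes = {name: seqs[name] for name in leaves}
        stack = np.stack([genomes[name] for name in leaves], axis=1)
        variant = (stack != stack[:, :1]).any(axis=1)
        positions = np.flatnonzero(variant)
        alleles = stack[positions]
        # keep the biallelic-matrix invariant: drop multi-hit columns
        keep = np.array(
            [len(set(alleles[i])) == 2 for i in range(len(positions))], dtype=bool
        )
        matrix = SnpMatrix(positions[keep], ancestor[positions[keep]],
                           alleles[keep], leaves)

    truth = TruthSet(genome_length=L)
    return GenomeSet(genomes), matrix, truth


def apply_recombination(
    genomes: GenomeSet,
    snp_matrix: SnpMatrix,
    truth: TruthSet,
    config: SimulationConfig,
) -> tuple[GenomeSet, SnpMatrix, TruthSet]:
    """Overlay gene-conversion tracts on clonally simulated genomes.

    Per strain the tract count is Poisson(``recomb_rate``), lengths are
    geometric with mean ``tract_length_mean``, donors are uniform among the
    other strains, and events are applied sequentially (later tracts may
    copy previously recombined sequence).  Tracts never initiate inside a
    configured suppressed region and are truncated at its boundary, which
    reproduces the observable of such regions -- no incompatible sites --
    without modelling a cause.  Columns homogenised by conversion are
    dropped from the returned matrix.
    """
    L = config.genome_length
    suppressed = sorted((int(s), int(s) + int(l)) for s, l in config.suppressed_region_specs)
    for s, e in suppressed:
        if not (0 <= s < e <= L):
            raise ValueError(f"suppressed region [{s}, {e}) outside genome bounds [0, {L})")

    out_genomes = genomes.copy()
    alleles = snp_matrix.alleles.copy()
    positions = snp_matrix.positions
    strains = list(genomes.strains)
    col = {s: i for i, s in enumerate(strains)}
    rng = stage_rng(config.seed, "recombination")
    tracts: list[RecombTract] = []

    def in_suppressed(p: int) -> bool:
        return any(s <= p < e for s, e in suppressed)

    for recipient in strains:
        n_tracts = int(rng.poisson(config.recomb_rate))
        others = [s for s in strains if s != recipient]
        for _ in range(n_tracts):
            donor = others[int(rng.integers(0, len(others)))]
            for _attempt in range(1000):
                start = int(rng.integers(0, L))
                if not in_suppressed(start):
                    break
            else:  # pragma: no cover - only with pathological configs
                raise RuntimeError("could not place tract outside suppressed regions")
            length = int(rng.geometric(1.0 / config.tract_length_mean))
            end = min(start + length, L)
            for s, e in suppressed:
                if start < s < end:
                    end = s
            if end <= start:
                continue
            out_genomes[recipient][start:end] = out_genomes[donor][start:end]
            lo, hi = np.searchsorted(positions, (start, end))
            alleles[lo:hi, col[recipient]] = alleles[lo:hi, col[donor]]
            tracts.append(RecombTract(recipient, donor, start, end))

    polymorphic = (alleles != alleles[:, :1]).any(axis=1) if alleles.size else \
        np.zeros(0, dtype=bool)
    matrix = SnpMatrix(
        positions[polymorphic], snp_matrix.ref[polymorphic],
        alleles[polymorphic], snp_matrix.strains,
    )
    truth.recomb_tracts = truth.recomb_tracts + tracts
    truth.suppressed_regions = list(suppressed)
    return out_genomes, matrix, truth


def layout_genes(
    genome_length: int, gene_length: int = 1_000, gene_spacer: int = 100
) -> list[tuple[int, int]]:
    """Deterministic gene grid: fixed-length genes separated by spacers."""
    step = gene_length + gene_spacer
    n = (genome_length + gene_spacer) // step
    return [(i * step, i * step + gene_length) for i in range(n)]


def build_true_ortholog_table(config: SimulationConfig) -> OrthologTable:
    """Lay out the gene grid and assign each slot core or strain-specific.

    Each slot is core (present in all strains, identical coordinates) with
    probability ``core_fraction``, otherwise specific to one uniformly
    chosen strain.  Strand is random but unused by downstream statistics.
    """
    strains = config.strains
    rng = stage_rng(config.seed, "layout")
    groups = []
    for i, (start, end) in enumerate(
        layout_genes(config.genome_length, config.gene_length, config.gene_spacer)
    ):
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"og{i:05d}"
        if rng.random() < config.core_fraction:
            entries = tuple(
                GeneEntry(f"{s}_{i:05d}", start, end, strand) for s in strains
            )
        else:
            owner = int(rng.integers(0, len(strains)))
            entries = tuple(
                GeneEntry(f"{s}_{i:05d}", start, end, strand) if j == owner else None
                for j, s in enumerate(strains)
            )
        groups.append(OrthologGroup(gid, entries))
    return OrthologTable(strains, groups)


def inject_strain_islands(
    genomes: GenomeSet,
    ortholog_table: OrthologTable,
    truth: TruthSet,
    island_specs: Sequence[tuple],
    seed: int,
) -> tuple[GenomeSet, OrthologTable, TruthSet]:
    """Convert chosen spans into strain-specific genomic islands.

    Each spec ``(strain, length, n_genes[, start])`` replaces the target
    strain's gene content over ``[start, start+length)`` with ``n_genes``
    genes present in that strain only; the other strains keep whatever the
    slots carried.  Explicit starts that overlap an already recorded island
    raise; random starts are resampled until they fit.
    """
    L = truth.genome_length
    strains = ortholog_table.strains
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(_STAGE_KEYS["islands"],)))
    existing: dict[str, list[tuple[int, int]]] = {}
    for strain, s, e in truth.islands:
        existing.setdefault(strain, []).append((s, e))

    groups = list(ortholog_table.groups)
    new_islands: list[tuple[str, int, int]] = []
    serial = sum(1 for g in groups if g.group_id.startswith("isl"))

    for spec in island_specs:
        if len(spec) == 4:
            strain, length, n_genes, start = spec
            start = int(start)
            explicit = True
        else:
            strain, length, n_genes = spec
            start, explicit = None, False
        length, n_genes = int(length), int(n_genes)
        if length <= 0 or n_genes < 1:
            raise ValueError(f"bad island spec {spec!r}")
        if length > L:
            raise ValueError(f"island of {length} bp does not fit in genome of {L} bp")
        taken = existing.setdefault(strain, [])

        def overlaps(s0):
            return any(s0 < e and s0 + length > s for s, e in taken)

        if explicit:
            if start + length > L:
                raise ValueError(f"island at {start}+{length} exceeds genome bounds")
            if overlaps(start):
                raise ValueError(
                    f"island at [{start}, {start + length}) overlaps an existing "
                    f"island in strain {strain}"
                )
        else:
            for _ in range(1000):
                start = int(rng.integers(0, L - length + 1))
                if not overlaps(start):
                    break
            else:
                raise RuntimeError("could not place island without overlap")
        end = start + length
        taken.append((start, end))

        si = list(strains).index(strain)
        # evict the target strain's genes overlapping the island span
        pruned = []
        for g in groups:
            e = g.entries[si]
            if e is not None and e.start < end and e.end > start:
                entries = tuple(
                    None if j == si else ge for j, ge in enumerate(g.entries)
                )
                if any(x is not None for x in entries):
                    pruned.append(OrthologGroup(g.group_id, entries))
            else:
                pruned.append(g)
        groups = pruned

        # insert island genes spanning exactly [start, end)
        gene_len = min(1_000, max(100, length // n_genes - 50))
        if n_genes == 1:
            starts = [start]
            gene_len = length
        else:
            starts = np.linspace(start, end - gene_len, n_genes).astype(int).tolist()
        for k, gs in enumerate(starts):
            gid = f"isl{serial:04d}"
            serial += 1
            entries = tuple(
                GeneEntry(f"{strain}_isl{serial:04d}_{k}", int(gs), int(gs) + gene_len, "+")
                if j == si else None
                for j in range(len(strains))
            )
            groups.append(OrthologGroup(gid, entries))
        new_islands.append((strain, start, end))

    truth.islands = truth.islands + new_islands
    truth.validate()
    return genomes, OrthologTable(strains, groups), truth


def simulate_paired_locus_alignments(
    n_loci: int,
    lengths_A: int | Sequence[int],
    lengths_B: int | Sequence[int],
    coupling: float,
    seed: int,
    strains: Sequence[str] = ("S1", "S2", "S3", "S4", "S5"),
    max_rate: float = 0.35,
    noise: str = "binomial",
    truth: Optional[TruthSet] = None,
) -> list[PairedLocusAlignments]:
    """Co-evolving partner-A/partner-B protein alignments for paired loci.

    A per-locus latent variability level is drawn once through a Gaussian
    copula with correlation ``coupling`` between partners, then converted to
    a per-column substitution rate in ``[0, max_rate]``; the count of
    variable columns is Binomial(length, rate) (``noise="binomial"``) or its
    rounded expectation (``noise="none"``, which makes coupling 1 give
    perfectly rank-correlated proportions).
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    lens_A = [int(lengths_A)] * n_loci if np.isscalar(lengths_A) else [int(x) for x in lengths_A]
    lens_B = [int(lengths_B)] * n_loci if np.isscalar(lengths_B) else [int(x) for x in lengths_B]
    if len(lens_A) != n_loci or len(lens_B) != n_loci:
        raise ValueError("length vectors must have n_loci entries")
    if any(l < 1 for l in lens_A + lens_B):
        raise ValueError("alignment lengths must be >= 1")
    from scipy.stats import norm

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(_STAGE_KEYS["pairs"],)))
    z1 = rng.standard_normal(n_loci)
    z2 = rng.standard_normal(n_loci)
    zB = coupling * z1 + np.sqrt(1.0 - coupling**2) * z2
    rate_A = norm.cdf(z1) * max_rate
    rate_B = norm.cdf(zB) * max_rate

    def make_alignment(length: int, rate: float) -> dict[str, str]:
        if noise == "binomial":
            k = int(rng.binomial(length, rate))
        elif noise == "none":
            k = int(round(length * rate))
        else:
            raise ValueError(f"unknown noise mode {noise!r}")
        anc = rng.choice(AMINO_ACIDS, size=length)
        seqs = np.tile(anc, (len(strains), 1))
        var_cols = rng.choice(length, size=k, replace=False)
        for c in var_cols:
            # a random nonempty proper subset of strains carries an alternative
            while True:
                members = rng.random(len(strains)) < 0.5
                if 0 < members.sum() < len(strains):
                    break
            alt = rng.choice(AMINO_ACIDS)
            while alt == anc[c]:
                alt = rng.choice(AMINO_ACIDS)
            seqs[members, c] = alt
        return {s: seqs[i].tobytes().decode() for i, s in enumerate(strains)}

    pairs = []
    for i in range(n_loci):
        locus = f"pair{i:03d}"
        pairs.append(
            PairedLocusAlignments(
                locus_id=locus,
                alignment_A=make_alignment(lens_A[i], rate_A[i]),
                alignment_B=make_alignment(lens_B[i], rate_B[i]),
            )
        )
        if truth is not None:
            truth.pair_loci.append((locus, float(rate_A[i])))
    return pairs


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimulationConfig
    genomes: GenomeSet
    snp_matrix: SnpMatrix
    ortholog_table: OrthologTable
    pairs: list[PairedLocusAlignments]
    truth: TruthSet


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: clonal descent, recombination overlay,
    gene grid with strain-specific content, islands, and co-evolving pairs."""
    genomes, matrix, truth = simulate_clonal_genomes(config)
    genomes, matrix, truth = apply_recombination(genomes, matrix, truth, config)
    table = build_true_ortholog_table(config)
    genomes, table, truth = inject_strain_islands(
        genomes, table, truth, config.island_specs, config.seed
    )
    pairs = simulate_paired_locus_alignments(
        config.n_gene_pairs,
        config.pair_length_A,
        config.pair_length_B,
        config.coupling,
        config.seed,
        strains=config.strains,
        truth=truth,
    )
    truth.true_ortholog_table = table
    return SimulatedDataset(config, genomes, matrix, table, pairs, truth)


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict[str, object]:
    """Write the dataset to ``out_dir`` in the documented file layout.

    Emits per-strain FASTA, GFF3 gene coordinates, a TSV SNP matrix, a TSV
    ortholog table, per-locus protein-alignment FASTA files, and
    ``truth.json``.  Re-reading the files with :mod:`strepdiv.io`
    reproduces the in-memory objects exactly.
    """
    from . import io as sio

    return sio.write_dataset_files(dataset, out_dir)
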