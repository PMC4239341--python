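"""Shared in-memory containers for the five-genome comparison pipeline.

All genomic coordinates are 0-based, half-open. On-disk formats keep their
native conventions (GFF3 and the SNP matrix TSV are 1-based; BED stays
0-based half-open); the readers and writers in :mod:`strepdiv.io` convert.
Sequences are stored as ``numpy`` byte arrays (dtype ``S1``) so that a
7.5 Mb chromosome costs one byte per base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

GC_BASES = frozenset(b"GCgc")


def seq_to_array(seq: str | bytes | np.ndarray) -> np.ndarray:
    """Coerce a nucleotide or protein sequence to a 1-byte-per-symbol array."""
    if isinstance(seq, np.ndarray):
        return seq.astype("S1", copy=False)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return np.frombuffer(seq, dtype="S1").copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def gc_fraction(arr: np.ndarray) -> float:
    """G+C fraction of a sequence array (upper- or lower-case)."""
    if arr.size == 0:
        return float("nan")
    return float(np.isin(arr, (b"G", b"C", b"g", b"c")).mean())


class GenomeSet:
    """Aligned, collinear chromosomes: one equal-length sequence per strain."""

    def __init__(self, sequences: Mapping[str, str | bytes | np.ndarray]):
        self._seqs = {name: seq_to_array(s) for name, s in sequences.items()}
        lengths = {a.size for a in self._seqs.values()}
        if len(lengths) > 1:
            raise ValueError(f"genomes have unequal lengths: {sorted(lengths)}")

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(self._seqs)

    @property
    def length(self) -> int:
        return next(iter(self._seqs.values())).size if self._seqs else 0

    def __getitem__(self, strain: str) -> np.ndarray:
        return self._seqs[strain]

    def __contains__(self, strain: str) -> bool:
        return strain in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self):
        return self._seqs.items()

    def copy(self) -> "GenomeSet":
        return GenomeSet({k: v.copy() for k, v in self._seqs.items()})

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeSet):
            return NotImplemented
        return self.strains == other.strains and all(
            np.array_equal(self._seqs[s], other._seqs[s]) for s in self._seqs
        )


class SnpMatrix:
    """Biallelic variant calls over aligned genome positions for N strains.

    Attributes
    ----------
    positions : strictly increasing 0-based coordinates (``int64``).
    ref : the ancestral/reference base at each position (dtype ``S1``).
    alleles : per-strain calls, shape ``(n_sites, n_strains)``, dtype ``S1``.
    strains : strain names, column order of ``alleles``.
    """

    def __init__(self, positions, ref, alleles, strains: Sequence[str]):
        self.positions = np.asarray(positions, dtype=np.int64)
        self.ref = np.asarray(ref, dtype="S1")
        self.alleles = np.asarray(alleles, dtype="S1")
        self.strains = tuple(strains)
        if self.alleles.shape != (self.positions.size, len(self.strains)):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{self.positions.size} positions x {len(self.strains)} strains"
            )

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def validate(self, one_based: bool = False) -> None:
        """Enforce the matrix invariants; raise ``ValueError`` naming the
        first offending position (``one_based=True`` reports coordinates in
        the on-disk 1-based convention)."""
        off = 1 if one_based else 0
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            i = int(np.argmax(np.diff(self.positions) <= 0))
            raise ValueError(
                f"positions not strictly increasing at index {i} "
                f"(position {self.positions[i + 1] + off})"
            )
        bad = np.isin(self.alleles, (b".", b"N", b"n", b"-", b""))
        if bad.any():
            i = int(np.argmax(bad.any(axis=1)))
            raise ValueError(f"missing call at position {self.positions[i] + off}")
        for i in range(self.n_sites):
            n_alleles = len(set(self.alleles[i]))
            if n_alleles != 2:
                raise ValueError(
                    f"site at position {self.positions[i] + off} has {n_alleles} "
                    "allele(s); exactly two required"
                )

    def subset(self, mask: np.ndarray) -> "SnpMatrix":
        return SnpMatrix(
            self.positions[mask], self.ref[mask], self.alleles[mask], self.strains
        )

    def copy(self) -> "SnpMatrix":
        return SnpMatrix(
            self.positions.copy(), self.ref.copy(), self.alleles.copy(), self.strains
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SnpMatrix):
            return NotImplemented
        return (
            self.strains == other.strains
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alleles, other.alleles)
        )

    @classmethod
    def empty(cls, strains: Sequence[str]) -> "SnpMatrix":
        return cls(
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype="S1"),
            np.empty((0, len(strains)), dtype="S1"),
            strains,
        )


@dataclass(frozen=True)
class GeneEntry:
    """One strain's gene in an ortholog group; coordinates 0-based half-open."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class OrthologGroup:
    group_id: str
    entries: tuple[Optional[GeneEntry], ...]  # parallel to OrthologTable.strains

    def presence(self) -> tuple[bool, ...]:
        return tuple(e is not None for e in self.entries)

    def n_present(self) -> int:
        return sum(e is not None for e in self.entries)


class OrthologTable:
    """Positional-ortholog groups x strains with coordinates/presence."""

    def __init__(self, strains: Sequence[str], groups: Iterable[OrthologGroup]):
        self.strains = tuple(strains)
        self.groups = list(groups)
        seen: set[str] = set()
        for g in self.groups:
            if len(g.entries) != len(self.strains):
                raise ValueError(f"group {g.group_id}: wrong entry count")
            if g.n_present() == 0:
                raise ValueError(f"group {g.group_id}: present in no strain")
            for e in g.entries:
                if e is not None:
                    if e.gene_id in seen:
                        raise ValueError(f"gene {e.gene_id} in more than one group")
                    seen.add(e.gene_id)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def __len__(self) -> int:
        return len(self.groups)

    def presence_matrix(self) -> np.ndarray:
        """Boolean array (n_groups, n_strains)."""
        return np.array([g.presence() for g in self.groups], dtype=bool).reshape(
            len(self.groups), len(self.strains)
        )

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"unknown strain {strain!r}") from None

    def genes_for(self, strain: str) -> list[tuple[OrthologGroup, GeneEntry]]:
        """Groups with a gene in `strain`, sorted by that strain's coordinates."""
        i = self.strain_index(strain)
        out = [(g, g.entries[i]) for g in self.groups if g.entries[i] is not None]
        out.sort(key=lambda ge: (ge[1].start, ge[1].end))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, OrthologTable):
            return NotImplemented
        return self.strains == other.strains and self.groups == other.groups


@dataclass
class RecombTract:
    """A realized gene-conversion event: recipient segment copied from donor."""

    recipient: str
    donor: str
    start: int
    end: int


@dataclass
class TruthSet:
    """Ground truth recorded by the simulator for recovery tests."""

    genome_length: int
    true_ortholog_table: Optional[OrthologTable] = None
    recomb_tracts: list[RecombTract] = field(default_factory=list)
    islands: list[tuple[str, int, int]] = field(default_factory=list)
    suppressed_regions: list[tuple[int, int]] = field(default_factory=list)
    pair_loci: list[tuple[str, float]] = field(default_factory=list)

    def validate(self) -> None:
        for t in self.recomb_tracts:
            if not (0 <= t.start < t.end <= self.genome_length):
                raise ValueError(f"tract {t} outside [0, {self.genome_length})")
        by_strain: dict[str, list[tuple[int, int]]] = {}
        for strain, s, e in self.islands:
            by_strain.setdefault(strain, []).append((s, e))
        for strain, spans in by_strain.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(f"islands overlap in strain {strain}")


@dataclass
class PairedLocusAlignments:
    """Co-localized partner-A/partner-B protein alignments for one locus."""

    locus_id: str
    alignment_A: dict[str, str]  # strain (or sequence) name -> aligned protein
    alignment_B: dict[str, str]

    def __post_init__(self):
        for name, aln in (("A", self.alignment_A), ("B", self.alignment_B)):
            if len(aln) < 2:
                raise ValueError(f"locus {self.locus_id}: partner {name} needs >=2 sequences")
            lengths = {len(s) for s in aln.values()}
            if len(lengths) > 1:
                raise ValueError(
                    f"locus {self.locus_id}: partner {name} sequences unequal lengths"
                )
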