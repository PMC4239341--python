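"""Core/pan genome statistics, gene-sharing histogram, strain-specific
island detection, and windowed conservation / G+C profiles.

All statistics run over a positional-ortholog table: gene groups defined
by occupying the same location in a whole-genome alignment, a stricter
criterion than similarity-only orthology.  Core/pan rarefaction curves are
exact means over all strain subsets of each size (cheap for five genomes),
not sampled orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import GeneEntry, OrthologGroup, OrthologTable, gc_fraction


@dataclass
class IslandRegion:
    """A run of consecutive reference-strain genes enriched in
    strain-specific content."""

    strain: str
    start: int
    end: int
    n_genes: int
    n_specific: int

    @property
    def specific_fraction(self) -> float:
        return self.n_specific / self.n_genes

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ConservationWindow:
    start: int
    end: int
    mean_sharing: float  # NaN for windows containing no gene midpoints
    gc: float
    short: bool = False


@dataclass
class ConservationProfile:
    windows: list[ConservationWindow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "start": w.start,
                    "end": w.end,
                    "mean_sharing": w.mean_sharing,
                    "gc": w.gc,
                    "short": w.short,
                }
                for w in self.windows
            ]
        )


def _reciprocal_overlap(a: GeneEntry, b: GeneEntry) -> bool:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return ov >= 0.5 * (a.end - a.start) and ov >= 0.5 * (b.end - b.start)


def build_positional_orthologs(
    gene_maps: dict[str, Sequence[GeneEntry]],
) -> OrthologTable:
    """Group genes across collinear genomes by reciprocal positional overlap.

    Genes from different strains join one group iff their (projected)
    intervals reciprocally overlap by at least 50%; unmatched genes become
    singleton groups.  Assumes the caller has already projected each
    strain's coordinates onto a common frame (for the synthetic collinear
    genomes the identity projection applies); genuinely rearranged genomes
    need a precomputed table from a whole-genome aligner.
    """
    strains = tuple(sorted(gene_maps))
    # sweep over all genes sorted by start; union-find on reciprocal overlap
    items: list[tuple[str, GeneEntry]] = []
    for s in strains:
        genes = sorted(gene_maps[s], key=lambda g: (g.start, g.end))
        for g1, g2 in zip(genes, genes[1:]):
            if g2.start < g1.end:
                raise ValueError(
                    f"strain {s}: genes {g1.gene_id} and {g2.gene_id} overlap; "
                    "projection is not collinear -- supply a precomputed "
                    "ortholog table instead"
                )
        items.extend((s, g) for g in genes)
    items.sort(key=lambda t: (t[1].start, t[1].end))

    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    active: list[int] = []
    for i, (si, gi) in enumerate(items):
        active = [j for j in active if items[j][1].end > gi.start]
        for j in active:
            sj, gj = items[j]
            if sj != si and _reciprocal_overlap(gi, gj):
                union(i, j)
        active.append(i)

    clusters: dict[int, list[int]] = {}
    for i in range(len(items)):
        clusters.setdefault(find(i), []).append(i)

    groups = []
    ordered = sorted(clusters.values(), key=lambda idxs: items[idxs[0]][1].start)
    for gi, idxs in enumerate(ordered):
        entries: dict[str, GeneEntry] = {}
        for i in idxs:
            s, g = items[i]
            if s in entries:
                raise ValueError(
                    f"strain {s} contributes two genes ({entries[s].gene_id}, "
                    f"{g.gene_id}) to one positional group"
                )
            entries[s] = g
        groups.append(
            OrthologGroup(
                f"og{gi:05d}", tuple(entries.get(s) for s in strains)
            )
        )
    return OrthologTable(strains, groups)


def core_pan_curves(table: OrthologTable) -> pd.DataFrame:
    """Exact core/pan rarefaction over all strain subsets of each size.

    For k = 1..N, ``core(k)`` / ``pan(k)`` are means over all size-k
    subsets of the number of groups present in all / any of the k strains.
    A group present in m strains is in the core of C(m,k)/C(N,k) of the
    subsets and in the pan of 1 - C(N-m,k)/C(N,k).
    """
    n = table.n_strains
    if n < 1:
        raise ValueError("table has no strains")
    m_counts = np.array([g.n_present() for g in table.groups])
    rows = []
    for k in range(1, n + 1):
        denom = comb(n, k)
        core = sum(comb(int(m), k) for m in m_counts) / denom
        pan = sum(1 - comb(n - int(m), k) / denom for m in m_counts)
        rows.append({"k": k, "core": core, "pan": pan})
    return pd.DataFrame(rows)


def sharing_histogram(table: OrthologTable) -> pd.Series:
    """Group counts indexed by the number of genomes carrying the group;
    values sum to the total group count."""
    m = [g.n_present() for g in table.groups]
    counts = pd.Series(m).value_counts().sort_index()
    counts.index.name = "n_genomes"
    counts.name = "n_groups"
    return counts.reindex(range(1, table.n_strains + 1), fill_value=0)


def find_islands(
    table: OrthologTable,
    reference_strain: str,
    min_island_length: int = 10_000,
    min_specific_fraction: float = 0.5,
) -> list[IslandRegion]:
    """Scan the reference strain for genomic islands enriched in
    strain-specific genes.

    An island is a maximal run of consecutive reference genes, starting
    and ending on a reference-specific gene, whose strain-specific gene
    fraction is at least ``min_specific_fraction`` and whose span is at
    least ``min_island_length``.  Extension is greedy: the region absorbs
    the next specific gene to the right whenever the enlarged region still
    meets the fraction threshold.
    """
    genes = table.genes_for(reference_strain)
    specific = [g.n_present() == 1 for g, _ in genes]
    out: list[IslandRegion] = []
    i = 0
    n = len(genes)
    while i < n:
        if not specific[i]:
            i += 1
            continue
        # region currently [i..last]; try absorbing the next specific gene
        last = i
        n_spec = 1
        j = i + 1
        while j < n:
            # next specific gene at j2
            j2 = j
            while j2 < n and not specific[j2]:
                j2 += 1
            if j2 >= n:
                break
            cand_genes = j2 - i + 1
            cand_spec = n_spec + 1
            if cand_spec / cand_genes >= min_specific_fraction:
                last = j2
                n_spec = cand_spec
                j = j2 + 1
            else:
                break
        start = genes[i][1].start
        end = genes[last][1].end
        n_genes = last - i + 1
        if (end - start >= min_island_length
                and n_spec / n_genes >= min_specific_fraction):
            out.append(
                IslandRegion(
                    strain=reference_strain,
                    start=start,
                    end=end,
                    n_genes=n_genes,
                    n_specific=n_spec,
                )
            )
        i = last + 1
    return out


def conservation_gc_profile(
    table: OrthologTable,
    genome: np.ndarray,
    reference_strain: str,
    window_size: int = 50_000,
) -> ConservationProfile:
    """Windowed mean gene sharing and G+C along the reference chromosome.

    Non-overlapping windows are tiled from position 0; a gene contributes
    to the window containing its midpoint.  ``mean_sharing`` is the mean
    number of genomes carrying the window's genes (NaN when the window
    holds no gene midpoint); the final short window is retained and
    flagged.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    L = int(genome.size)
    genes = table.genes_for(reference_strain)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for g, e in genes:
        w = int(e.midpoint // window_size)
        sums[w] = sums.get(w, 0.0) + g.n_present()
        counts[w] = counts.get(w, 0) + 1
    windows = []
    for w in range(int(np.ceil(L / window_size))):
        start = w * window_size
        end = min(start + window_size, L)
        ms = sums[w] / counts[w] if counts.get(w) else float("nan")
        windows.append(
            ConservationWindow(
                start=start,
                end=end,
                mean_sharing=ms,
                gc=gc_fraction(genome[start:end]),
                short=(end - start) < window_size,
            )
        )
    return ConservationProfile(windows)
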