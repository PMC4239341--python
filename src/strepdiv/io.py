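"""Readers and writers for the formats the pipeline touches.

Conventions: coordinates are 0-based half-open in memory; GFF3, the SNP
matrix TSV and the ortholog table TSV are written 1-based inclusive (BED
output stays 0-based half-open).  Strains are ordered lexicographically
unless an explicit order is supplied.  Every writer/reader pair
round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    GeneEntry,
    GenomeSet,
    OrthologGroup,
    OrthologTable,
    PairedLocusAlignments,
    RecombTract,
    SnpMatrix,
    TruthSet,
    array_to_seq,
)

logger = logging.getLogger("strepdiv")


@dataclasses.dataclass
class RunConfig:
    """Tunable analysis parameters with their field-anchored defaults:
    50 kb windows, >5% divergence, 10 kb region gap, 20 kb maximum pair
    distance with 100 bp bins, 100 permutation replicates, 20 baseline
    shuffles, and the 10 kb / 50% island thresholds."""

    window_size: int = 50_000
    divergence_threshold: float = 0.05
    region_gap: int = 10_000
    max_pair_distance: int = 20_000
    bin_size: int = 100
    n_permutations: int = 100
    n_shuffles: int = 20
    min_island_length: int = 10_000
    min_specific_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("window_size", "region_gap", "max_pair_distance",
                     "bin_size", "n_permutations", "n_shuffles",
                     "min_island_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bin_size > self.max_pair_distance:
            raise ValueError("bin_size must not exceed max_pair_distance")
        for name in ("divergence_threshold", "min_specific_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def updated(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)


# ---------------------------------------------------------------------------
# genomes (FASTA)


def write_genomes(genomes: GenomeSet, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for strain, seq in genomes.items():
        p = out_dir / f"{strain}.fasta"
        SeqIO.write(
            [SeqRecord(Seq(array_to_seq(seq)), id=strain, description="")], p, "fasta"
        )
        paths.append(p)
    return paths


def read_genomes(paths: Sequence) -> GenomeSet:
    """One single-record FASTA per strain; the record id names the strain."""
    seqs = {}
    for p in paths:
        records = list(SeqIO.parse(str(p), "fasta"))
        if len(records) != 1:
            raise ValueError(f"{p}: expected exactly one record, found {len(records)}")
        rec = records[0]
        if rec.id in seqs:
            raise ValueError(f"duplicate strain {rec.id!r} in {p}")
        seqs[rec.id] = str(rec.seq)
    return GenomeSet({k: seqs[k] for k in sorted(seqs)})


# ---------------------------------------------------------------------------
# gene coordinates (GFF3, 1-based inclusive)


def write_gff3(table: OrthologTable, strain: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for group, e in table.genes_for(strain):
            attrs = f"ID={e.gene_id};ortholog_group={group.group_id}"
            fh.write(
                f"{strain}\tstrepdiv\tgene\t{e.start + 1}\t{e.end}\t.\t"
                f"{e.strand}\t.\t{attrs}\n"
            )


def read_gff3_genes(path) -> list[tuple[str, GeneEntry]]:
    """(ortholog_group or '', GeneEntry) per gene row, converted to 0-based."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            out.append(
                (
                    attrs.get("ortholog_group", ""),
                    GeneEntry(attrs["ID"], int(f[3]) - 1, int(f[4]), f[6]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# SNP matrix (TSV, 1-based; or minimal VCF)


def write_snp_matrix(matrix: SnpMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tref\t" + "\t".join(matrix.strains) + "\n")
        ref = matrix.ref.astype("U1")
        alleles = matrix.alleles.astype("U1")
        for i in range(matrix.n_sites):
            fh.write(
                f"{matrix.positions[i] + 1}\t{ref[i]}\t" + "\t".join(alleles[i]) + "\n"
            )


def _validated_matrix(positions, ref, alleles, strains, order) -> SnpMatrix:
    strains = list(strains)
    if order is not None:
        missing = set(order) - set(strains)
        if missing:
            raise ValueError(f"unknown strain column(s): {sorted(missing)}")
        idx = [strains.index(s) for s in order]
    else:
        order = sorted(strains)
        idx = [strains.index(s) for s in order]
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size:
        dup = np.flatnonzero(np.diff(positions) == 0)
        if dup.size:
            raise ValueError(f"duplicate position {positions[dup[0]] + 1}")
    srt = np.argsort(positions, kind="stable")
    m = SnpMatrix(
        positions[srt],
        np.asarray(ref, dtype="S1")[srt],
        np.asarray(alleles, dtype="S1")[srt][:, idx],
        order,
    )
    m.validate(one_based=True)
    return m


def read_snp_matrix(path, strain_order: Optional[Sequence[str]] = None) -> SnpMatrix:
    """Read a SNP matrix from the TSV schema or a minimal VCF.

    TSV columns: pos (1-based), ref, one allele column per strain.  VCF:
    biallelic SNP records with one sample per strain; a multiallelic
    record or a missing genotype raises, naming the position.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_vcf(path, strain_order)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["pos", "ref"]:
        raise ValueError(f"{path}: first two columns must be 'pos' and 'ref'")
    strains = list(df.columns[2:])
    positions = df["pos"].astype(np.int64).to_numpy() - 1
    ref = df["ref"].to_numpy(dtype="S1")
    alleles = df[strains].to_numpy(dtype="S1")
    try:
        return _validated_matrix(positions, ref, alleles, strains, strain_order)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def _read_vcf(path, strain_order) -> SnpMatrix:
    import pysam

    positions, ref, rows = [], [], []
    with pysam.VariantFile(str(path)) as vf:
        strains = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                raise ValueError(
                    f"{path}: record at position {rec.pos} is not a biallelic SNP"
                )
            bases = (rec.ref, alts[0])
            row = []
            for s in strains:
                gt = rec.samples[s].get("GT")
                if gt is None or len(gt) < 1 or gt[0] is None:
                    raise ValueError(f"{path}: missing call at position {rec.pos}")
                row.append(bases[gt[0]])
            positions.append(rec.pos - 1)
            ref.append(rec.ref)
            rows.append(row)
    alleles = np.array(rows, dtype="S1") if rows else np.empty((0, len(strains)), "S1")
    try:
        return _validated_matrix(positions, ref, alleles, strains, strain_order)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# ortholog table (TSV, entries gene_id:start-end:strand 1-based inclusive)


def write_ortholog_table(table: OrthologTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\t" + "\t".join(table.strains) + "\n")
        for g in table.groups:
            cells = []
            for e in g.entries:
                cells.append(
                    "." if e is None
                    else f"{e.gene_id}:{e.start + 1}-{e.end}:{e.strand}"
                )
            fh.write(g.group_id + "\t" + "\t".join(cells) + "\n")


def read_ortholog_table(path) -> OrthologTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "group_id":
            raise ValueError(f"{path}: first column must be 'group_id'")
        strains = header[1:]
        groups = []
        for ln, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(strains) + 1:
                raise ValueError(f"{path}:{ln}: wrong column count")
            entries = []
            for cell in cells[1:]:
                if cell == ".":
                    entries.append(None)
                    continue
                try:
                    gene_id, span, strand = cell.rsplit(":", 2)
                    s, e = span.split("-")
                    entries.append(GeneEntry(gene_id, int(s) - 1, int(e), strand))
                except Exception:
                    raise ValueError(f"{path}:{ln}: malformed entry {cell!r}") from None
            groups.append(OrthologGroup(cells[0], tuple(entries)))
    return OrthologTable(strains, groups)


# ---------------------------------------------------------------------------
# paired protein alignments (FASTA, <locus>_<partner>.faa)


def write_pair_alignments(pairs: Sequence[PairedLocusAlignments], out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pair in pairs:
        for partner, aln in (("A", pair.alignment_A), ("B", pair.alignment_B)):
            p = out_dir / f"{pair.locus_id}_{partner}.faa"
            SeqIO.write(
                [SeqRecord(Seq(s), id=name, description="") for name, s in aln.items()],
                p, "fasta",
            )
            paths.append(p)
    return paths


def read_pair_alignments(paths: Sequence) -> list[PairedLocusAlignments]:
    """Pair up ``<locus>_A.faa`` / ``<locus>_B.faa`` files by locus id."""
    by_locus: dict[str, dict[str, dict[str, str]]] = {}
    for p in paths:
        p = Path(p)
        stem = p.name.rsplit(".", 1)[0]
        if not (stem.endswith("_A") or stem.endswith("_B")):
            raise ValueError(f"{p}: alignment file must end in _A or _B")
        locus, partner = stem[:-2], stem[-1]
        aln = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(p), "fasta")}
        by_locus.setdefault(locus, {})[partner] = aln
    pairs = []
    for locus in sorted(by_locus):
        parts = by_locus[locus]
        if set(parts) != {"A", "B"}:
            raise ValueError(f"locus {locus}: missing partner file")
        pairs.append(PairedLocusAlignments(locus, parts["A"], parts["B"]))
    return pairs


# ---------------------------------------------------------------------------
# truth (JSON)


def _table_to_json(table: Optional[OrthologTable]):
    if table is None:
        return None
    return {
        "strains": list(table.strains),
        "groups": [
            {
                "group_id": g.group_id,
                "entries": [
                    None if e is None else [e.gene_id, e.start, e.end, e.strand]
                    for e in g.entries
                ],
            }
            for g in table.groups
        ],
    }


def _table_from_json(data) -> Optional[OrthologTable]:
    if data is None:
        return None
    groups = [
        OrthologGroup(
            g["group_id"],
            tuple(None if e is None else GeneEntry(*e) for e in g["entries"]),
        )
        for g in data["groups"]
    ]
    return OrthologTable(data["strains"], groups)


def write_truth(truth: TruthSet, path) -> None:
    data = {
        "genome_length": truth.genome_length,
        "true_ortholog_table": _table_to_json(truth.true_ortholog_table),
        "recomb_tracts": [
            [t.recipient, t.donor, t.start, t.end] for t in truth.recomb_tracts
        ],
        "islands": [list(i) for i in truth.islands],
        "suppressed_regions": [list(r) for r in truth.suppressed_regions],
        "pair_loci": [list(p) for p in truth.pair_loci],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_truth(path) -> TruthSet:
    with open(path) as fh:
        data = json.load(fh)
    return TruthSet(
        genome_length=data["genome_length"],
        true_ortholog_table=_table_from_json(data["true_ortholog_table"]),
        recomb_tracts=[RecombTract(*t) for t in data["recomb_tracts"]],
        islands=[tuple(i) for i in data["islands"]],
        suppressed_regions=[tuple(r) for r in data["suppressed_regions"]],
        pair_loci=[tuple(p) for p in data["pair_loci"]],
    )


# ---------------------------------------------------------------------------
# dataset layout


def write_dataset_files(dataset, out_dir) -> dict:
    """Write a simulated dataset under ``out_dir``:

    ``genomes/<strain>.fasta``, ``genes/<strain>.gff3``, ``snps.tsv``,
    ``orthologs.tsv``, ``pairs/<locus>_<partner>.faa`` and ``truth.json``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "genomes": [str(p) for p in write_genomes(dataset.genomes, out_dir / "genomes")],
        }
        (out_dir / "genes").mkdir(exist_ok=True)
        gffs = []
        for strain in dataset.ortholog_table.strains:
            p = out_dir / "genes" / f"{strain}.gff3"
            write_gff3(dataset.ortholog_table, strain, p)
            gffs.append(str(p))
        manifest["genes"] = gffs
        write_snp_matrix(dataset.snp_matrix, out_dir / "snps.tsv")
        write_ortholog_table(dataset.ortholog_table, out_dir / "orthologs.tsv")
        manifest["snps"] = str(out_dir / "snps.tsv")
        manifest["orthologs"] = str(out_dir / "orthologs.tsv")
        manifest["pairs"] = [
            str(p) for p in write_pair_alignments(dataset.pairs, out_dir / "pairs")
        ]
        write_truth(dataset.truth, out_dir / "truth.json")
        manifest["truth"] = str(out_dir / "truth.json")
    except OSError as exc:
        raise OSError(f"failed writing dataset under {out_dir}: {exc}") from exc
    return manifest


def read_dataset(in_dir):
    """Re-read a dataset written by :func:`write_dataset_files`."""
    from .simulate import SimulatedDataset

    in_dir = Path(in_dir)
    genomes = read_genomes(sorted((in_dir / "genomes").glob("*.fasta")))
    matrix = read_snp_matrix(in_dir / "snps.tsv")
    table = read_ortholog_table(in_dir / "orthologs.tsv")
    pairs = read_pair_alignments(sorted((in_dir / "pairs").glob("*.faa")))
    truth = read_truth(in_dir / "truth.json")
    return SimulatedDataset(None, genomes, matrix, table, pairs, truth)
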