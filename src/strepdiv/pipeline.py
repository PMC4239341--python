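"""End-to-end orchestration: content -> divergence -> recombination ->
coevolution, with TSV/BED/JSON outputs and per-stage seed logging."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import coevolution as coevo
from . import content, divergence, recombination
from .datatypes import GenomeSet, OrthologTable, SnpMatrix
from .io import RunConfig

logger = logging.getLogger("strepdiv")

STAGES = ("content", "divergence", "recombination", "coevolution")


def core_alignments_from_genomes(
    table: OrthologTable, genomes: GenomeSet
) -> dict[str, dict[str, str]]:
    """Per-core-group 'alignments' sliced from collinear genomes.

    Valid only for genomes aligned on a common coordinate frame (as the
    synthetic datasets are); each strain's slice at the group coordinates
    is already positionally aligned, so no aligner is needed.
    """
    out = {}
    for g in table.groups:
        if g.n_present() < table.n_strains:
            continue
        aln = {}
        for strain, e in zip(table.strains, g.entries):
            aln[strain] = genomes[strain][e.start:e.end].tobytes().decode()
        out[g.group_id] = aln
    return out


def core_mask(table: OrthologTable, genome_length: int) -> np.ndarray:
    """Boolean per-base mask of spans covered by core genes (the conserved
    regions over which SNP density is measured)."""
    mask = np.zeros(genome_length, dtype=bool)
    ref = table.strains[0]
    i = table.strain_index(ref)
    for g in table.groups:
        if g.n_present() == table.n_strains:
            e = g.entries[i]
            mask[e.start:e.end] = True
    return mask


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (logged so stages can be replayed)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def run_content_stage(
    table: OrthologTable,
    genomes: Optional[GenomeSet],
    config: RunConfig,
    reference_strain: Optional[str] = None,
) -> dict:
    ref = reference_strain or table.strains[0]
    curves = content.core_pan_curves(table)
    hist = content.sharing_histogram(table)
    islands = content.find_islands(
        table, ref, config.min_island_length, config.min_specific_fraction
    )
    profile = None
    if genomes is not None:
        profile = content.conservation_gc_profile(
            table, genomes[ref], ref, config.window_size
        )
    return {"curves": curves, "histogram": hist, "islands": islands,
            "profile": profile, "reference": ref}


def run_divergence_stage(
    table: OrthologTable,
    genomes: GenomeSet,
    matrix: SnpMatrix,
    config: RunConfig,
    reference_strain: Optional[str] = None,
) -> dict:
    ref = reference_strain or table.strains[0]
    alignments = core_alignments_from_genomes(table, genomes)
    records = divergence.core_gene_distances(table, alignments, ref)
    flagged_ids = divergence.flag_divergent_core_genes(
        table, alignments, ref, config.divergence_threshold
    )
    i = table.strain_index(ref)
    coords = {
        g.group_id: (g.entries[i].gene_id, g.entries[i].start, g.entries[i].end)
        for g in table.groups
        if g.entries[i] is not None
    }
    flagged = [coords[gid] for gid in flagged_ids]
    regions = divergence.group_divergent_regions(flagged, config.region_gap)
    mask = core_mask(table, genomes.length)
    dens = divergence.snp_density_windows(
        matrix, genomes.length, config.window_size, conserved_mask=mask
    )
    return {
        "distances": records,
        "flagged": flagged_ids,
        "regions": regions,
        "region_summary": divergence.summarize_regions(regions),
        "densities": dens,
        "density_summary": divergence.density_summary(dens) if len(dens) else None,
    }


def run_recombination_stage(matrix: SnpMatrix, config: RunConfig) -> dict:
    seed = stage_seed(config.seed, "recombination")
    logger.info("recombination stage sub-seed: %d", seed)
    sites = recombination.call_informative_sites(matrix)
    counts = recombination.pairwise_informative_counts(matrix)
    c_rand = recombination.shuffled_baseline(
        sites, config.n_shuffles, seed, config.max_pair_distance
    )
    curve = recombination.phylogenetic_signal_curve(
        sites, config.max_pair_distance, config.bin_size, baseline=c_rand
    )
    fit = recombination.fit_exponential_decay(curve)
    try:
        spacing = {
            "adjacent": recombination.mean_incompatible_distance(sites, "adjacent"),
            "hudson_kaplan": recombination.mean_incompatible_distance(
                sites, "hudson_kaplan", config.max_pair_distance
            ),
        }
    except ValueError:
        spacing = None
    regions = recombination.find_compatible_regions(
        sites, config.max_pair_distance, min_length=0
    )
    regions = recombination.permutation_test_regions(
        regions, sites, fit, c_rand, config.n_permutations, seed,
        config.max_pair_distance,
    )
    return {
        "sites": sites,
        "pairwise_counts": counts,
        "c_rand": c_rand,
        "curve": curve,
        "fit": fit,
        "spacing": spacing,
        "regions": regions,
        "sub_seed": seed,
    }


def run_coevolution_stage(pairs, config: RunConfig) -> dict:
    result = coevo.coevolution_test(pairs)
    return {"result": result}


def _write_regions_bed(regions, path, name_prefix: str, chrom: str = "genome"):
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            score = getattr(r, "p_value", None)
            fh.write(
                f"{chrom}\t{r.start}\t{r.end}\t{name_prefix}{i}"
                + (f"\t{score:.5g}" if score is not None and score == score else "")
                + "\n"
            )


def run_pipeline(
    run_config: RunConfig,
    dataset,
    out_dir,
    stages: Optional[Sequence[str]] = None,
) -> dict:
    """Execute the requested stages on a dataset bundle and write results.

    ``dataset`` needs ``ortholog_table``, ``genomes``, ``snp_matrix`` and
    ``pairs`` attributes (a :class:`~strepdiv.simulate.SimulatedDataset`
    or the object returned by :func:`strepdiv.io.read_dataset`).  A stage
    failure aborts with the stage name.  Returns a JSON-serialisable
    summary that is also written to ``summary.json``.
    """
    stages = tuple(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": run_config.__dict__.copy(), "stages": {}}
    logger.info("pipeline parameters: %s", summary["parameters"])

    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            if stage == "content":
                res = run_content_stage(dataset.ortholog_table, dataset.genomes,
                                        run_config)
                res["curves"].to_csv(out_dir / "core_pan.tsv", sep="\t", index=False)
                res["histogram"].to_csv(out_dir / "sharing_hist.tsv", sep="\t")
                _write_regions_bed(res["islands"], out_dir / "islands.bed", "island",
                                   chrom=res["reference"])
                pd.DataFrame(
                    [
                        {"strain": r.strain, "start": r.start, "end": r.end,
                         "n_genes": r.n_genes, "n_specific": r.n_specific,
                         "specific_fraction": r.specific_fraction}
                        for r in res["islands"]
                    ]
                ).to_csv(out_dir / "islands.tsv", sep="\t", index=False)
                if res["profile"] is not None:
                    res["profile"].to_frame().to_csv(
                        out_dir / "conservation_profile.tsv", sep="\t", index=False
                    )
                summary["stages"]["content"] = {
                    "n_groups": len(dataset.ortholog_table),
                    "core_size": float(res["curves"]["core"].iloc[-1]),
                    "pan_size": float(res["curves"]["pan"].iloc[-1]),
                    "n_islands": len(res["islands"]),
                }
            elif stage == "divergence":
                res = run_divergence_stage(
                    dataset.ortholog_table, dataset.genomes, dataset.snp_matrix,
                    run_config,
                )
                pd.DataFrame(
                    [
                        {"group_id": r.group_id, "strain": r.strain_a,
                         "reference": r.strain_b, "distance": r.distance,
                         "model": r.model}
                        for r in res["distances"]
                    ]
                ).to_csv(out_dir / "gene_distances.tsv", sep="\t", index=False)
                pd.Series(res["flagged"], name="group_id").to_csv(
                    out_dir / "divergent_genes.tsv", sep="\t", index=False
                )
                _write_regions_bed(res["regions"], out_dir / "divergent_regions.bed",
                                   "divreg")
                res["densities"].to_csv(out_dir / "snp_density.tsv", sep="\t",
                                        index=False)
                summary["stages"]["divergence"] = {
                    "n_flagged": len(res["flagged"]),
                    "region_summary": res["region_summary"],
                    "density_summary": res["density_summary"],
                }
            elif stage == "recombination":
                res = run_recombination_stage(dataset.snp_matrix, run_config)
                pd.DataFrame(
                    [
                        {"position": s.position,
                         "minority_set": ",".join(sorted(s.minority_set))}
                        for s in res["sites"]
                    ]
                ).to_csv(out_dir / "informative_sites.tsv", sep="\t", index=False)
                res["pairwise_counts"].to_csv(out_dir / "pairwise_counts.tsv", sep="\t")
                res["curve"].to_frame().to_csv(out_dir / "decay_curve.tsv", sep="\t",
                                               index=False)
                with open(out_dir / "decay_fit.json", "w") as fh:
                    json.dump({"b": res["fit"].b, "sse": res["fit"].sse,
                               "c_rand": res["c_rand"]}, fh)
                _write_regions_bed(res["regions"], out_dir / "compatible_regions.bed",
                                   "region")
                pd.DataFrame(
                    [
                        {"start": r.start, "end": r.end, "length": r.length,
                         "n_sites": r.n_sites, "p_value": r.p_value}
                        for r in res["regions"]
                    ]
                ).to_csv(out_dir / "compatible_regions.tsv", sep="\t", index=False)
                summary["stages"]["recombination"] = {
                    "n_informative": len(res["sites"]),
                    "c_rand": res["c_rand"],
                    "b": res["fit"].b,
                    "spacing": res["spacing"],
                    "n_regions": len(res["regions"]),
                    "sub_seed": res["sub_seed"],
                }
            elif stage == "coevolution":
                res = run_coevolution_stage(dataset.pairs, run_config)
                r = res["result"]
                pd.DataFrame(
                    {"locus": list(r.locus_ids), "proportion_A": r.proportions_A,
                     "proportion_B": r.proportions_B}
                ).to_csv(out_dir / "pair_proportions.tsv", sep="\t", index=False)
                with open(out_dir / "coevolution.json", "w") as fh:
                    json.dump({"rho": r.rho, "p_value": r.p_value, "n": r.n}, fh)
                summary["stages"]["coevolution"] = {
                    "rho": r.rho, "p_value": r.p_value, "n": r.n,
                }
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary
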