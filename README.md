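# strepdiv

Intraspecies comparative genomics for small sets of closely related,
collinear bacterial genomes — built around the situation found in
*Streptomyces pratensis*, where five conspecific isolates from disparate
locations share almost all of their gene content yet carry chromosomes that
are mosaics of homologous recombination.

The package answers four questions a population genomicist asks of such a
sample:

1. **Gene content.** How large are the core and pan genomes, how are genes
   shared, and where are the strain-specific genomic islands?
   (`strepdiv.content`)
2. **Sequence divergence.** Which core genes are unusually divergent, how do
   they cluster along the chromosome, and what is the windowed SNP density?
   (`strepdiv.divergence`)
3. **Recombination.** How far along the chromosome does one polymorphism
   predict the ancestry supported by another, and which regions are
   anomalously free of recombination? (`strepdiv.recombination`)
4. **Co-evolution.** Do co-localized gene pairs (a BldB/Hpb-like putative
   toxin–antitoxin family) diversify in step? (`strepdiv.coevolution`)

A synthetic-data generator (`strepdiv.simulate`) produces five-genome
datasets with recorded ground truth — clonal descent under infinite-sites
mutation, gene-conversion tracts, engineered recombination-free regions,
strain-specific islands and co-evolving gene pairs — so the entire pipeline
is testable without downloading genomes.

## The statistic at the core

For `N = 5` genomes, an *informative site* is a biallelic SNP whose minor
allele is carried by exactly two strains, so it supports a bipartition of
the sample. Two informative sites are *compatible* when fewer than four of
the haplotype classes `{00, 01, 10, 11}` occur — the four-gamete test; for
2-of-5 minority sets this reduces to "equal or disjoint". Under clonal
descent with infinite-sites mutation every pair is compatible;
recombination creates incompatibilities.

Every unordered pair of informative sites within 20 kb is binned by
distance (100-bp bins); with `c(x)` the compatible fraction at distance `x`
and `c_rand` the fraction after shuffling allele patterns across positions,
the **phylogenetic signal** is

    y(x) = (c(x) − c_rand) / (1 − c_rand),

which is 1 under pure vertical inheritance and 0 when incompatible sites are
randomly distributed. Its decay is summarised by least squares as
`y = e^(−b·x)`. Extended runs of consecutive informative sites free of
close-range incompatibility are tested against a null that redraws each
pair's compatibility as Bernoulli with probability
`c_rand + (1 − c_rand)·e^(−b·d)` across 20-kb tracts centred on every
informative site (100 replicates per tract, pooled; add-one-corrected
p-value).

The co-evolution test takes per-locus protein alignments of the two partner
families, computes each partner's proportion of variable columns, and
reports Spearman's ρ with a two-sided p from
`t = ρ·sqrt((n−2)/(1−ρ²))` on `n − 2` degrees of freedom.

## Worked example

Simulate a desk-scale (2 Mb) study-like dataset and run every stage:

```bash
strepdiv simulate --genome-length 2000000 --seed 7 --out-dir demo/dataset
strepdiv run-all --dataset demo/dataset --out-dir demo/results --seed 7
```

The first command writes per-strain FASTA and GFF3, a SNP matrix TSV, an
ortholog table TSV, per-locus protein alignments and `truth.json`
(12,871 SNPs, 1,853 ortholog groups). The second writes TSV/BED/JSON
results; `demo/results/summary.json` contains, for this seed:

```
content:        core_size 1538.0 of 1853 groups, 3 islands detected
divergence:     median windowed SNP density 0.0081 (sd 0.0013)
recombination:  5045 informative sites, c_rand 0.430, b 2.02e-4 /bp,
                mean adjacent incompatible spacing 1095 bp
coevolution:    rho 0.593, p 0.0199, n 15
```

Reading the numbers: the fitted decay coefficient `b ≈ 2.0e-4 /bp` means
the phylogenetic signal falls to `1/e` within ~5 kb — a site's supported
ancestry says nothing about a site 15–20 kb away, the mosaic-chromosome
regime. `c_rand ≈ 0.43` sits near the 0.4 expected when all ten strain-pair
patterns are used evenly, i.e. recombination has erased the clonal tree.
The engineered recombination-suppressed region planted at 0.4 of the
chromosome surfaces in `compatible_regions.tsv` as a ~22 kb run with
permutation p ≈ 2e-6. The co-evolution test recovers a significant positive
rank correlation between partner variabilities at the fifteen paired loci.

Each subcommand (`core-pan`, `islands`, `divergence`, `recomb-signal`,
`linkage-regions`, `coevolution`) runs its stage alone; `--config` takes a
YAML file overriding the defaults and flags override the config file.

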