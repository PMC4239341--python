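# Methods

This note documents the models implemented in `strepdiv`, the design
choices made where the problem left the design open, what the synthetic
data emulate, and the limits of what the tests show.

## Coordinates, containers, conventions

All in-memory coordinates are 0-based, half-open. GFF3, the SNP-matrix TSV
and the ortholog-table TSV are written 1-based inclusive per those formats'
conventions; BED stays 0-based half-open. Strains are ordered
lexicographically unless an explicit order is passed. The SNP matrix
(`SnpMatrix`) requires strictly increasing positions, exactly two alleles
per site across strains, and no missing calls: positions not confidently
called in every strain must be excluded at ingest, since every downstream
statistic assumes a complete biallelic column. Multiallelic or missing
records are rejected with the offending (1-based) position named.

## Gene content

Positional orthology groups genes that occupy the same location in a
common coordinate frame: genes from different strains join one group iff
their projected intervals reciprocally overlap by ≥ 50%. This is
implemented for collinear genomes only (the generator's output); genuinely
rearranged genomes need a precomputed table from a whole-genome aligner,
and the builder refuses non-collinear input rather than guessing.

Core/pan rarefaction curves are exact: a group present in `m` of `N`
strains is in the core of `C(m,k)/C(N,k)` of all size-`k` subsets and in
the pan of `1 − C(N−m,k)/C(N,k)`, so the mean over subsets has a closed
form. No ordering sampling is involved; a subset-enumeration oracle checks
the closed form in the tests for `N ≤ 6`.

Island detection scans the reference strain's genes in positional order.
A candidate region starts and ends on a reference-specific gene
(present in no other strain) and is extended greedily: the next specific
gene to the right is absorbed whenever the enlarged region still meets the
minimum specific-gene fraction (default 0.5). Regions spanning less than
the minimum length (default 10 kb) are dropped. Island boundaries are the
outermost specific genes' span; intergenic flanks are not annexed, and the
reported spans follow that convention.

The conservation profile tiles non-overlapping windows (default 50 kb)
from position 0; a gene contributes to the window containing its midpoint,
which avoids double counting. Windows without gene midpoints report NaN
sharing; the final short window is kept and flagged. G+C is computed over
the window's nucleotides of the reference sequence.

## Divergence

Gene distances default to the p-distance with pairwise deletion (columns
holding a gap in either sequence are excluded); the Jukes–Cantor
correction `−(3/4)·ln(1 − 4p/3)` is available and raises for `p ≥ 0.75`.
At the < 5% divergences this module deals in, model choice is immaterial
(JC at p = 0.05 is 0.0517) and the plain mismatch fraction keeps the
flagging threshold transparent; richer models (e.g. F84) would need
base-frequency and transition/transversion machinery without changing any
decision made here.

A core gene is flagged as divergent when its **maximum** distance from any
non-reference strain to the reference strictly exceeds the threshold
("more than 5%" is read as a strict inequality). Max was chosen over mean
because a single highly divergent ortholog is the biological signal of
interest; the choice is logged in the distance output so either reading
can be recomputed. Flagged genes chain into regions by single linkage with
a 10-kb gap; chaining is order-invariant by construction (genes are sorted
before chaining).

Windowed SNP density is SNP count over masked-in (core-gene) bases per
50-kb window, windows with no masked bases dropped; the summary pairs the
median with the standard deviation, the customary pairing for this
statistic in the field's intraspecies comparisons.

## Recombination statistics

**Informative sites.** A site is informative when its minor allele class
has between 2 and N−2 members (for N = 5, exactly 2). An exact tie (even N
only) breaks toward the non-reference class, deterministically.

**Four-gamete test.** Sites are stored as minority bitmasks; a pair is
incompatible iff the two sets intersect, each has a private member, and
their union is not the whole strain set — equivalent to all four haplotype
classes being observed. For 2-of-5 sets this is "equal or disjoint". The
closed form is verified against brute-force haplotype enumeration on all
100 ordered pattern pairs.

**Signal curve.** Each unordered pair within 20 kb counts once (the
symmetric double-count would change no fraction); distance `d` maps to bin
`⌈d/100⌉` and `d = 0` cannot occur because positions are strictly
increasing. The normalisation `y = (c − c_rand)/(1 − c_rand)` is the
unique affine map sending the clonal anchor (`c = 1`) to 1 and the random
anchor (`c = c_rand`) to 0; the raw `c` is always co-reported. `c_rand`
comes from permuting the minority patterns across the fixed positions
(default 20 shuffles, pooled), which preserves per-pattern counts exactly.
With uniform 2-of-5 patterns the analytic baseline is 0.4 (40 of the 100
ordered pattern pairs are equal-or-disjoint), which the shuffled estimate
reproduces. If every site carries one pattern, `c_rand = 1` and the
normalisation is undefined: the curve constructor raises rather than
dividing by zero — purely clonal data have no random anchor.

**Exponential fit.** `y = e^(−b·x)` with the intercept fixed at 1, the
asymptote at 0, and `b ≥ 0`, by unweighted least squares over occupied
bins (trust-region, initialised from a log-linear slope; tight `xtol`
so a noiseless curve round-trips to 1e-6 relative). A pair-count-weighted
variant is available behind a flag; it changes the study-regime fit by
less than the seed-to-seed spread.

**Incompatible-site spacing.** Two estimators are reported side by side,
since the measurement underlying a single "mean distance between
incompatible sites" is ambiguous: (i) the mean distance over consecutive
informative-site pairs that are incompatible, and (ii) the informative-site
span divided by the size of the minimal set of non-overlapping incompatible
intervals (Hudson–Kaplan interval pruning, greedy-by-right-endpoint, which
an exact recursion verifies in the tests). Neither is asserted to be the
other's equal; in the calibrated study regime the adjacent-pair estimator
sits near 1.1 kb.

**Compatible regions.** Maximal runs of consecutive informative sites in
which every within-run pair closer than 20 kb is compatible, found by a
sliding scan whose left edge advances past the latest offending
predecessor. Region span is measured site-to-site with no flank
extrapolation, so a detected span slightly undershoots the generating
tract.

**Permutation test.** For each informative site the tract of sites within
± 10 kb is taken; per replicate every within-tract pair's compatibility is
drawn independently as Bernoulli with success probability
`c_rand + (1 − c_rand)·e^(−b·d)`; the replicate's maximal compatible-run
span is recorded, spans are pooled over all tracts × replicates (default
100), and a region's p-value is `(k + 1)/(M + 1)` where `k` counts pooled
null spans at least as long. Drawing pair compatibilities independently
ignores the transitivity structure among sites and the spatial correlation
of real compatibility; it is a fidelity choice — the null is the stated
"random draws from the exponential decay" — not a statistical ideal. The
consequence, visible in heavily recombining simulations, is that the null
understates how long compatible runs can get by chance correlation, so
several background regions can reach nominal significance alongside an
engineered one; the engineered region is still recovered as a dominant,
maximally significant span. Calibration under shuffle-equilibrium data
(no spatial structure, where the independence assumption is close to true)
gives approximately uniform p-values for the longest observed region, with
the ≤ 5% tail at its nominal size.

## Co-evolution

A column of a protein alignment is variable when ≥ 2 distinct non-gap
residues occur (default `missing` gap policy); the `state` policy instead
treats the gap as a 21st residue. The denominator is always the total
column count, so gap columns dilute but never create variability under the
default. Spearman's ρ uses average ranks for ties; the two-sided p-value
uses `t = ρ·sqrt((n−2)/(1−ρ²))` on `n − 2` df, which reproduces the
reference value p = 0.01605 at ρ = 0.609, n = 15, and is cross-checked
against an exact permutation option (and against `scipy.stats.spearmanr`)
in the tests. With n = 15 loci the t approximation and the permutation
p agree to well within Monte-Carlo error. The default locus count is 15;
a duplicated partner at one locus can be included as a 16th point in an
optional mode, reflecting the two ways such a plot can be drawn. The
pairing census joins partner-A and partner-B loci within a 2-kb adjacency
window and reports unpaired loci and duplications.

## The synthetic-data generator

The generator emulates the structure of a five-strain intraspecies sample
of a large, GC-rich, linear-chromosome actinomycete:

- **Scale and composition:** default 7.5 Mb per strain at G+C 0.71.
- **Mutation:** one ancestor evolved along a fixed, balanced rooted tree
  (`((S1,S2),(S3,S4),S5)`) with total length 0.009 substitutions/site, so
  a 1 Mb genome carries ~9,000 SNPs — matching a windowed SNP density of
  ~0.009. Infinite sites is the default: every variant position mutates
  exactly once, so four-gamete violations can come only from
  recombination, which isolates exactly the signal the statistic measures.
  A finite-sites Jukes–Cantor mode exists for studying homoplasy;
  multi-hit (non-biallelic) columns are dropped from its matrix. The
  generator refuses infinite-sites runs whose expected mutation count
  exceeds the genome length instead of silently recycling positions.
- **Tree choice:** most branch length (5/6) is terminal, so most SNPs are
  singletons and the clonal informative patterns are confined to the two
  true clades — a sample with little resolvable intraspecies structure.
  Per-branch rate variation is not modelled.
- **Recombination:** per strain, Poisson-many gene-conversion tracts
  (donors uniform among the other strains, applied sequentially so later
  tracts can copy earlier mosaic), geometric lengths. Tracts never
  initiate inside a configured suppressed region and are truncated at its
  boundary: suppression is mechanical, reproducing the observable (no
  incompatibilities) without asserting a cause. Columns homogenised by
  conversion are dropped from the matrix.
- **Gene content:** a deterministic gene grid (1 kb genes, 100 bp
  spacers), each slot core with probability 0.859 else specific to one
  uniform strain — adequate for positional logic, with no operon realism.
  Islands replace the target strain's slots over a chosen span with
  strain-specific genes laid out to span the island exactly.
- **Co-evolving pairs:** a per-locus latent variability drawn through a
  Gaussian copula with correlation equal to the `coupling` parameter
  drives both partners' variable-column counts (Binomial around
  `latent × 0.35` of columns; a noise-free mode rounds the expectation).
  Defaults: 15 loci, partner lengths 76 and 274 columns, coupling 0.61 —
  the observed end-to-end rank correlation.
- **Determinism:** every stage draws from a sub-generator derived from the
  master seed by a fixed spawn key, so identical configurations produce
  byte-identical datasets and any stage can be replayed from its logged
  sub-seed.

What the generator does **not** emulate: rearrangements and inversions,
plasmids, read-level noise or assembly artifacts, selection, operon
structure, donor population structure, or per-branch rate variation.
Passing tests therefore demonstrate the correctness and calibration of the
statistics on an idealised collinear mosaic genome, not robustness to
assembly error or structural variation in real data.

## Calibration

The study regime is frozen at **100 gene-conversion tracts per strain per
Mb with a 5 kb mean tract length**. Three structural targets guided the
choice, all checked before the defaults were fixed:

- the fitted decay coefficient lands near the reference value 2.07e-4/bp
  at desk scale (measured 1.9–2.5e-4 across seeds at 2 Mb);
- informative SNPs use all ten strain-pair patterns at comparable
  frequencies, putting the shuffled baseline near 0.42;
- the mean adjacent incompatible-site spacing sits near 1.1 kb.

A finding worth recording: under a gene-conversion overlay with geometric
tract lengths, the normalised signal is approximately
`y(d) ≈ 1 − E[min(T, d)]/E[T] = e^(−d/m)` for mean tract length `m`, so
the fitted decay coefficient measures the **tract length** (`b ≈ 1/m`),
not the tract count. The tract count mainly sets how far `c_rand` falls
below 1 (how thoroughly the clonal pattern pool is randomised); the
numerator and denominator of the normalisation both scale linearly with
rate at low-to-moderate rates and cancel. Only in the saturated mosaic
regime, where overlapping tracts shorten the visible donor blocks, does
`b` creep upward with tract count, by roughly 20–30% between 50 and
800 tracts/strain/Mb with substantial seed-to-seed spread. The trend test
in the acceptance suite therefore compares seed-paired means across that
high-rate grid, and the b-vs-rate relationship should be read as weak by
the statistic's construction; the strong monotone response to
recombination intensity appears instead in the incompatible-pair fraction,
which is tested separately. Read the other way, this gives the decay
coefficient a concrete interpretation for real data: `b = 2.07e-4`/bp
corresponds to conversion tracts averaging ~5 kb.

## Problem sizes

The test and benchmark runs use 0.3–2 Mb chromosomes: 1 Mb (~10⁴ SNPs)
for the clonal anchor, ≥ 5,000–10,000 sites for the random anchor, and
2 Mb for the engineered-region study, which preserves every density the
statistics depend on (SNPs/bp, informative sites/bp, tracts/bp) at a size
a laptop reruns in seconds. The full 7.5 Mb configuration runs the same
code paths unchanged.

## Known limitations

- The independence assumption of the permutation null (discussed above)
  makes background long-run p-values anti-conservative in strongly
  spatially-correlated data; region p-values are best interpreted for the
  top-ranked spans.
- The signal normalisation is undefined for perfectly clonal data
  (`c_rand = 1`); callers must handle the raised error, and the raw
  compatible fraction (identically 1 there) is the meaningful report.
- Positional orthology and the core alignments sliced from collinear
  genomes assume no rearrangement; real draft genomes need an external
  aligner's ortholog table and per-gene alignments.
- Island spans are gene-span based; conventions that annex intergenic
  flanks will report systematically longer islands.
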