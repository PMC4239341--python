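"""Four-gamete recombination statistics over a biallelic SNP matrix.

The central quantity is the distance-binned "phylogenetic signal": for
every unordered pair of informative sites within ``max_pair_distance`` of
each other, the four-gamete test classifies the pair as compatible with a
single bifurcating genealogy or not; the compatible fraction per 100-bp
distance bin, normalised against a shuffled baseline so that clonal
inheritance maps to 1 and random assortment to 0, decays approximately as
``y = exp(-b*x)`` in a recombining population.  Regions unusually free of
incompatibilities (extended linkage) are detected and assigned a
permutation p-value under a null that redraws pair compatibilities from
the fitted decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datatypes import SnpMatrix


@dataclass(frozen=True)
class InformativeSite:
    """A SNP whose minor allele is carried by >= 2 strains (non-singleton),
    so it supports a bipartition of the strain set."""

    position: int
    minority_set: frozenset
    strains: tuple

    def __post_init__(self):
        k = len(self.minority_set)
        n = len(self.strains)
        if not 2 <= k <= n - 2:
            raise ValueError(
                f"informative site at {self.position}: minority set of size {k} "
                f"invalid for {n} strains"
            )


@dataclass
class DecayCurve:
    """Binned compatibility vs inter-site distance.

    ``bin_mid`` holds midpoints of the 100-bp (by default) distance bins
    spanning (0, max_pair_distance]; ``c`` is the raw compatible fraction
    and ``y`` the normalised signal ``(c - c_rand) / (1 - c_rand)``.  Bins
    with no pairs carry NaN in ``c`` and ``y``.
    """

    bin_mid: np.ndarray
    n_pairs: np.ndarray
    c: np.ndarray
    c_rand: float
    y: np.ndarray

    def occupied(self) -> np.ndarray:
        return self.n_pairs > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_mid": self.bin_mid, "n_pairs": self.n_pairs, "c": self.c, "y": self.y}
        )


@dataclass
class DecayFit:
    """Least-squares exponential decay ``y = exp(-b*x)``; intercept fixed at
    1, asymptote at 0, ``b >= 0`` in 1/bp."""

    b: float
    sse: float


@dataclass
class CompatibleRegion:
    """A maximal run of informative sites free of close-range
    incompatibilities, with its permutation p-value."""

    start: int
    end: int
    length: int
    n_sites: int
    p_value: float = float("nan")


# ---------------------------------------------------------------------------
# informative sites and the four-gamete test


def call_informative_sites(matrix: SnpMatrix) -> list[InformativeSite]:
    """Extract non-singleton sites; order preserved.

    The minority set is the smaller allele class; an exact tie (possible
    only for an even strain count) is broken toward the non-reference
    class.  Raises if a site is not biallelic.
    """
    n = matrix.n_strains
    sites: list[InformativeSite] = []
    for i in range(matrix.n_sites):
        row = matrix.alleles[i]
        uniq = sorted(set(row))
        if len(uniq) != 2:
            raise ValueError(
                f"site at position {matrix.positions[i]} is not biallelic"
            )
        a0 = row[0]
        alt_mask = row != a0
        k_alt = int(alt_mask.sum())
        if k_alt * 2 <= n:
            members = alt_mask
        else:
            members = ~alt_mask
        k = int(members.sum())
        if 2 <= k <= n - 2:
            sites.append(
                InformativeSite(
                    position=int(matrix.positions[i]),
                    minority_set=frozenset(
                        s for s, m in zip(matrix.strains, members) if m
                    ),
                    strains=matrix.strains,
                )
            )
    return sites


def _site_arrays(sites: Sequence[InformativeSite]) -> tuple[np.ndarray, np.ndarray, int]:
    """Positions, minority bitmasks, and the full-universe bitmask."""
    if not sites:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64), 0
    strains = sites[0].strains
    idx = {s: i for i, s in enumerate(strains)}
    positions = np.empty(len(sites), dtype=np.int64)
    masks = np.empty(len(sites), dtype=np.uint64)
    for i, s in enumerate(sites):
        if s.strains != strains:
            raise ValueError("informative sites carry mismatched strain sets")
        positions[i] = s.position
        m = 0
        for name in s.minority_set:
            m |= 1 << idx[name]
        masks[i] = m
    universe = (1 << len(strains)) - 1
    return positions, masks, universe


def _compatible_masks(a: np.ndarray, b: np.ndarray, universe: int) -> np.ndarray:
    """Vectorised four-gamete test on minority bitmasks.

    A pair is incompatible iff all four haplotype classes occur, i.e. the
    sets intersect, each has a private member, and their union is not the
    whole strain set.
    """
    U = np.uint64(universe)
    both = (a & b) != 0
    only_a = (a & ~b & U) != 0
    only_b = (b & ~a & U) != 0
    neither = (U & ~(a | b)) != 0
    return ~(both & only_a & only_b & neither)


def four_gamete_compatible(a: InformativeSite, b: InformativeSite) -> bool:
    """Four-gamete test between two informative sites.

    True iff fewer than four of the haplotype classes {00,01,10,11} occur
    across the strains.  For five strains with 2-strain minority sets this
    reduces to: compatible iff the two sets are equal or disjoint.
    """
    if a.strains != b.strains:
        raise ValueError("sites have mismatched strain sets")
    pa, ma, universe = _site_arrays([a])
    _, mb, _ = _site_arrays([b])
    return bool(_compatible_masks(ma, mb, universe)[0])


def pairwise_informative_counts(matrix: SnpMatrix) -> pd.DataFrame:
    """Strain-pair table of informative SNPs: cell (i, j) counts sites whose
    minority set is exactly {i, j}.  For five strains the cells sum to the
    total informative-site count."""
    sites = call_informative_sites(matrix)
    strains = matrix.strains
    counts = pd.DataFrame(0, index=list(strains), columns=list(strains))
    for s in sites:
        if len(s.minority_set) == 2:
            i, j = sorted(s.minority_set)
            counts.loc[i, j] += 1
            counts.loc[j, i] += 1
    return counts


# ---------------------------------------------------------------------------
# pair scan, baseline, decay curve and fit


def _pair_index(positions: np.ndarray, max_pair_distance: int) -> tuple[np.ndarray, np.ndarray]:
    """Unordered site pairs (i < j) with pos[j] - pos[i] <= max_pair_distance."""
    n = positions.size
    if n < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ends = np.searchsorted(positions, positions + max_pair_distance, side="right")
    ar = np.arange(n, dtype=np.int64)
    counts = ends - ar - 1
    total = int(counts.sum())
    i_idx = np.repeat(ar, counts)
    offs = np.repeat(np.cumsum(counts) - counts, counts)
    j_idx = np.arange(total, dtype=np.int64) - offs + i_idx + 1
    return i_idx, j_idx


def shuffled_baseline(
    sites: Sequence[InformativeSite],
    n_shuffles: int,
    seed: int,
    max_pair_distance: int = 20_000,
) -> float:
    """Random-assortment compatibility baseline ``c_rand``.

    Minority-set patterns are permuted across the fixed site positions
    ``n_shuffles`` times and the compatible fraction among all pairs within
    ``max_pair_distance`` is pooled.  Per-pattern counts are preserved
    exactly by construction.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if len(sites) < 2:
        raise ValueError("need at least two informative sites")
    positions, masks, universe = _site_arrays(sites)
    i_idx, j_idx = _pair_index(positions, max_pair_distance)
    if i_idx.size == 0:
        raise ValueError("no site pairs within max_pair_distance")
    rng = np.random.default_rng(seed)
    n_compat = 0
    n_total = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(masks)
        compat = _compatible_masks(perm[i_idx], perm[j_idx], universe)
        n_compat += int(compat.sum())
        n_total += compat.size
    return n_compat / n_total


def shuffled_signal_curve(
    sites: Sequence[InformativeSite],
    n_shuffles: int,
    seed: int,
    max_pair_distance: int = 20_000,
    bin_size: int = 100,
) -> DecayCurve:
    """Per-bin signal of the shuffled (random-assortment) ensemble.

    Pools pair compatibilities over ``n_shuffles`` pattern permutations per
    distance bin and normalises by the pooled overall compatible fraction;
    the resulting ``y`` sits at 0 in every bin up to sampling noise, which
    the pooling suppresses by a factor ``sqrt(n_shuffles)``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    positions, masks, universe = _site_arrays(sites)
    i_idx, j_idx = _pair_index(positions, max_pair_distance)
    if i_idx.size == 0:
        raise ValueError("no site pairs within max_pair_distance")
    n_bins = int(np.ceil(max_pair_distance / bin_size))
    bins = (positions[j_idx] - positions[i_idx] - 1) // bin_size
    rng = np.random.default_rng(seed)
    n_pairs = np.zeros(n_bins, dtype=np.int64)
    n_comp = np.zeros(n_bins, dtype=float)
    for _ in range(n_shuffles):
        perm = rng.permutation(masks)
        compat = _compatible_masks(perm[i_idx], perm[j_idx], universe)
        n_pairs += np.bincount(bins, minlength=n_bins)
        n_comp += np.bincount(bins, weights=compat.astype(float), minlength=n_bins)
    c_rand = float(n_comp.sum() / n_pairs.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(n_pairs > 0, n_comp / np.maximum(n_pairs, 1), np.nan)
    y = (c - c_rand) / (1.0 - c_rand)
    mids = (np.arange(n_bins) + 0.5) * bin_size
    return DecayCurve(bin_mid=mids, n_pairs=n_pairs, c=c, c_rand=c_rand, y=y)


def phylogenetic_signal_curve(
    sites: Sequence[InformativeSite],
    max_pair_distance: int = 20_000,
    bin_size: int = 100,
    baseline: float = 0.0,
) -> DecayCurve:
    """Distance-binned compatible fraction and normalised signal.

    Each unordered pair within ``max_pair_distance`` contributes once to
    the bin of its distance (bin k covers distances in
    (k*bin_size, (k+1)*bin_size]).  The normalised signal
    ``y = (c - c_rand)/(1 - c_rand)`` maps clonal inheritance to 1 and
    random assortment to 0; the raw ``c`` is retained alongside.
    """
    if not 0.0 <= baseline < 1.0:
        raise ValueError(
            "baseline compatible fraction must lie in [0, 1); c_rand = 1 "
            "leaves the normalisation undefined"
        )
    if bin_size <= 0 or max_pair_distance <= 0 or bin_size > max_pair_distance:
        raise ValueError("need 0 < bin_size <= max_pair_distance")
    positions, masks, universe = _site_arrays(sites)
    i_idx, j_idx = _pair_index(positions, max_pair_distance)
    n_bins = int(np.ceil(max_pair_distance / bin_size))
    d = positions[j_idx] - positions[i_idx]
    # distances are >= 1 by the strictly-increasing-positions invariant
    bins = (d - 1) // bin_size
    compat = _compatible_masks(masks[i_idx], masks[j_idx], universe)
    n_pairs = np.bincount(bins, minlength=n_bins).astype(np.int64)
    n_comp = np.bincount(bins, weights=compat.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(n_pairs > 0, n_comp / np.maximum(n_pairs, 1), np.nan)
    y = (c - baseline) / (1.0 - baseline)
    mids = (np.arange(n_bins) + 0.5) * bin_size
    return DecayCurve(bin_mid=mids, n_pairs=n_pairs, c=c, c_rand=baseline, y=y)


def fit_exponential_decay(curve: DecayCurve, weighted: bool = False) -> DecayFit:
    """Fit ``y = exp(-b*x)`` to the occupied bins by least squares.

    Intercept is fixed at 1 and the asymptote at 0; ``b`` is constrained
    non-negative.  Unweighted by default; ``weighted=True`` weights bins by
    pair count.
    """
    occ = curve.occupied()
    x = curve.bin_mid[occ]
    y = curve.y[occ]
    if x.size < 3:
        raise ValueError(f"need >= 3 occupied bins to fit, have {x.size}")
    pos = y > 1e-12
    if pos.sum() >= 2:
        slope = np.polyfit(x[pos], np.log(y[pos]), 1)[0]
        b0 = max(-slope, 1e-12)
    else:
        b0 = 1e-4
    sigma = None
    if weighted:
        sigma = 1.0 / np.sqrt(curve.n_pairs[occ])
    try:
        popt, _ = curve_fit(
            lambda xx, b: np.exp(-b * xx),
            x,
            y,
            p0=[b0],
            bounds=(0.0, np.inf),
            sigma=sigma,
            maxfev=10_000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    b = float(popt[0])
    resid = y - np.exp(-b * x)
    return DecayFit(b=b, sse=float(np.sum(resid**2)))


# ---------------------------------------------------------------------------
# incompatible-site spacing


def _incompatible_adjacent(positions, masks, universe):
    compat = _compatible_masks(masks[:-1], masks[1:], universe)
    return positions[:-1][~compat], positions[1:][~compat]


def hudson_kaplan_intervals(
    sites: Sequence[InformativeSite], max_pair_distance: Optional[int] = None
) -> list[tuple[int, int]]:
    """Minimal set of non-overlapping intervals each bracketing at least one
    incompatible pair (interval pruning, every interval open).

    The size of the set lower-bounds the number of recombination events.
    ``max_pair_distance`` optionally restricts the pairs examined.
    """
    positions, masks, universe = _site_arrays(sites)
    limit = max_pair_distance if max_pair_distance is not None else \
        int(positions[-1] - positions[0]) if positions.size else 0
    i_idx, j_idx = _pair_index(positions, limit)
    compat = _compatible_masks(masks[i_idx], masks[j_idx], universe)
    lefts = positions[i_idx[~compat]]
    rights = positions[j_idx[~compat]]
    order = np.argsort(rights, kind="stable")
    chosen: list[tuple[int, int]] = []
    last_end = -np.inf
    for l, r in zip(lefts[order], rights[order]):
        if l >= last_end:
            chosen.append((int(l), int(r)))
            last_end = r
    return chosen


def mean_incompatible_distance(
    sites: Sequence[InformativeSite],
    mode: str = "adjacent",
    max_pair_distance: Optional[int] = None,
) -> float:
    """Mean spacing of incompatible sites, in bp.

    ``"adjacent"`` (default): mean distance over consecutive informative-
    site pairs that are incompatible.  ``"hudson_kaplan"``: span of the
    informative sites divided by the size of the minimal non-overlapping
    incompatible-interval set.  Raises when no incompatible pair exists.
    """
    positions, masks, universe = _site_arrays(sites)
    if mode == "adjacent":
        left, right = _incompatible_adjacent(positions, masks, universe)
        if left.size == 0:
            raise ValueError("no incompatible adjacent pairs: spacing undefined")
        return float(np.mean(right - left))
    if mode == "hudson_kaplan":
        intervals = hudson_kaplan_intervals(sites, max_pair_distance)
        if not intervals:
            raise ValueError("no incompatible pairs: spacing undefined")
        span = float(positions[-1] - positions[0])
        return span / len(intervals)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# compatible regions and the permutation test


def find_compatible_regions(
    sites: Sequence[InformativeSite],
    max_pair_distance: int = 20_000,
    min_length: int = 0,
) -> list[CompatibleRegion]:
    """Maximal runs of consecutive informative sites in which every
    within-run pair closer than ``max_pair_distance`` is compatible.

    Region span is measured site-to-site (no flank extrapolation); runs
    spanning less than ``min_length`` are dropped.
    """
    positions, masks, universe = _site_arrays(sites)
    n = positions.size
    if n == 0:
        return []
    raw: list[tuple[int, int]] = []
    s = 0
    for e in range(1, n):
        lo = int(np.searchsorted(positions, positions[e] - max_pair_distance))
        k0 = max(s, lo)
        if k0 < e:
            compat = _compatible_masks(masks[k0:e], np.repeat(masks[e], e - k0), universe)
            bad = np.flatnonzero(~compat)
            if bad.size:
                raw.append((s, e - 1))
                s = k0 + int(bad[-1]) + 1
    raw.append((s, n - 1))
    regions = []
    for a, b in raw:
        span = int(positions[b] - positions[a])
        if span >= min_length:
            regions.append(
                CompatibleRegion(
                    start=int(positions[a]),
                    end=int(positions[b]),
                    length=span,
                    n_sites=b - a + 1,
                )
            )
    return regions


def null_span_distribution(
    sites: Sequence[InformativeSite],
    fit: DecayFit,
    c_rand: float,
    n_permutations: int,
    seed: int,
    max_pair_distance: int = 20_000,
) -> np.ndarray:
    """Pooled null distribution of maximal compatible-run spans.

    For each informative site, the tract of sites within
    +/- ``max_pair_distance``/2 is taken; per replicate, every within-tract
    pair's compatibility is drawn independently as Bernoulli with success
    probability ``c_rand + (1 - c_rand) * exp(-b * d)`` for inter-site
    distance ``d``, and the replicate's maximal compatible-run span is
    recorded.  Spans are pooled over all tracts x replicates.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    positions, _, _ = _site_arrays(sites)
    n = positions.size
    half = max_pair_distance // 2
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] = []
    for center in range(n):
        lo = int(np.searchsorted(positions, positions[center] - half, side="left"))
        hi = int(np.searchsorted(positions, positions[center] + half, side="right"))
        pos = positions[lo:hi]
        m = pos.size
        if m < 2:
            pooled.append(np.zeros(n_permutations, dtype=np.int64))
            continue
        i_idx, j_idx = _pair_index(pos, max_pair_distance)
        d = (pos[j_idx] - pos[i_idx]).astype(float)
        p = c_rand + (1.0 - c_rand) * np.exp(-fit.b * d)
        # incompatibility indicator per replicate x pair
        incompat = rng.random((n_permutations, p.size)) >= p[None, :]
        # offending predecessor per right site e: the largest k with an
        # incompatible (k, e) pair, else -1 (pairs come sorted by (i, j),
        # so within each e-group the k values ascend)
        offend = np.full((n_permutations, m), -1, dtype=np.int64)
        kval = np.where(incompat, i_idx[None, :], -1)
        group_starts = np.searchsorted(j_idx, np.arange(m))
        has_pairs = np.diff(np.append(group_starts, j_idx.size)) > 0
        red = np.maximum.reduceat(kval, np.minimum(group_starts, j_idx.size - 1), axis=1)
        offend[:, has_pairs] = red[:, has_pairs]
        run_start = np.maximum.accumulate(offend + 1, axis=1)
        spans = pos[np.arange(m)][None, :] - pos[run_start]
        pooled.append(spans.max(axis=1))
    return np.concatenate(pooled) if pooled else np.zeros(0, dtype=np.int64)


def permutation_test_regions(
    regions: Sequence[CompatibleRegion],
    sites: Sequence[InformativeSite],
    fit: DecayFit,
    c_rand: float,
    n_permutations: int = 100,
    seed: int = 0,
    max_pair_distance: int = 20_000,
) -> list[CompatibleRegion]:
    """Assign each compatible region a pooled permutation p-value.

    ``p = (k + 1) / (M + 1)`` where ``k`` counts pooled null spans at least
    as long as the observed region span (the add-one correction avoids
    p = 0 at finite replicate counts).
    """
    null = null_span_distribution(
        sites, fit, c_rand, n_permutations, seed, max_pair_distance
    )
    null_sorted = np.sort(null)
    M = null_sorted.size
    out = []
    for r in regions:
        k = M - int(np.searchsorted(null_sorted, r.length, side="left"))
        out.append(
            CompatibleRegion(
                start=r.start,
                end=r.end,
                length=r.length,
                n_sites=r.n_sites,
                p_value=(k + 1) / (M + 1),
            )
        )
    return out
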