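"""Co-evolution statistics for co-localized gene pairs.

Models a BldB/Hpb-like putative toxin-antitoxin family: for each locus
carrying both partners, the proportion of variable columns in the
partner-A protein alignment is compared with the partner-B proportion at
the same locus; a positive Spearman rank correlation across loci is
evidence that substitutions in one partner encourage compensatory change
in the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import PairedLocusAlignments, seq_to_array

GAP_CHARS = (b"-", b".", b"X")


@dataclass
class CoevolutionResult:
    proportions_A: np.ndarray
    proportions_B: np.ndarray
    rho: float
    p_value: float
    n: int
    locus_ids: tuple[str, ...] = ()


def variable_site_proportion(
    alignment: Sequence[str] | dict[str, str], gap_policy: str = "missing"
) -> float:
    """Fraction of alignment columns with >= 2 distinct residues.

    Under the default ``"missing"`` policy gaps are ignored, so a column
    varies only if two distinct non-gap residues occur; ``"state"`` treats
    the gap as a 21st residue state.  The denominator is always the total
    column count.
    """
    seqs = list(alignment.values()) if isinstance(alignment, dict) else list(alignment)
    if not seqs:
        raise ValueError("empty alignment")
    arrs = [seq_to_array(s) for s in seqs]
    lengths = {a.size for a in arrs}
    if len(lengths) > 1:
        raise ValueError("alignment sequences have unequal lengths")
    mat = np.stack(arrs)
    if mat.shape[1] == 0:
        raise ValueError("empty alignment (zero columns)")
    if gap_policy == "missing":
        gap = np.isin(mat, GAP_CHARS)
        variable = np.zeros(mat.shape[1], dtype=bool)
        for c in range(mat.shape[1]):
            residues = set(mat[~gap[:, c], c])
            variable[c] = len(residues) >= 2
    elif gap_policy == "state":
        variable = (mat != mat[0]).any(axis=0)
    else:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    return float(variable.sum()) / mat.shape[1]


def spearman_t_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value for a Spearman correlation via the t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n - 2 degrees of freedom."""
    if n < 3:
        raise ValueError("need at least 3 observations")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def coevolution_test(
    pairs: Sequence[PairedLocusAlignments],
    gap_policy: str = "missing",
    method: str = "t",
    n_resamples: int = 10_000,
    seed: int = 0,
) -> CoevolutionResult:
    """Spearman co-evolution test over paired variable-site proportions.

    Ranks use average ties; the two-sided p-value comes from the t
    approximation (default) or an exact/Monte-Carlo permutation of one
    proportion vector (``method="permutation"``, useful at small n).
    Raises when either partner's proportions are all tied (rho undefined).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 loci")
    pa = np.array([variable_site_proportion(p.alignment_A, gap_policy) for p in pairs])
    pb = np.array([variable_site_proportion(p.alignment_B, gap_policy) for p in pairs])
    if np.all(pa == pa[0]) or np.all(pb == pb[0]):
        raise ValueError("all proportions tied in one partner: rho undefined")
    ra = stats.rankdata(pa)
    rb = stats.rankdata(pb)
    rho = float(np.corrcoef(ra, rb)[0, 1])
    n = len(pairs)
    if method == "t":
        p = spearman_t_pvalue(rho, n)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_resamples):
            r = float(np.corrcoef(ra, rng.permutation(rb))[0, 1])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_resamples + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CoevolutionResult(
        proportions_A=pa,
        proportions_B=pb,
        rho=rho,
        p_value=p,
        n=n,
        locus_ids=tuple(pr.locus_id for pr in pairs),
    )


def pairing_census(
    loci_A: Sequence[tuple[str, int]],
    loci_B: Sequence[tuple[str, int]],
    adjacency_window: int = 2_000,
) -> dict:
    """Census of paired and unpaired loci of two gene families.

    ``loci_A`` / ``loci_B`` hold (locus_id, position); an A locus pairs
    with every B locus within ``adjacency_window``.  Reports paired and
    unpaired counts per family, the number of distinct pair loci (B loci
    with at least one partner), and duplications (B loci claimed by more
    than one A, the locally duplicated-partner case).
    """
    paired_A = []
    unpaired_A = []
    partners_of_B: dict[str, list[str]] = {bid: [] for bid, _ in loci_B}
    for aid, apos in loci_A:
        hits = [bid for bid, bpos in loci_B if abs(apos - bpos) <= adjacency_window]
        if hits:
            paired_A.append(aid)
            for bid in hits:
                partners_of_B[bid].append(aid)
        else:
            unpaired_A.append(aid)
    paired_B = [bid for bid, ps in partners_of_B.items() if ps]
    duplicated = {bid: ps for bid, ps in partners_of_B.items() if len(ps) > 1}
    return {
        "n_A": len(loci_A),
        "n_B": len(loci_B),
        "paired_A": len(paired_A),
        "unpaired_A": len(unpaired_A),
        "paired_B": len(paired_B),
        "unpaired_B": len(loci_B) - len(paired_B),
        "n_pair_loci": len(paired_B),
        "duplicated_A_at": sorted(duplicated),
    }
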