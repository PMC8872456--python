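"""Pairwise differentiation and population trees.

Jost's D_EST measures locus-wise differentiation between a population pair on
the effective-allele-number scale, which stays interpretable at the high
within-population heterozygosities typical of microsatellites (where
F_ST-family statistics compress toward 0).  The estimator uses the
bias-corrected within- and total heterozygosities with harmonic-mean sample
size:

    H_S^ = (2*nh / (2*nh - 1)) * (1 - mean_i sum_a p_ia^2)
    H_T^ = 1 - sum_a pbar_a^2 + H_S^ / (2 * nh * n_pops)
    D    = (H_T^ - H_S^) / (1 - H_S^) * n_pops / (n_pops - 1)

Nei's standard genetic distance D = -ln I sums genetic identity jointly over
loci; neighbor-joining on the resulting matrix gives the population network,
with clade confidence from bootstrap resampling of loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from .genotypes import AlleleFrequencyTable

__all__ = [
    "jost_dest",
    "dest_profile",
    "nei_d",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "dest_distribution_compare",
    "tree_bipartitions",
    "DestResult",
]


@dataclass
class DestResult:
    pair_id: str
    per_locus: pd.DataFrame  # columns: locus, dest, h_s, h_t, monomorphic

    @property
    def values(self) -> np.ndarray:
        return self.per_locus["dest"].to_numpy()

    def reporting_values(self, floor: float = 0.001) -> np.ndarray:
        return np.clip(self.values, floor, None)


def jost_dest(counts_a: dict[int, float], counts_b: dict[int, float]) -> dict:
    """Jost's D for one locus and two populations from allele gene-copy counts.

    Returns dict with dest (clamped at 0, flag if the raw estimate was
    negative), h_s, h_t, and a monomorphic flag (D = 0 by convention when the
    locus is monomorphic across both populations).
    """
    na = sum(counts_a.values())
    nb = sum(counts_b.values())
    if na <= 0 or nb <= 0:
        raise ValueError("both populations need gene copies at the locus")
    alleles = sorted(set(counts_a) | set(counts_b))
    pa = np.array([counts_a.get(a, 0) / na for a in alleles])
    pb = np.array([counts_b.get(a, 0) / nb for a in alleles])
    if len(alleles) < 2:
        return {"dest": 0.0, "h_s": 0.0, "h_t": 0.0, "monomorphic": True, "clamped": False}
    # harmonic mean number of individuals
    ia, ib = na / 2.0, nb / 2.0
    nh = 2.0 / (1.0 / ia + 1.0 / ib)
    h_s_raw = 1.0 - 0.5 * (np.sum(pa**2) + np.sum(pb**2))
    h_s = (2 * nh / (2 * nh - 1)) * h_s_raw
    pbar = 0.5 * (pa + pb)
    h_t = 1.0 - float(np.sum(pbar**2)) + h_s / (2 * nh * 2)
    if h_s >= 1.0:
        d = 0.0
    else:
        d = (h_t - h_s) / (1.0 - h_s) * 2.0
    clamped = d < 0
    return {
        "dest": float(min(max(d, 0.0), 1.0)),
        "h_s": float(h_s),
        "h_t": float(h_t),
        "monomorphic": False,
        "clamped": bool(clamped),
    }


def dest_profile(
    freqs: AlleleFrequencyTable, pop_a: str, pop_b: str, pair_id: str | None = None
) -> DestResult:
    """Per-locus Jost's D for one population pair."""
    rows = []
    for locus in freqs.loci:
        ka, kb = (pop_a, locus), (pop_b, locus)
        if freqs.n_copies.get(ka, 0) == 0 or freqs.n_copies.get(kb, 0) == 0:
            continue
        ca = {a: f * freqs.n_copies[ka] for a, f in freqs.freqs[ka].items()}
        cb = {a: f * freqs.n_copies[kb] for a, f in freqs.freqs[kb].items()}
        res = jost_dest(ca, cb)
        rows.append({"locus": locus, **res})
    return DestResult(
        pair_id=pair_id or f"{pop_a}_vs_{pop_b}", per_locus=pd.DataFrame(rows)
    )


def nei_d(
    freqs: AlleleFrequencyTable,
    pop_a: str,
    pop_b: str,
    loci: list[str] | None = None,
) -> float:
    """Nei's (1972) standard genetic distance D = -ln I with the identity
    summed jointly over loci.  Returns inf (flagged by warning) when the
    populations share no alleles at any locus."""
    loci = list(loci) if loci is not None else list(freqs.loci)
    jxy = jx = jy = 0.0
    used = 0
    for locus in loci:
        ka, kb = (pop_a, locus), (pop_b, locus)
        fa = freqs.freqs.get(ka, {})
        fb = freqs.freqs.get(kb, {})
        if not fa or not fb:
            continue
        used += 1
        for a, x in fa.items():
            jx += x * x
            jxy += x * fb.get(a, 0.0)
        for _, y in fb.items():
            jy += y * y
    if used == 0:
        raise ValueError(f"no shared scored loci between {pop_a} and {pop_b}")
    if jxy == 0.0:
        warnings.warn(f"no shared alleles between {pop_a} and {pop_b}; D = inf")
        return float("inf")
    identity = jxy / np.sqrt(jx * jy)
    return float(-np.log(min(identity, 1.0)))


def distance_matrix(
    freqs: AlleleFrequencyTable,
    populations: list[str] | None = None,
    loci: list[str] | None = None,
) -> pd.DataFrame:
    pops = list(populations) if populations is not None else list(freqs.groups)
    mat = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            d = nei_d(freqs, pops[i], pops[j], loci)
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=pops, columns=pops)


def nj_tree(dm: pd.DataFrame) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei) from a symmetric distance matrix.

    Negative branch lengths are clamped to zero.  Raises on NaN or asymmetry.
    """
    arr = dm.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix is not symmetric")
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 populations")
    arr = 0.5 * (arr + arr.T)  # remove float-level asymmetry
    sk = SkbioDM(arr, ids=[str(c) for c in dm.columns])
    return skbio_nj(sk, neg_as_zero=True)


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    side not containing the lexicographically first leaf."""
    leaves = sorted(n.name for n in tree.tips())
    anchor = leaves[0]
    full = set(leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = full - side
        if 1 < len(side) < len(full) - 1:
            parts.add(frozenset(side))
    return parts


def bootstrap_support(
    freqs: AlleleFrequencyTable,
    populations: list[str] | None = None,
    reps: int = 10_000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree with bootstrap-over-loci bipartition supports (percent).

    Loci are resampled with replacement ``reps`` times; support for each
    bipartition of the point-estimate tree is the percentage of replicate
    trees containing it.  Supports are written onto internal node names.
    """
    loci = list(freqs.loci)
    if len(loci) < 2:
        raise ValueError("need >= 2 loci for a locus bootstrap")
    if reps < 100:
        warnings.warn(f"only {reps} bootstrap replicates; supports will be coarse")
    pops = list(populations) if populations is not None else list(freqs.groups)
    point = nj_tree(distance_matrix(freqs, pops))
    target = tree_bipartitions(point)
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        sample = [loci[k] for k in rng.integers(0, len(loci), size=len(loci))]
        rep_tree = nj_tree(distance_matrix(freqs, pops, sample))
        rep_parts = tree_bipartitions(rep_tree)
        for bp in target:
            if bp in rep_parts:
                hits[bp] += 1
    support = {bp: 100.0 * h / reps for bp, h in hits.items()}
    # annotate internal nodes
    leaves = sorted(n.name for n in point.tips())
    anchor, full = leaves[0], set(leaves)
    for node in point.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        key = frozenset(full - side if anchor in side else side)
        if key in support:
            node.name = f"{support[key]:.0f}"
    return point, support


def dest_distribution_compare(
    a: DestResult, b: DestResult, equal_var: bool = False
) -> dict:
    """Two-sample t-test (Welch by default) on per-locus D_EST values."""
    xa, xb = a.values, b.values
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("both profiles need >= 2 loci")
    if np.var(xa, ddof=1) == 0 and np.var(xb, ddof=1) == 0:
        if np.isclose(xa.mean(), xb.mean()):
            return {"t": 0.0, "df": float(len(xa) + len(xb) - 2), "p": 1.0, "flagged": True}
        raise ValueError("zero variance in both samples with different means")
    res = stats.ttest_ind(xa, xb, equal_var=equal_var)
    if equal_var:
        df = float(len(xa) + len(xb) - 2)
    else:
        va, vb = np.var(xa, ddof=1) / len(xa), np.var(xb, ddof=1) / len(xb)
        df = float((va + vb) ** 2 / (va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1)))
    return {"t": float(res.statistic), "df": df, "p": float(res.pvalue), "flagged": False}
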