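"""Allelic diversity: rarefied richness, asymptotic richness estimates,
private alleles, and among-taxon richness comparison.

Rarefied richness follows the standardized-subsample convention: the expected
number of distinct alleles alpha_g among g gene copies drawn without
replacement from the N observed copies, computed from the hypergeometric
probability that each allele is represented.  Rarefaction curves are
summarized by a saturating Michaelis-Menten fit alpha(g) = A*g/(B+g), whose
asymptote A estimates the underlying allele count.

A private allele of a focal taxon is a fragment-length variant absent from
every population of the reference taxon and present in at least ``min_pops``
populations of the focal taxon (singletons and single-site variants are
thereby excluded); its reported frequency is the gene-copy-weighted frequency
across all focal individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .genotypes import AlleleFrequencyTable

__all__ = [
    "rarefied_richness",
    "rarefaction_curve",
    "fit_asymptote",
    "private_alleles",
    "compare_richness",
    "richness_by_population",
    "PrivateAlleleReport",
    "AsymptoteFit",
]


def rarefied_richness(counts, g: int) -> float:
    """Expected number of distinct alleles in a subsample of g gene copies.

    ``counts`` maps allele -> gene-copy count (or is a count array); exact
    hypergeometric expectation  alpha_g = sum_i [1 - C(N-N_i, g)/C(N, g)].
    """
    n_i = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, dtype=np.int64)
    n_i = n_i[n_i > 0]
    n = int(n_i.sum())
    if n == 0:
        raise ValueError("no gene copies at this (population, locus)")
    if not 2 <= g <= n:
        raise ValueError(f"g must be in [2, {n}], got {g}")
    # log-space ratio of binomials; exact to double precision
    log_absent = (
        special.gammaln(n - n_i + 1)
        - special.gammaln(n - n_i - g + 1)
        - special.gammaln(n + 1)
        + special.gammaln(n - g + 1)
    )
    absent = np.where(n - n_i >= g, np.exp(log_absent), 0.0)
    return float(np.sum(1.0 - absent))


def rarefaction_curve(counts, g_max: int | None = None) -> dict[int, float]:
    """alpha_g for g = 2..g_max (default: the full gene-copy count)."""
    n_i = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, dtype=np.int64)
    n = int(n_i.sum())
    g_max = n if g_max is None else min(g_max, n)
    return {g: rarefied_richness(n_i, g) for g in range(2, g_max + 1)}


@dataclass
class AsymptoteFit:
    a_inf: float  # asymptotic allele count
    b: float  # half-saturation gene-copy count
    residuals: np.ndarray
    at_bound: bool = False


def fit_asymptote(curve: dict[int, float]) -> AsymptoteFit:
    """Least-squares Michaelis-Menten fit alpha(g) = A*g/(B+g) to a
    rarefaction curve, with A constrained >= alpha at the largest g."""
    if len(curve) < 4:
        raise ValueError("need >= 4 distinct g values")
    g = np.array(sorted(curve), dtype=float)
    y = np.array([curve[int(v)] for v in g])
    a_floor = float(y[-1])
    if np.ptp(y) < 1e-12:  # flat curve (monomorphic or saturated)
        warnings.warn("flat rarefaction curve; asymptote fixed at observed richness")
        return AsymptoteFit(a_inf=a_floor, b=1e-9, residuals=np.zeros_like(y), at_bound=True)

    def resid(theta):
        a, b = theta
        return a * g / (b + g) - y

    # initialize from the largest-g point and a crude half-saturation guess
    a0 = max(a_floor * 1.2, a_floor + 0.1)
    b0 = max(g[-1] * (a0 / a_floor - 1.0), 0.5)
    sol = optimize.least_squares(
        resid, x0=[a0, b0], bounds=([a_floor, 1e-9], [np.inf, np.inf])
    )
    a, b = sol.x
    return AsymptoteFit(
        a_inf=float(a),
        b=float(b),
        residuals=resid(sol.x),
        at_bound=bool(abs(a - a_floor) < 1e-9),
    )


def richness_by_population(
    freqs: AlleleFrequencyTable, g_std: int | None = None
) -> pd.DataFrame:
    """Per-population mean asymptotic richness across loci.

    Curves are computed for g = 2..g_std, where g_std defaults to the
    smallest gene-copy count over all (population, locus) entries with data
    (so every population is standardized to the same subsample size).
    """
    if g_std is None:
        g_std = min(n for n in freqs.n_copies.values() if n > 0)
    rows = []
    for pop in freqs.groups:
        fits = []
        for locus in freqs.loci:
            key = (pop, locus)
            n = freqs.n_copies.get(key, 0)
            if n == 0:
                continue
            counts = {a: round(f * n) for a, f in freqs.freqs[key].items()}
            curve = rarefaction_curve(counts, min(g_std, n))
            if len(curve) < 4:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits.append(fit_asymptote(curve).a_inf)
        rows.append(
            {
                "population": pop,
                "mean_a_inf": float(np.mean(fits)) if fits else float("nan"),
                "se_a_inf": float(np.std(fits, ddof=1) / np.sqrt(len(fits))) if len(fits) > 1 else float("nan"),
                "n_loci": len(fits),
                "g_std": g_std,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PrivateAlleleReport:
    focal_taxon: str
    reference_taxa: list[str]
    min_pops: int
    # per locus: summed gene-copy-weighted frequency of private alleles
    frequency: dict[str, float] = field(default_factory=dict)
    alleles: dict[str, list[int]] = field(default_factory=dict)
    populations_of_occurrence: dict[str, dict[int, int]] = field(default_factory=dict)

    def loci_with_private(self) -> list[str]:
        return sorted(l for l, f in self.frequency.items() if f > 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "locus": l,
                "taxon": self.focal_taxon,
                "private_frequency": self.frequency.get(l, 0.0),
                "alleles": ";".join(map(str, self.alleles.get(l, []))),
            }
            for l in sorted(self.frequency)
        ]
        return pd.DataFrame(rows)


def private_alleles(
    freqs: AlleleFrequencyTable,
    taxon_of: dict[str, str],
    focal_taxon: str,
    reference_taxa: str | list[str],
    min_pops: int = 2,
) -> PrivateAlleleReport:
    """Private alleles of ``focal_taxon`` relative to ``reference_taxa``.

    ``freqs`` must be grouped by population; ``taxon_of`` maps population id
    to taxon label.  An allele is private iff it has frequency 0 in every
    reference population and nonzero frequency in >= min_pops focal
    populations.  For single-population taxa pass min_pops=1.
    """
    if isinstance(reference_taxa, str):
        reference_taxa = [reference_taxa]
    known = set(taxon_of.values())
    for t in [focal_taxon, *reference_taxa]:
        if t not in known:
            raise KeyError(f"unknown taxon {t!r}")
    focal_pops = [p for p in freqs.groups if taxon_of.get(p) == focal_taxon]
    ref_pops = [p for p in freqs.groups if taxon_of.get(p) in set(reference_taxa)]
    if len(focal_pops) < min_pops:
        raise ValueError(
            f"{focal_taxon} has {len(focal_pops)} populations < min_pops={min_pops}"
        )
    report = PrivateAlleleReport(
        focal_taxon=focal_taxon, reference_taxa=list(reference_taxa), min_pops=min_pops
    )
    for locus in freqs.loci:
        ref_alleles: set[int] = set()
        for p in ref_pops:
            fm = freqs.freqs.get((p, locus), {})
            ref_alleles.update(a for a, f in fm.items() if f > 0)
        occurrence: dict[int, int] = {}
        for p in focal_pops:
            fm = freqs.freqs.get((p, locus), {})
            for a, f in fm.items():
                if f > 0 and a not in ref_alleles:
                    occurrence[a] = occurrence.get(a, 0) + 1
        private = {a: c for a, c in occurrence.items() if c >= min_pops}
        total_copies = sum(freqs.n_copies.get((p, locus), 0) for p in focal_pops)
        freq = 0.0
        if private and total_copies > 0:
            weighted = sum(
                freqs.freqs.get((p, locus), {}).get(a, 0.0) * freqs.n_copies.get((p, locus), 0)
                for p in focal_pops
                for a in private
            )
            freq = weighted / total_copies
        report.frequency[locus] = freq
        report.alleles[locus] = sorted(private)
        report.populations_of_occurrence[locus] = private
    return report


def _letter_groups(groups: list[str], reject: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display from pairwise significance (insert-absorb)."""
    letters: list[set[str]] = [set(groups)]
    for (a, b), rej in reject.items():
        if not rej:
            continue
        for col in list(letters):
            if a in col and b in col:
                letters.remove(col)
                ca, cb = col - {b}, col - {a}
                for c in (ca, cb):
                    if not any(c <= other for other in letters):
                        letters.append(c)
    # order columns by the first group they contain
    order = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda col: min(order[g] for g in col))
    out: dict[str, str] = {g: "" for g in groups}
    for k, col in enumerate(letters):
        ch = chr(ord("a") + k)
        for g in col:
            out[g] += ch
    return out


def compare_richness(richness: dict[str, list[float]], alpha: float = 0.05) -> dict:
    """One-way ANOVA on per-population mean richness across groups, plus
    Tukey HSD letter groups.  Groups with a single population are excluded
    from the test (and get no letter)."""
    usable = {g: v for g, v in richness.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 populations each")
    names = list(usable)
    f_stat, p = stats.f_oneway(*usable.values())
    if np.isnan(f_stat):  # zero within-group variance
        means = [np.mean(v) for v in usable.values()]
        f_stat, p = (0.0, 1.0) if np.ptp(means) < 1e-12 else (np.inf, 0.0)
    values = np.concatenate([usable[g] for g in names])
    labels = np.concatenate([[g] * len(usable[g]) for g in names])
    if np.allclose(values.std(), 0):
        letters = {g: "a" for g in names}
    else:
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pairs = list(zip(*np.triu_indices(len(tk.groupsunique), k=1)))
        reject = {
            (str(tk.groupsunique[i]), str(tk.groupsunique[j])): bool(r)
            for (i, j), r in zip(pairs, tk.reject)
        }
        letters = _letter_groups([str(g) for g in tk.groupsunique], reject)
    df1 = len(names) - 1
    df2 = sum(len(v) for v in usable.values()) - len(names)
    return {
        "F": float(f_stat),
        "df": (df1, df2),
        "p": float(p),
        "letters": letters,
        "excluded": sorted(set(richness) - set(usable)),
    }
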