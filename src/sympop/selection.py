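"""Migration-selection balance in a symmetric two-island model.

The question the model answers: given an observed allele-frequency difference
between a sympatric pair of populations that exchange migrants at a gross rate
m per generation, how strong must viability selection be at each locus to hold
that difference in place at equilibrium?

Multi-allelic microsatellite data are first collapsed to two allele classes
per locus and per pair: one class of alleles more common in the ancestral
population, one of alleles more common in the derived population.  For each
locus we then solve, in both directions, for the selection coefficient s such
that one generation of selection (genotype fitnesses 1, 1-h*s, 1-s for the
favored homozygote, heterozygote, disfavored homozygote) exactly compensates
the homogenizing frequency change m*(p_resident - p_immigrant) from migration.
With h = 1/2 the solution is closed-form; for general h it is found by
bisection on the full diploid update.  Solutions exceeding s = 1 mean the
observed difference cannot be maintained at equilibrium under that m; they are
reported as s = 1 with a capped flag.

`MigrationSelectionModel` wraps this as a fitted-model object: build it from a
pair of allele-frequency maps (or an `AlleleFrequencyTable`), call `.fit()`,
and read per-locus coefficients, summaries, and asymmetry tests off the
returned `SelectionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import AlleleFrequencyTable

__all__ = [
    "pool_alleles",
    "required_s",
    "selection_delta_p",
    "MigrationSelectionModel",
    "SelectionResults",
    "SolveResult",
    "PooledPair",
]

# Default per-pair gross migration rates (fraction of each population that is
# immigrant per generation), from field estimates for the study system.
DEFAULT_MIGRATION_RATES = {
    "mayhaw_vs_green_hawthorn": 0.05,
    "apple_vs_downy_hawthorn": 0.045,
    "blueberry_hawthorn_vs_mayhaw": 0.04,
    "mendax_vs_downy_hawthorn": 0.02,
    "dogwood_fly_vs_downy_hawthorn": 0.03,
    "zephyria_vs_black_hawthorn": 0.01,
}


def selection_delta_p(p: float | np.ndarray, s: float, h: float = 0.5):
    """One-generation frequency change of the favored allele under viability
    selection with fitnesses (1, 1-h*s, 1-s)."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    wbar = p**2 + 2 * p * q * (1 - h * s) + q**2 * (1 - s)
    p_next = (p**2 + p * q * (1 - h * s)) / wbar
    return p_next - p


@dataclass
class SolveResult:
    s: float
    capped: bool = False
    degenerate: bool = False


def required_s(
    p_favored: float,
    p_immigrant: float,
    m: float,
    h: float = 0.5,
    convention: str = "compensatory",
) -> SolveResult:
    """Selection coefficient needed to offset migration at equilibrium.

    Parameters
    ----------
    p_favored : resident frequency of the locally favored allele class.
    p_immigrant : frequency of the same class among immigrants (source deme).
    m : symmetric gross migration rate per generation, in [0, 0.5].
    h : dominance coefficient of the disfavored class.
    convention : "compensatory" equates the selection response at the observed
        frequency to the migration deficit; "sequential" first applies
        migration and solves for the selection step that returns the
        post-migration frequency to the observed one (the literal
        one-generation equilibrium condition; it inverts deterministic
        two-island equilibria exactly).
    """
    if not 0.0 <= m <= 0.5:
        raise ValueError("m must be in [0, 0.5]")
    if p_favored < p_immigrant - 1e-12:
        raise ValueError("p_favored must be >= p_immigrant")
    delta = m * (p_favored - p_immigrant)
    if delta <= 0.0:
        return SolveResult(0.0)
    if convention == "compensatory":
        p_eval = p_favored
    elif convention == "sequential":
        p_eval = (1 - m) * p_favored + m * p_immigrant
    else:
        raise ValueError(f"unknown convention {convention!r}")
    q = 1.0 - p_eval
    if p_eval <= 0.0 or q <= 0.0:
        # fixed resident frequency cannot respond to selection at all
        return SolveResult(1.0, capped=True, degenerate=True)
    if h == 0.5:
        # delta_p = 0.5*p*q*s/(1 - q*s)  =>  s = delta / (q*(p/2 + delta))
        s = delta / (q * (0.5 * p_eval + delta))
    else:
        hi = selection_delta_p(p_eval, 1.0, h)
        if delta >= hi:
            return SolveResult(1.0, capped=True)
        s = float(
            optimize.brentq(
                lambda x: selection_delta_p(p_eval, x, h) - delta, 0.0, 1.0, xtol=1e-14
            )
        )
    if s > 1.0:
        return SolveResult(1.0, capped=True)
    return SolveResult(float(s))


@dataclass
class PooledLocus:
    locus: str
    a1: float  # ancestral-class frequency in the ancestral population
    a2: float  # ancestral-class frequency in the derived population
    ancestral_class: tuple[int, ...] = ()


@dataclass
class PooledPair:
    """Two-class frequencies per locus for one sympatric population pair."""

    pair_id: str
    ancestral: str
    derived: str
    loci: list[PooledLocus]
    m: float
    h: float = 0.5
    skipped_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 0.5:
            raise ValueError("m must be in [0, 0.5]")
        for rec in self.loci:
            if rec.a1 < rec.a2 - 1e-12:
                raise ValueError(f"pooling violated a1 >= a2 at {rec.locus}")


def pool_alleles(
    freq_anc: dict[int, float], freq_der: dict[int, float]
) -> tuple[float, float, tuple[int, ...]]:
    """Collapse a multi-allelic locus to two classes for one population pair.

    An allele joins the ancestral class iff its frequency in the ancestral
    population strictly exceeds that in the derived population; ties (equal
    frequency, including shared absence) go to the ancestral class, which
    leaves the frequency difference unchanged.  Returns (a1, a2, class): the
    summed ancestral-class frequency in the ancestral and derived populations
    and the member alleles.
    """
    alleles = sorted(set(freq_anc) | set(freq_der))
    anc_class = tuple(a for a in alleles if freq_anc.get(a, 0.0) >= freq_der.get(a, 0.0))
    a1 = sum(freq_anc.get(a, 0.0) for a in anc_class)
    a2 = sum(freq_der.get(a, 0.0) for a in anc_class)
    return a1, a2, anc_class


def build_pooled_pair(
    freqs: AlleleFrequencyTable,
    ancestral: str,
    derived: str,
    m: float,
    h: float = 0.5,
    pair_id: str | None = None,
) -> PooledPair:
    loci_recs: list[PooledLocus] = []
    skipped: list[str] = []
    for locus in freqs.loci:
        ka, kd = (ancestral, locus), (derived, locus)
        if (
            ka not in freqs.freqs
            or kd not in freqs.freqs
            or freqs.n_copies[ka] == 0
            or freqs.n_copies[kd] == 0
        ):
            skipped.append(locus)
            continue
        a1, a2, cls = pool_alleles(freqs.freqs[ka], freqs.freqs[kd])
        loci_recs.append(PooledLocus(locus=locus, a1=a1, a2=a2, ancestral_class=cls))
    return PooledPair(
        pair_id=pair_id or f"{derived}_vs_{ancestral}",
        ancestral=ancestral,
        derived=derived,
        loci=loci_recs,
        m=m,
        h=h,
        skipped_loci=skipped,
    )


class MigrationSelectionModel:
    """Two-island migration-selection balance model for one sympatric pair.

    Parameters
    ----------
    pair : PooledPair
        Per-locus two-class frequencies plus the assumed gross migration rate.
    """

    def __init__(self, pair: PooledPair):
        self.pair = pair

    @classmethod
    def from_frequencies(
        cls,
        freqs: AlleleFrequencyTable,
        ancestral: str,
        derived: str,
        m: float,
        h: float = 0.5,
        pair_id: str | None = None,
    ) -> "MigrationSelectionModel":
        return cls(build_pooled_pair(freqs, ancestral, derived, m, h, pair_id))

    def fit(self, convention: str = "compensatory") -> "SelectionResults":
        rows = []
        for rec in self.pair.loci:
            # in the ancestral population the ancestral class is favored
            r_anc = required_s(rec.a1, rec.a2, self.pair.m, self.pair.h, convention)
            # in the derived population the derived class (complement) is favored
            r_der = required_s(
                1.0 - rec.a2, 1.0 - rec.a1, self.pair.m, self.pair.h, convention
            )
            rows.append(
                {
                    "locus": rec.locus,
                    "a1": rec.a1,
                    "a2": rec.a2,
                    "s_derived": r_der.s,
                    "s_ancestral": r_anc.s,
                    "capped_derived": r_der.capped,
                    "capped_ancestral": r_anc.capped,
                    "degenerate": r_anc.degenerate or r_der.degenerate,
                }
            )
        profile = pd.DataFrame(rows)
        return SelectionResults(self, profile, convention)


class SelectionResults:
    """Per-locus selection coefficients for one pair, with summaries and tests.

    ``s_derived`` is selection against the ancestral-favored allele class in
    the derived population; ``s_ancestral`` the reverse.  Values are capped at
    1 (capped flags mark loci whose observed difference cannot be maintained
    at equilibrium under the assumed m); summaries are over capped values.
    """

    directions = ("s_derived", "s_ancestral")

    def __init__(self, model: MigrationSelectionModel, profile: pd.DataFrame, convention: str):
        self.model = model
        self.profile = profile
        self.convention = convention

    @property
    def pair(self) -> PooledPair:
        return self.model.pair

    def summary_stats(self) -> pd.DataFrame:
        out = []
        for d in self.directions:
            s = self.profile[d]
            out.append(
                {
                    "direction": d,
                    "mean": float(s.mean()),
                    "min": float(s.min()),
                    "max": float(s.max()),
                    "n_loci": int(len(s)),
                    "n_capped": int(self.profile["capped" + d[1:]].sum()),
                }
            )
        return pd.DataFrame(out)

    def asymmetry_tests(self) -> dict:
        """Paired t-test across loci between directions plus a variance-ratio
        F-test with the derived-direction variance in the numerator."""
        sd = self.profile["s_derived"].to_numpy()
        sa = self.profile["s_ancestral"].to_numpy()
        if len(sd) < 3:
            raise ValueError("need >= 3 loci for asymmetry tests")
        diffs = sd - sa
        if np.allclose(diffs.std(ddof=1), 0.0):
            t_stat, t_p = 0.0, 1.0
        else:
            t_res = stats.ttest_rel(sd, sa)
            t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
        df = len(sd) - 1
        va, vd = sa.var(ddof=1), sd.var(ddof=1)
        if va == 0.0 or vd == 0.0:
            f_stat, f_p, f_flag = float("nan"), float("nan"), True
        else:
            f_stat = vd / va
            # two-sided p for the variance ratio
            cdf = stats.f.cdf(f_stat, df, df)
            f_p = float(2 * min(cdf, 1 - cdf))
            f_flag = False
        return {
            "paired_t": t_stat,
            "paired_t_df": df,
            "paired_t_p": t_p,
            "F": float(f_stat),
            "F_df": (df, df),
            "F_p": f_p,
            "F_undefined": f_flag,
            "larger_variance": "derived" if vd >= va else "ancestral",
        }

    def reporting_profile(self, floor: float = 0.001) -> pd.DataFrame:
        """Profile for tables with small values floored at ``floor`` (raw
        values stay available on .profile)."""
        rep = self.profile.copy()
        for d in self.directions:
            rep[d] = rep[d].clip(lower=floor)
        return rep

    def summary(self) -> str:
        p = self.pair
        stats_df = self.summary_stats()
        tests = self.asymmetry_tests()
        lines = [
            "Migration-selection balance (two-island, symmetric m)",
            f"  pair: {p.pair_id}  (ancestral={p.ancestral}, derived={p.derived})",
            f"  m = {p.m:g}, h = {p.h:g}, convention = {self.convention}, "
            f"loci = {len(p.loci)}",
            "",
            stats_df.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            f"  paired t = {tests['paired_t']:.3f} (df={tests['paired_t_df']}, "
            f"p={tests['paired_t_p']:.4f})",
            f"  F = {tests['F']:.2f} (df={tests['F_df'][0]},{tests['F_df'][1]}, "
            f"p={tests['F_p']:.4f}; larger variance: {tests['larger_variance']})",
        ]
        return "\n".join(lines)
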