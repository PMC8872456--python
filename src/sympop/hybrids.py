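"""Likelihood classification of individuals into hybrid classes.

For a sympatric pair of parental pools A and B, each individual from pool A
is scored under five gamete-origin models: pure natal (both gametes drawn
from A's allele frequencies), pure migrant (both from B), F1 (one from each),
backcross-to-natal (one from A, one from the even A/B mixture an F1 parent
transmits), and backcross-to-other (one from B, one from the mixture).
Ancestry is modeled two generations back only — the migrant/F1/backcross
categories — with no F2 class.

This is a transparent simplification of model-based clustering with prior
population information: it conditions on two predefined parental pools rather
than jointly inferring clusters, so results quantify evidence for recent
mixed ancestry given the pools, not de novo population structure.  When the
pools are weakly differentiated the posteriors stay near the prior and a
warning is attached.

Parental allele frequencies are estimated leave-one-out for the focal
individual's natal pool; alleles unseen in both pools are floored at
1/(2N+1) so likelihoods stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable

__all__ = ["CLASSES", "class_genotype_loglik", "classify_individuals", "HybridClassPosterior"]

CLASSES = ("pure_natal", "migrant", "F1", "backcross_natal", "backcross_other")

# Prior weights within the migration-prior mass, proportional to the number
# of ancestor configurations at each depth of a two-generation pedigree:
# migrant self (1), one of two parents (2), one/three of four grandparents (4 each).
_CLASS_WEIGHTS = {"migrant": 1.0, "F1": 2.0, "backcross_natal": 4.0, "backcross_other": 4.0}


def _gamete_dists(freq_a: dict[int, float], freq_b: dict[int, float], cls: str):
    mix = {a: 0.5 * freq_a.get(a, 0.0) + 0.5 * freq_b.get(a, 0.0) for a in set(freq_a) | set(freq_b)}
    return {
        "pure_natal": (freq_a, freq_a),
        "migrant": (freq_b, freq_b),
        "F1": (freq_a, freq_b),
        "backcross_natal": (freq_a, mix),
        "backcross_other": (freq_b, mix),
    }[cls]


def class_genotype_loglik(
    genotype: tuple[int, int],
    freq_a: dict[int, float],
    freq_b: dict[int, float],
    cls: str,
    floor: float = 1e-6,
) -> float:
    """Log-probability of one diploid call under a hybrid class's
    gamete-origin model.  Missing calls contribute 0.  ``floor`` replaces
    zero frequencies (unseen alleles) so the result is finite."""
    x, y = genotype
    if x == MISSING or y == MISSING:
        return 0.0
    u, v = _gamete_dists(freq_a, freq_b, cls)

    def f(dist: dict[int, float], allele: int) -> float:
        return max(dist.get(allele, 0.0), floor)

    if x == y:
        p = f(u, x) * f(v, x)
    else:
        p = f(u, x) * f(v, y) + f(u, y) * f(v, x)
    return float(np.log(p))


@dataclass
class HybridClassPosterior:
    individual: str
    natal_population: str
    posterior: dict[str, float]
    migration_prior: float
    loci_used: int
    warning: str | None = None
    top_class: str = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.posterior.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("posterior does not sum to 1")
        self.top_class = max(self.posterior, key=self.posterior.get)


def _class_prior(migration_prior: float) -> dict[str, float]:
    w_tot = sum(_CLASS_WEIGHTS.values())
    prior = {c: migration_prior * w / w_tot for c, w in _CLASS_WEIGHTS.items()}
    prior["pure_natal"] = 1.0 - migration_prior
    return prior


def _pool_freqs(calls: np.ndarray) -> list[dict[int, float]]:
    """Per-locus allele frequency maps from a (n, L, 2) call block."""
    out = []
    for j in range(calls.shape[1]):
        flat = calls[:, j, :].ravel()
        flat = flat[flat != MISSING]
        if flat.size == 0:
            out.append({})
            continue
        vals, counts = np.unique(flat, return_counts=True)
        out.append({int(a): c / flat.size for a, c in zip(vals, counts)})
    return out


def classify_individuals(
    table: GenotypeTable,
    pop_a: str,
    pop_b: str,
    migration_prior: float = 0.01,
    divergence_warning_dest: float = 0.05,
) -> list[HybridClassPosterior]:
    """Posterior hybrid-class membership for every individual of ``pop_a``
    (natal) against ``pop_b`` (other parental pool).

    Natal-pool frequencies are recomputed leave-one-out per individual.  A
    dataset-level warning is attached when the pools are too weakly
    differentiated (mean Jost's D below ``divergence_warning_dest``) for
    genotypic hybrid detection to be well supported.
    """
    ids = np.array(table.population_ids)
    idx_a = np.nonzero(ids == pop_a)[0]
    idx_b = np.nonzero(ids == pop_b)[0]
    if len(idx_a) < 10 or len(idx_b) < 10:
        raise ValueError("both populations need >= 10 individuals")
    calls_a = table.calls[idx_a]
    calls_b = table.calls[idx_b]
    freq_b = _pool_freqs(calls_b)

    # differentiation check (on full pools, not leave-one-out)
    from .distance import jost_dest

    freq_a_full = _pool_freqs(calls_a)
    dests = []
    for j in range(len(table.loci)):
        fa, fb = freq_a_full[j], freq_b[j]
        if not fa or not fb:
            continue
        na = 2 * int(np.sum(calls_a[:, j, 0] != MISSING))
        nb = 2 * int(np.sum(calls_b[:, j, 0] != MISSING))
        dests.append(
            jost_dest({a: f * na for a, f in fa.items()}, {a: f * nb for a, f in fb.items()})["dest"]
        )
    warn = None
    if dests and float(np.mean(dests)) < divergence_warning_dest:
        warn = (
            f"mean D_EST {np.mean(dests):.3f} < {divergence_warning_dest}: parental pools "
            "are weakly differentiated; hybrid posteriors are prior-dominated"
        )

    floor = 1.0 / (2 * len(idx_a) + 1)
    prior = _class_prior(migration_prior)
    out = []
    for k, i in enumerate(idx_a):
        loo = np.delete(calls_a, k, axis=0)
        freq_a = _pool_freqs(loo)
        logpost = {}
        used = 0
        for j in range(len(table.loci)):
            if table.calls[i, j, 0] != MISSING:
                used += 1
        if used == 0:
            raise ValueError(f"individual {table.individual_ids[i]} missing at all loci")
        for cls in CLASSES:
            ll = np.log(prior[cls])
            for j in range(len(table.loci)):
                g = tuple(table.calls[i, j])
                if g[0] == MISSING or not freq_a[j] or not freq_b[j]:
                    continue
                ll += class_genotype_loglik(g, freq_a[j], freq_b[j], cls, floor=floor)
            logpost[cls] = ll
        mx = max(logpost.values())
        w = {c: np.exp(v - mx) for c, v in logpost.items()}
        z = sum(w.values())
        post = {c: v / z for c, v in w.items()}
        out.append(
            HybridClassPosterior(
                individual=table.individual_ids[i],
                natal_population=pop_a,
                posterior=post,
                migration_prior=migration_prior,
                loci_used=used,
                warning=warn,
            )
        )
    return out


def posteriors_to_frame(
    posteriors: list[HybridClassPosterior], threshold: float = 0.5
) -> pd.DataFrame:
    rows = []
    for p in posteriors:
        non_natal = 1.0 - p.posterior["pure_natal"]
        rows.append(
            {
                "individual": p.individual,
                "population": p.natal_population,
                **{c: p.posterior[c] for c in CLASSES},
                "top_class": p.top_class,
                "non_natal_flag": non_natal > threshold,
                "loci_used": p.loci_used,
            }
        )
    return pd.DataFrame(rows)
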