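"""Latitudinal clines summarized by per-locus PCA, and mosaic classification
of derived taxa against the ancestral clines.

At each locus the population x allele frequency matrix of the ancestral
(hawthorn-race) populations is centered (unweighted population mean, no
scaling) and decomposed; PC1 collapses the multi-allelic variation to a
single axis per population.  Its sign is fixed so that score correlates
non-negatively with latitude (higher score = more northern).  Loci whose PC1
correlates strongly with latitude (|r| >= 0.8, p <= 0.05 by default) are
flagged 'major clinal'.

Derived-taxon populations are projected onto each ancestral axis (alleles
unseen in the ancestral populations get zero loading and are recorded) and
classified per locus by confidence-interval overlap: the taxon's mean score
CI is compared with the 95% regression band of ancestral score on latitude
evaluated over the derived taxon's latitude range — entirely above the band =
northern-like, entirely below = southern-like, otherwise mid-latitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "locus_pca",
    "detect_clinal_loci",
    "project_and_classify",
    "LocusPCA",
    "ClinalCall",
]


@dataclass
class LocusPCA:
    locus: str
    alleles: list[int]
    loadings: np.ndarray  # unit-norm PC1 loadings over alleles
    center: np.ndarray  # per-allele mean frequency over ancestral populations
    scores: pd.Series  # PC1 score per ancestral population
    var_explained: float
    latitudes: pd.Series
    degenerate: bool = False

    def project(self, freq_matrix: pd.DataFrame) -> tuple[pd.Series, list[int]]:
        """Scores of new populations in the ancestral axis.

        Columns are allele labels; alleles absent from the ancestral space
        get zero loading and are returned as unseen.
        """
        unseen = [int(a) for a in freq_matrix.columns if int(a) not in self.alleles]
        mat = np.zeros((freq_matrix.shape[0], len(self.alleles)))
        cols = {int(a): j for j, a in enumerate(self.alleles)}
        for a in freq_matrix.columns:
            if int(a) in cols:
                mat[:, cols[int(a)]] = freq_matrix[a].to_numpy()
        scores = (mat - self.center) @ self.loadings
        return pd.Series(scores, index=freq_matrix.index), unseen


def locus_pca(freq_matrix: pd.DataFrame, latitudes: pd.Series, locus: str = "") -> LocusPCA:
    """PC1 of the centered ancestral population x allele frequency matrix.

    ``freq_matrix``: populations x alleles (rows indexed by population id,
    columns by integer allele label); ``latitudes``: per population.
    """
    if freq_matrix.shape[0] < 4:
        raise ValueError("need >= 4 ancestral populations")
    if freq_matrix.shape[1] < 2:
        raise ValueError("need >= 2 alleles")
    lat = latitudes.reindex(freq_matrix.index).to_numpy(dtype=float)
    x = freq_matrix.to_numpy(dtype=float)
    center = x.mean(axis=0)
    xc = x - center
    u, s_vals, vt = np.linalg.svd(xc, full_matrices=False)
    degenerate = bool(s_vals[0] < 1e-12)
    load = vt[0]
    scores = xc @ load
    # orient so the score-latitude correlation is >= 0 (ties keep sign as is)
    if np.std(scores) > 0 and np.std(lat) > 0:
        if np.corrcoef(scores, lat)[0, 1] < 0:
            load, scores = -load, -scores
    total = float(np.sum(s_vals**2))
    return LocusPCA(
        locus=locus,
        alleles=[int(a) for a in freq_matrix.columns],
        loadings=load,
        center=center,
        scores=pd.Series(scores, index=freq_matrix.index),
        var_explained=float(s_vals[0] ** 2 / total) if total > 0 else 0.0,
        latitudes=latitudes.reindex(freq_matrix.index),
        degenerate=degenerate,
    )


def detect_clinal_loci(
    pcas: list[LocusPCA], r_threshold: float = 0.8, alpha: float = 0.05
) -> pd.DataFrame:
    """Flag 'major clinal' loci: |Pearson r(PC1, latitude)| >= r_threshold
    and p <= alpha."""
    rows = []
    for pca in pcas:
        if len(pca.scores) < 4:
            raise ValueError("need >= 4 populations")
        lat = pca.latitudes.to_numpy(dtype=float)
        sc = pca.scores.to_numpy()
        if pca.degenerate or np.std(sc) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(sc, lat)
        rows.append(
            {
                "locus": pca.locus,
                "r": float(r),
                "p": float(p),
                "clinal": bool(abs(r) >= r_threshold and p <= alpha),
                "var_explained": pca.var_explained,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ClinalCall:
    locus: str
    taxon: str
    mean_score: float
    ci_low: float
    ci_high: float
    band_low: float
    band_high: float
    classification: str  # northern-like | southern-like | mid-latitude
    unseen_alleles: list[int] = field(default_factory=list)
    ci_degenerate: bool = False


def _ancestral_band(pca: LocusPCA, lat_range: tuple[float, float], alpha: float = 0.05):
    """95% mean-prediction band of ancestral PC1 score regressed on latitude,
    taken over a latitude interval."""
    lat = pca.latitudes.to_numpy(dtype=float)
    y = pca.scores.to_numpy()
    xs = np.linspace(lat_range[0], lat_range[1], 25)
    model = sm.OLS(y, sm.add_constant(lat, has_constant="add")).fit()
    pred = model.get_prediction(sm.add_constant(xs, has_constant="add"))
    ci = pred.conf_int(alpha=alpha)
    return float(ci[:, 0].min()), float(ci[:, 1].max())


def project_and_classify(
    pca: LocusPCA,
    derived_freqs: pd.DataFrame,
    derived_latitudes: pd.Series,
    taxon: str = "",
    ci_reps: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ClinalCall:
    """Project derived-taxon populations onto one ancestral locus axis and
    classify by CI overlap with the ancestral latitude band.

    The taxon mean score gets a percentile bootstrap CI over populations when
    >= 3 are scored, a normal-approximation CI for 2, and a degenerate
    (flagged) point interval for a single population.
    """
    scores, unseen = pca.project(derived_freqs)
    if scores.empty:
        raise ValueError("derived taxon has no scored populations at this locus")
    vals = scores.to_numpy()
    mean = float(vals.mean())
    degenerate_ci = False
    if len(vals) >= 3:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(vals), size=(ci_reps, len(vals)))
        boots = vals[idx].mean(axis=1)
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    elif len(vals) == 2:
        se = vals.std(ddof=1) / np.sqrt(2)
        z = stats.norm.ppf(1 - alpha / 2)
        lo, hi = mean - z * se, mean + z * se
    else:
        lo = hi = mean
        degenerate_ci = True
    lat = derived_latitudes.reindex(scores.index).to_numpy(dtype=float)
    band_lo, band_hi = _ancestral_band(pca, (float(lat.min()), float(lat.max())), alpha)
    if lo > band_hi:
        cls = "northern-like"
    elif hi < band_lo:
        cls = "southern-like"
    else:
        cls = "mid-latitude"
    return ClinalCall(
        locus=pca.locus,
        taxon=taxon,
        mean_score=mean,
        ci_low=float(lo),
        ci_high=float(hi),
        band_low=band_lo,
        band_high=band_hi,
        classification=cls,
        unseen_alleles=unseen,
        ci_degenerate=degenerate_ci,
    )
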