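"""Synthetic microsatellite datasets with the structure the analyses assume.

Three generators are provided:

* a deterministic two-island recursion (migration at symmetric gross rate m,
  then viability selection with fitnesses 1, 1-h*s, 1-s on each deme's locally
  favored allele class) iterated to a stable fixed point — the oracle against
  which the selection solver is checked;
* a finite-N Wright-Fisher version of the same model with multi-allelic loci,
  stepwise mutation (label steps of +/-2 bp, dinucleotide repeats), and
  diploid sampling of individuals;
* latitudinal-cline and whole-radiation fixtures: ~33 populations from 6
  host-associated taxa at 19 loci, with clines in the ancestral taxon,
  sympatric pairs, and private alleles injected into derived taxa.

All randomness flows from explicit seeds; the same seed yields a
byte-identical dataset.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, PopulationMeta, attach_metadata

__all__ = [
    "TwoIslandConfig",
    "ClineConfig",
    "iterate_two_island_deterministic",
    "simulate_two_island",
    "simulate_cline",
    "make_radiation_fixture",
    "RadiationFixture",
    "STUDY_POPULATIONS",
]


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, state=None):
        super().__init__(msg)
        self.state = state


@dataclass
class TwoIslandConfig:
    """Two demes exchanging migrants at symmetric gross rate m, with per-locus
    antagonistic selection: in deme 1 the tracked allele class is favored with
    coefficient s_l, in deme 2 the complementary class is favored with the
    same s_l.  ``n_e`` is the diploid size per deme (None for the
    deterministic recursion, which requires mu = 0)."""

    m: float
    s: np.ndarray  # per-locus selection coefficients, >= 0
    h: float = 0.5
    n_e: int | None = None
    mu: float = 0.0
    generations: int = 1000
    p_init: tuple[float, float] = (0.5, 0.5)  # tracked-class start freq per deme
    n_sample: int = 50
    alleles_per_class: int = 2
    step_bp: int = 2
    order: str = "migration_first"
    seed: int = 0

    def __post_init__(self) -> None:
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        if not 0.0 <= self.m <= 0.5:
            raise ValueError("m must be in [0, 0.5]")
        if (self.s < 0).any():
            raise ValueError("selection coefficients must be >= 0")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must be in [0, 1]")
        if self.n_e is None and self.mu != 0.0:
            raise ValueError("deterministic mode requires mu = 0")
        if self.order not in ("migration_first", "selection_first"):
            raise ValueError(f"unknown life-cycle order {self.order!r}")

    def to_yaml(self, path) -> None:
        import yaml

        raw = {k: (list(map(float, v)) if isinstance(v, np.ndarray) else v)
               for k, v in self.__dict__.items()}
        raw["p_init"] = list(self.p_init)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TwoIslandConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["s"] = np.asarray(raw["s"], dtype=float)
        raw["p_init"] = tuple(raw["p_init"])
        return cls(**raw)


def _sel_update(p: np.ndarray, s: np.ndarray, h: float) -> np.ndarray:
    """One generation of viability selection favoring the tracked class."""
    q = 1.0 - p
    wbar = p**2 + 2 * p * q * (1 - h * s) + q**2 * (1 - s)
    return (p**2 + p * q * (1 - h * s)) / wbar


def iterate_two_island_deterministic(
    p1: float | np.ndarray,
    p2: float | np.ndarray,
    cfg: TwoIslandConfig,
    order: str | None = None,
    tol: float = 1e-12,
    max_generations: int = 2_000_000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the deterministic recursion to a fixed point.

    Tracks the frequency of the class favored in deme 1.  Deme 2's selection
    favors the complementary class with the same coefficient.  Returns
    (p1*, p2*, generations used); raises ConvergenceError (carrying the last
    state) if ``max_generations`` is exceeded.
    """
    order = order or cfg.order
    p1 = np.atleast_1d(np.asarray(p1, dtype=float)).copy()
    p2 = np.atleast_1d(np.asarray(p2, dtype=float)).copy()
    s, h, m = cfg.s, cfg.h, cfg.m
    for gen in range(1, max_generations + 1):
        if order == "migration_first":
            n1 = (1 - m) * p1 + m * p2
            n2 = (1 - m) * p2 + m * p1
            n1 = _sel_update(n1, s, h)
            n2 = 1.0 - _sel_update(1.0 - n2, s, h)
        else:
            n1 = _sel_update(p1, s, h)
            n2 = 1.0 - _sel_update(1.0 - p2, s, h)
            n1, n2 = (1 - m) * n1 + m * n2, (1 - m) * n2 + m * n1
        delta = max(np.abs(n1 - p1).max(), np.abs(n2 - p2).max())
        p1, p2 = n1, n2
        if delta < tol:
            return p1, p2, gen
    raise ConvergenceError(
        f"no fixed point within {max_generations} generations", state=(p1, p2)
    )


def _class_marginal_fitness(p: float, s: float, h: float, favored: bool) -> tuple[float, float]:
    """Marginal fitnesses (w_tracked, w_other) given tracked-class freq p."""
    q = 1.0 - p
    if favored:  # tracked class favored
        w_t = p * 1.0 + q * (1 - h * s)
        w_o = p * (1 - h * s) + q * (1 - s)
    else:
        w_t = p * (1 - s) + q * (1 - h * s)
        w_o = p * (1 - h * s) + q * 1.0
    return w_t, w_o


def simulate_two_island(cfg: TwoIslandConfig) -> tuple[GenotypeTable, dict]:
    """Wright-Fisher two-island simulation with multi-allelic stepwise loci.

    Each locus carries ``alleles_per_class`` alleles per selection class;
    selection acts on class genotypes, drift is multinomial over alleles, and
    stepwise mutation moves a gene copy +/- one repeat (2 bp by default),
    the mutant inheriting its parent's class.  Emits diploid genotypes of
    ``n_sample`` individuals per deme (sampled without replacement from the
    final generation's gene copies) plus a true-parameter record.
    """
    if cfg.n_e is None:
        raise ValueError("finite n_e required; use iterate_two_island_deterministic")
    rng = np.random.default_rng(cfg.seed)
    L = len(cfg.s)
    two_n = 2 * cfg.n_e
    k = cfg.alleles_per_class
    loci = [f"L{i + 1:02d}" for i in range(L)]

    # per locus: labels (2k,), class mask (True = tracked class), counts per deme
    labels: list[np.ndarray] = []
    is_tracked: list[np.ndarray] = []
    counts = [[], []]  # deme -> list of count arrays
    for i in range(L):
        base = 100 + 40 * i if 100 + 40 * i + 4 * k < 1000 else 100
        lab = base + cfg.step_bp * np.arange(2 * k)
        tracked = np.zeros(2 * k, dtype=bool)
        tracked[:k] = True
        labels.append(lab.astype(np.int64))
        is_tracked.append(tracked)
        for d, p0 in enumerate(cfg.p_init):
            w = np.where(tracked, p0 / k, (1 - p0) / k)
            counts[d].append(rng.multinomial(two_n, w))

    def step_locus(i: int) -> None:
        f = [counts[0][i] / two_n, counts[1][i] / two_n]
        tr = is_tracked[i]
        s, h = float(cfg.s[i]), cfg.h

        def migrate(f):
            return [(1 - cfg.m) * f[0] + cfg.m * f[1], (1 - cfg.m) * f[1] + cfg.m * f[0]]

        def select(f):
            out = []
            for d in range(2):
                p = float(f[d][tr].sum())
                w_t, w_o = _class_marginal_fitness(p, s, h, favored=(d == 0))
                w = np.where(tr, w_t, w_o)
                g = f[d] * w
                out.append(g / g.sum())
            return out

        if cfg.order == "migration_first":
            f = select(migrate(f))
        else:
            f = migrate(select(f))
        for d in range(2):
            c = rng.multinomial(two_n, f[d] / f[d].sum())
            if cfg.mu > 0:
                n_mut = rng.binomial(c, cfg.mu)
                if n_mut.sum():
                    c = c - n_mut
                    up = rng.binomial(n_mut, 0.5)
                    down = n_mut - up
                    for j in np.nonzero(n_mut)[0]:
                        for delta, cnt in ((1, up[j]), (-1, down[j])):
                            if cnt == 0:
                                continue
                            new_label = labels[i][j] + delta * cfg.step_bp
                            pos = np.nonzero(labels[i] == new_label)[0]
                            if pos.size:
                                c[pos[0]] += cnt
                            else:
                                labels[i] = np.append(labels[i], new_label)
                                is_tracked[i] = np.append(is_tracked[i], tr[j])
                                c = np.append(c, cnt)
                                for dd in range(2):
                                    if counts[dd][i].size < c.size and dd != d:
                                        counts[dd][i] = np.append(counts[dd][i], 0)
                                tr = is_tracked[i]
            counts[d][i] = c
            if c.size < labels[i].size:  # other deme grew the allele list
                counts[d][i] = np.append(c, np.zeros(labels[i].size - c.size, dtype=c.dtype))

    for _ in range(cfg.generations):
        for i in range(L):
            step_locus(i)

    # sample diploid individuals without replacement from final gene copies
    n = cfg.n_sample
    ids, pops, calls = [], [], np.zeros((2 * n, L, 2), dtype=np.int64)
    for d in range(2):
        for ind in range(n):
            ids.append(f"d{d + 1}_i{ind + 1:03d}")
            pops.append(f"deme{d + 1}")
    for i in range(L):
        for d in range(2):
            pool = np.repeat(labels[i][: counts[d][i].size], counts[d][i])
            draw = rng.choice(pool.size, size=2 * n, replace=False)
            picked = pool[draw]
            calls[d * n : (d + 1) * n, i, 0] = picked[0::2]
            calls[d * n : (d + 1) * n, i, 1] = picked[1::2]

    table = GenotypeTable(ids, pops, loci, calls)
    truth = {
        "m": cfg.m,
        "h": cfg.h,
        "n_e": cfg.n_e,
        "mu": cfg.mu,
        "seed": cfg.seed,
        "s": [float(v) for v in cfg.s],
        "order": cfg.order,
        "generations": cfg.generations,
        "final_class_freq": {
            f"deme{d + 1}": [
                float(counts[d][i][is_tracked[i][: counts[d][i].size]].sum() / two_n)
                for i in range(L)
            ]
            for d in range(2)
        },
        "loci": loci,
    }
    return table, truth


def save_two_island_run(table: GenotypeTable, truth: dict, prefix) -> tuple[str, str]:
    """Write a simulated dataset as genotype CSV plus a true-parameters JSON
    sidecar (s, m, N_e, mu, seed, final class frequencies per locus)."""
    import json
    from pathlib import Path

    from .genotypes import write_genotypes_csv

    prefix = Path(prefix)
    geno = prefix.with_suffix(".genotypes.csv")
    sidecar = prefix.with_suffix(".truth.json")
    write_genotypes_csv(table, geno)
    sidecar.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return str(geno), str(sidecar)


# ---------------------------------------------------------------------------
# Latitudinal clines


@dataclass
class ClineConfig:
    """Demes along a latitude axis; clinal loci interpolate the frequency of a
    'northern' allele linearly between endpoint frequencies, non-clinal loci
    share one frequency across demes."""

    latitudes: list[float]
    clinal_loci: dict[str, tuple[float, float]]  # locus -> (freq at north end, at south end)
    neutral_loci: dict[str, float] = field(default_factory=dict)  # locus -> shared freq
    n_per_deme: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        lat = np.asarray(self.latitudes, dtype=float)
        if len(lat) < 5:
            raise ValueError("need >= 5 demes")
        d = np.diff(lat)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("latitudes must be strictly monotone along the axis")


def simulate_cline(cfg: ClineConfig) -> GenotypeTable:
    rng = np.random.default_rng(cfg.seed)
    lat = np.asarray(cfg.latitudes, dtype=float)
    lo, hi = lat.min(), lat.max()
    loci = list(cfg.clinal_loci) + list(cfg.neutral_loci)
    n = cfg.n_per_deme
    n_ind = n * len(lat)
    calls = np.zeros((n_ind, len(loci), 2), dtype=np.int64)
    ids, pops, metas = [], [], []
    for d, la in enumerate(lat):
        pop = f"deme{d + 1:02d}"
        metas.append(PopulationMeta(population=pop, taxon="cline", latitude=la, n=n))
        for i in range(n):
            ids.append(f"{pop}_i{i + 1:03d}")
            pops.append(pop)
    for j, locus in enumerate(loci):
        base = 100 + 6 * j
        for d, la in enumerate(lat):
            if locus in cfg.clinal_loci:
                f_n, f_s = cfg.clinal_loci[locus]
                t = (la - lo) / (hi - lo) if hi > lo else 0.0
                p = f_s + (f_n - f_s) * t
            else:
                p = cfg.neutral_loci[locus]
            draws = rng.random((n, 2)) < p
            calls[d * n : (d + 1) * n, j, :] = np.where(draws, base, base + 2)
    table = GenotypeTable(ids, pops, loci, calls)
    return attach_metadata(table, metas)


# ---------------------------------------------------------------------------
# Whole-radiation fixture

# Sampling frame of the study system: 33 host-associated populations from 6
# taxa (latitude/longitude in decimal degrees, n = individuals genotyped).
STUDY_POPULATIONS = """\
population,taxon,host,site,latitude,longitude,year,n,pair
p01,hawthorn,downy hawthorn,Newaygo Co. MI,43.35,85.9,2002,48,a
p02,hawthorn,downy hawthorn,Allegan Co. MI,42.6,86.15,2002,96,b
p03,hawthorn,downy hawthorn,Cass Co. MI,41.88,86.23,2002,49,d
p04,hawthorn,downy hawthorn,Champaign Co. IL,40.08,88.23,2002,46,c
p05,hawthorn,downy hawthorn,New Madrid Co. MO,36.53,89.43,2008,41,
p06,hawthorn,green hawthorn,Caldwell Pr. LA,32.04,91.55,2007,48,
p07,hawthorn,green hawthorn,La Salle Pr. LA,31.27,92.07,2009,56,e
p08,hawthorn,green hawthorn,Fort Bend Co. TX,29.22,95.36,2007,98,
p09,hawthorn,mayhaw,Nacogdoches Co. TX,31.31,94.46,2006,94,f
p10,hawthorn,mayhaw,La Salle Pr. LA,31.27,92.07,2009,40,e
p11,hawthorn,blueberry hawthorn,Nacogdoches Co. TX,31.31,94.46,2008,47,
p12,hawthorn,blueberry hawthorn,Angelina Co. TX,31.21,94.45,2010,49,f
p13,hawthorn,black hawthorn,Clark Co. WA,45.7,122.63,2009,39,
p14,hawthorn,black hawthorn,Skamania Co. WA,45.6,122.11,2009,47,g
p15,apple,apple,Newaygo Co. MI,43.35,85.9,2002,47,a
p16,apple,apple,Allegan Co. MI,42.6,86.15,2002,96,
p17,apple,apple,Cass Co. MI,41.88,86.23,2002,47,
p18,apple,apple,Champaign Co. IL,40.08,88.23,2002,48,
p19,apple,apple,Clark Co. WA,45.7,122.63,2009,48,
p20,apple,apple,Skamania Co. WA,45.6,122.11,2009,105,
p21,dogwood_fly,flowering dogwood,Cass Co. MI,42.0,85.97,2006,36,d
p22,dogwood_fly,flowering dogwood,Lake Co. TN,36.45,89.3,2010,40,
p23,dogwood_fly,flowering dogwood,Nacogdoches Co. TX,31.31,94.46,2007,39,
p24,mendax,blueberry,Allegan Co. MI,42.6,86.15,2007,32,b
p25,mendax,blueberry,Burlington Co. NJ,39.82,74.53,2006,32,
p26,mendax,deerberry,Aiken Co. SC,33.54,81.49,2009,26,
p27,mendax,deerberry,Richland Co. SC,34.08,80.9,2009,32,
p28,zephyria,snowberry,Clark Co. WA,45.73,122.63,2009,48,
p29,zephyria,snowberry,Skamania Co. WA,45.6,122.11,2009,72,g
p30,zephyria,snowberry,Etobicoke ON,43.58,79.54,2011,59,
p31,zephyria,snowberry,Musselshell Co. MT,46.57,107.94,1994,29,
p32,zephyria,snowberry,Polk Co. MN,47.52,96.28,1994,29,
p33,cornivora,silky dogwood,Champaign Co. IL,40.08,88.23,2001,34,c
"""

LOCI = [
    "p71", "p37", "p4", "p3", "p46", "p73", "p70", "p80", "p7", "p16",
    "p23", "p66", "p11", "p29", "p50", "p60", "p18", "p9", "p27",
]
CLINAL_LOCI = ["p71", "p37", "p70", "p80", "p16", "p7", "p23"]

# Private-allele injections: taxon -> locus -> taxon-wide design frequency.
PRIVATE_DESIGN = {
    "mendax": {"p71": 0.076, "p4": 0.104, "p70": 0.034, "p7": 0.187, "p11": 0.027},
    "zephyria": {
        "p37": 0.084, "p3": 0.236, "p46": 0.091, "p73": 0.036, "p80": 0.051,
        "p7": 0.746, "p23": 0.402, "p18": 0.124, "p27": 0.137,
    },
    "cornivora": {
        "p71": 0.219, "p4": 0.656, "p3": 1.0, "p46": 0.75, "p73": 0.241,
        "p70": 0.339, "p7": 0.167, "p16": 0.353, "p23": 0.303, "p29": 0.912,
        "p60": 0.054, "p18": 0.594, "p9": 1.0, "p27": 0.375,
    },
}

# Sympatric pairs (ancestral population, derived population, assumed gross m).
SYMPATRIC_PAIRS = [
    ("apple_vs_downy_hawthorn", "p01", "p15", 0.045),
    ("mendax_vs_downy_hawthorn", "p02", "p24", 0.02),
    ("cornivora_vs_downy_hawthorn", "p04", "p33", 0.01),
    ("dogwood_fly_vs_downy_hawthorn", "p03", "p21", 0.03),
    ("mayhaw_vs_green_hawthorn", "p07", "p10", 0.05),
    ("blueberry_hawthorn_vs_mayhaw", "p09", "p12", 0.04),
    ("zephyria_vs_black_hawthorn", "p14", "p29", 0.01),
]

# Per-locus clinal placement of the derived taxa ("north", "south", "mid").
MOSAIC_DESIGN = {
    "dogwood_fly": {
        "p71": "south", "p37": "south", "p70": "mid", "p80": "south",
        "p16": "south", "p7": "south", "p23": "north",
    },
    "mendax": {
        "p71": "mid", "p37": "mid", "p70": "north", "p80": "mid",
        "p16": "south", "p7": "north", "p23": "north",
    },
    "zephyria": {
        "p71": "mid", "p37": "north", "p70": "north", "p80": "south",
        "p16": "north", "p7": "north", "p23": "north",
    },
    "cornivora": {
        "p71": "north", "p37": "north", "p70": "north", "p80": "mid",
        "p16": "north", "p7": "north", "p23": "mid",
    },
}

_LAT_S, _LAT_N = 29.0, 46.6  # latitude range spanned by the sampling frame


@dataclass
class RadiationFixture:
    table: GenotypeTable
    design_freqs: dict[tuple[str, str], dict[int, float]]
    private_loci: dict[str, dict[str, int]]  # taxon -> locus -> private allele label
    clinal_loci: list[str]
    pairs: list[tuple[str, str, str, float]]
    seed: int


def _north_freq(lat: float) -> float:
    t = (lat - _LAT_S) / (_LAT_N - _LAT_S)
    return float(np.clip(0.08 + 0.84 * t, 0.05, 0.95))


def _clinal_freqs(base: int, lat: float) -> dict[int, float]:
    p = _north_freq(lat)
    return {base: 0.94 * p, base + 2: 0.94 * (1 - p), base + 4: 0.06}


def make_radiation_fixture(seed: int = 1) -> RadiationFixture:
    """Deterministic-for-seed whole-study synthetic dataset.

    33 populations / 6 taxa / 19 loci with the sampling frame's latitudes and
    sample sizes; 7 clinal loci in the ancestral (hawthorn) taxon; derived
    taxa placed on the ancestral clines per a locus-by-locus mosaic design;
    private alleles injected into mendax (5 loci), zephyria (9), and
    cornivora (14); sympatric pair structure preserved.
    """
    rng = np.random.default_rng(seed)
    meta_df = pd.read_csv(io.StringIO(STUDY_POPULATIONS))
    base_of = {locus: 100 + 8 * j for j, locus in enumerate(LOCI)}
    mid_lat = 0.5 * (_LAT_S + _LAT_N)

    # shared non-clinal frequency profiles (4 alleles each), one per locus
    neutral_profiles: dict[str, dict[int, float]] = {}
    for locus in LOCI:
        if locus in CLINAL_LOCI:
            continue
        w = rng.dirichlet([5.0, 4.0, 2.0, 1.0])
        w = 0.9 * w / w.sum() + 0.025  # keep every allele common enough to be seen
        b = base_of[locus]
        neutral_profiles[locus] = {b + 2 * k: float(w[k]) for k in range(4)}

    # divergence at non-clinal loci: shift mass between the two commonest
    # alleles; magnitude grows along the divergence continuum.  The unit of
    # divergence is the taxon, except within hawthorn where the host races
    # (downy reference, southern and western hosts) diverge weakly.
    shift_of = {
        "downy hawthorn": 0.0, "green hawthorn": 0.05, "mayhaw": 0.09,
        "blueberry hawthorn": 0.05, "black hawthorn": 0.06,
        "apple": 0.06, "dogwood_fly": 0.22, "mendax": 0.32,
        "zephyria": 0.42, "cornivora": 0.42,
    }
    shift_dir = {u: rng.choice([-1, 1], size=len(LOCI)) for u in shift_of}

    def divergence_unit(taxon: str, host: str) -> str:
        return host if taxon == "hawthorn" else taxon

    def pop_freqs(row) -> dict[str, dict[int, float]]:
        taxon, lat = row.taxon, float(row.latitude)
        out: dict[str, dict[int, float]] = {}
        for j, locus in enumerate(LOCI):
            b = base_of[locus]
            if locus in CLINAL_LOCI:
                if taxon in ("hawthorn", "apple"):
                    eff_lat = lat
                else:
                    place = MOSAIC_DESIGN[taxon][locus]
                    eff_lat = {"north": _LAT_N, "south": _LAT_S, "mid": mid_lat}[place]
                fm = _clinal_freqs(b, eff_lat)
            else:
                fm = dict(neutral_profiles[locus])
                unit = divergence_unit(taxon, row.host)
                shift = shift_of[unit]
                if shift > 0.0:
                    keys = sorted(fm, key=fm.get, reverse=True)[:2]
                    a, c = (keys if shift_dir[unit][j] > 0 else keys[::-1])
                    moved = min(shift, fm[c] - 0.01)
                    fm[a] += moved
                    fm[c] -= moved
            # private-allele injection
            priv = PRIVATE_DESIGN.get(taxon, {})
            if locus in priv:
                fp = priv[locus]
                fm = {al: f * (1 - fp) for al, f in fm.items()}
                fm[b + 101] = fp  # odd offset: label unreachable by 2-bp steps
            out[locus] = fm
        return out

    ids, pops, calls_rows, metas = [], [], [], []
    design: dict[tuple[str, str], dict[int, float]] = {}
    for row in meta_df.itertuples(index=False):
        freqs = pop_freqs(row)
        for locus, fm in freqs.items():
            design[(row.population, locus)] = fm
        n = int(row.n)
        metas.append(
            PopulationMeta(
                population=row.population, taxon=row.taxon, host=row.host,
                site=row.site, latitude=float(row.latitude),
                longitude=float(row.longitude), year=int(row.year), n=n,
            )
        )
        geno = np.zeros((n, len(LOCI), 2), dtype=np.int64)
        for j, locus in enumerate(LOCI):
            fm = freqs[locus]
            alleles = np.array(sorted(fm), dtype=np.int64)
            p = np.array([fm[a] for a in alleles])
            p = p / p.sum()
            geno[:, j, :] = alleles[rng.choice(alleles.size, size=(n, 2), p=p)]
        calls_rows.append(geno)
        for i in range(n):
            ids.append(f"{row.population}_i{i + 1:03d}")
            pops.append(row.population)

    table = GenotypeTable(ids, pops, list(LOCI), np.concatenate(calls_rows, axis=0))
    attach_metadata(table, metas)
    private_loci = {
        taxon: {locus: base_of[locus] + 101 for locus in d}
        for taxon, d in PRIVATE_DESIGN.items()
    }
    return RadiationFixture(
        table=table,
        design_freqs=design,
        private_loci=private_loci,
        clinal_loci=list(CLINAL_LOCI),
        pairs=list(SYMPATRIC_PAIRS),
        seed=seed,
    )
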