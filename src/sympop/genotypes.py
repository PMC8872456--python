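"""Diploid microsatellite genotype tables, GENEPOP/CSV readers and writers,
allele-frequency estimation, and the within-population inbreeding coefficient F_IS.

Allele labels are raw fragment lengths in base pairs (positive integers);
``0`` is the missing sentinel.  Any call containing a 0 code is treated as
wholly missing, following the GENEPOP convention.  The two alleles of a call
are unordered for every statistic in this package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0


class GenotypeParseError(ValueError):
    """Malformed genotype input; carries the offending line number."""


@dataclass
class PopulationMeta:
    """Per-population sampling metadata (host, site, coordinates, sample size)."""

    population: str
    taxon: str = ""
    host: str = ""
    site: str = ""
    latitude: float = float("nan")
    longitude: float = float("nan")
    year: int | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if not np.isnan(self.latitude) and not (0.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} outside [0, 90]")


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with population metadata.

    ``calls`` is an integer array of shape (n_individuals, n_loci, 2) holding
    fragment lengths in bp, with 0 for missing.
    """

    individual_ids: list[str]
    population_ids: list[str]  # per individual, parallel to individual_ids
    loci: list[str]
    calls: np.ndarray
    populations: list[PopulationMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        if len(self.population_ids) != n:
            raise ValueError("population_ids length mismatch")
        if (self.calls < 0).any():
            raise ValueError("allele labels must be non-negative integers")
        # a call with either allele missing is wholly missing
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING
        if not self.populations:
            seen: dict[str, int] = {}
            for p in self.population_ids:
                seen[p] = seen.get(p, 0) + 1
            self.populations = [PopulationMeta(population=p, n=c) for p, c in seen.items()]

    @property
    def population_order(self) -> list[str]:
        out: list[str] = []
        for p in self.population_ids:
            if p not in out:
                out.append(p)
        return out

    def meta(self, population: str) -> PopulationMeta:
        for m in self.populations:
            if m.population == population:
                return m
        raise KeyError(population)

    def subset(self, populations: list[str]) -> "GenotypeTable":
        keep = [i for i, p in enumerate(self.population_ids) if p in set(populations)]
        return GenotypeTable(
            individual_ids=[self.individual_ids[i] for i in keep],
            population_ids=[self.population_ids[i] for i in keep],
            loci=list(self.loci),
            calls=self.calls[keep].copy(),
            populations=[m for m in self.populations if m.population in set(populations)],
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, (ind, pop) in enumerate(zip(self.individual_ids, self.population_ids)):
            for j, locus in enumerate(self.loci):
                a, b = self.calls[i, j]
                rows.append((ind, pop, locus, int(a), int(b)))
        return pd.DataFrame(rows, columns=["individual", "population", "locus", "allele1", "allele2"])


@dataclass
class AlleleFrequencyTable:
    """Per (group, locus): allele -> frequency plus the gene-copy count N.

    Groups are populations or taxa depending on how the table was built.
    Entries with N == 0 are retained with an empty frequency map and listed
    in ``undefined`` rather than silently reported as zeros.
    """

    groups: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[int, float]]
    n_copies: dict[tuple[str, str], int]
    undefined: set[tuple[str, str]] = field(default_factory=set)

    def freq(self, group: str, locus: str) -> dict[int, float]:
        return self.freqs[(group, locus)]

    def n(self, group: str, locus: str) -> int:
        return self.n_copies[(group, locus)]

    def alleles(self, locus: str, groups: list[str] | None = None) -> list[int]:
        out: set[int] = set()
        for g in groups if groups is not None else self.groups:
            out.update(self.freqs.get((g, locus), {}))
        return sorted(out)

    def matrix(self, locus: str, groups: list[str] | None = None) -> pd.DataFrame:
        """Groups x alleles frequency matrix at one locus (absent alleles are 0)."""
        groups = list(groups) if groups is not None else list(self.groups)
        alleles = self.alleles(locus, groups)
        mat = np.zeros((len(groups), len(alleles)))
        for i, g in enumerate(groups):
            fm = self.freqs.get((g, locus), {})
            for j, a in enumerate(alleles):
                mat[i, j] = fm.get(a, 0.0)
        return pd.DataFrame(mat, index=groups, columns=alleles)

    def validate(self, tol: float = 1e-9) -> None:
        for key, fm in self.freqs.items():
            n = self.n_copies[key]
            if n > 0 and abs(sum(fm.values()) - 1.0) > tol:
                raise ValueError(f"frequencies at {key} sum to {sum(fm.values())}")
            if n % 2:
                raise ValueError(f"gene-copy count at {key} is odd")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (g, l), fm in sorted(self.freqs.items()):
            n = self.n_copies[(g, l)]
            if not fm:
                rows.append((g, l, MISSING, float("nan"), n))
            for a in sorted(fm):
                rows.append((g, l, a, fm[a], n))
        return pd.DataFrame(rows, columns=["population", "locus", "allele", "frequency", "N"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleFrequencyTable":
        groups = list(dict.fromkeys(df["population"]))
        loci = list(dict.fromkeys(df["locus"]))
        freqs: dict[tuple[str, str], dict[int, float]] = {}
        n_copies: dict[tuple[str, str], int] = {}
        undefined: set[tuple[str, str]] = set()
        for (g, l), sub in df.groupby(["population", "locus"], sort=False):
            key = (str(g), str(l))
            n = int(sub["N"].iloc[0])
            fm = {
                int(a): float(f)
                for a, f in zip(sub["allele"], sub["frequency"])
                if int(a) != MISSING and np.isfinite(f)
            }
            freqs[key] = fm
            n_copies[key] = n
            if n == 0:
                undefined.add(key)
        return cls(groups=groups, loci=loci, freqs=freqs, n_copies=n_copies, undefined=undefined)


@dataclass
class FisEstimate:
    per_locus: dict[str, float]
    overall: float
    ci_low: float
    ci_high: float
    bootstrap_reps: int
    seed: int
    excluded_loci: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# GENEPOP I/O

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path, allele_map: dict[int, int] | None = None) -> GenotypeTable:
    """Read a GENEPOP file (2- or 3-digit allele codes).

    ``allele_map`` optionally maps allele codes to fragment lengths in bp
    (the sidecar for datasets whose fragments exceed the 3-digit range).
    Codes of all zeros denote missing data.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenotypeParseError("empty GENEPOP file (line 1)")
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        if not chunk:
            raise GenotypeParseError(f"blank locus line (line {i + 1})")
        loci.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenotypeParseError("no POP line found (malformed header)")

    digits: int | None = None
    individual_ids: list[str] = []
    population_ids: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    pop_idx = 0
    pop_first_ind: list[str] = []
    current_rows: list[int] = []

    def close_pop() -> None:
        nonlocal pop_idx
        if current_rows:
            name = individual_ids[current_rows[0]].rstrip()
            pop_first_ind.append(name)
            pop_idx += 1
            current_rows.clear()

    while i < len(lines):
        line = lines[i]
        i += 1
        if not line.strip():
            continue
        if _POP_RE.match(line):
            close_pop()
            continue
        if "," not in line:
            raise GenotypeParseError(f"genotype row without ',' separator (line {i})")
        ind_id, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenotypeParseError(
                f"expected {len(loci)} genotypes, found {len(tokens)} (line {i})"
            )
        row: list[tuple[int, int]] = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenotypeParseError(f"bad genotype code {tok!r} (line {i})")
            w = len(tok) // 2
            if digits is None:
                digits = w
            elif w != digits:
                raise GenotypeParseError(f"mixed allele-code widths (line {i})")
            a, b = int(tok[:w]), int(tok[w:])
            if allele_map is not None:
                a = allele_map.get(a, a) if a else 0
                b = allele_map.get(b, b) if b else 0
            row.append((a, b))
        individual_ids.append(ind_id.strip())
        population_ids.append(f"pop{pop_idx + 1}")
        current_rows.append(len(calls))
        calls.append(row)
    close_pop()

    # GENEPOP names populations by their first (or last) individual; use the
    # first individual's id when unique, else positional names.
    names = pop_first_ind if len(set(pop_first_ind)) == len(pop_first_ind) else None
    if names:
        remap = {f"pop{k + 1}": names[k] for k in range(len(names))}
        population_ids = [remap[p] for p in population_ids]
    return GenotypeTable(
        individual_ids=individual_ids,
        population_ids=population_ids,
        loci=loci,
        calls=np.array(calls, dtype=np.int64),
    )


def write_genepop(table: GenotypeTable, path, digits: int = 3, title: str = "sympop export") -> None:
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    hi = 10**digits - 1
    if int(table.calls.max(initial=0)) > hi:
        raise ValueError(
            f"allele label exceeds the {digits}-digit GENEPOP range; supply a code sidecar"
        )
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        for pop in table.population_order:
            fh.write("POP\n")
            for i, p in enumerate(table.population_ids):
                if p != pop:
                    continue
                codes = " ".join(
                    f"{a:0{digits}d}{b:0{digits}d}" for a, b in table.calls[i]
                )
                fh.write(f"{table.individual_ids[i]} , {codes}\n")


# ---------------------------------------------------------------------------
# Long CSV I/O

def read_genotypes_csv(path) -> GenotypeTable:
    """Long-format genotype CSV: individual, population, locus, allele1, allele2."""
    df = pd.read_csv(path)
    need = {"individual", "population", "locus", "allele1", "allele2"}
    if not need.issubset(df.columns):
        raise GenotypeParseError(f"genotype CSV missing columns {need - set(df.columns)}")
    loci = list(dict.fromkeys(df["locus"].astype(str)))
    inds = list(dict.fromkeys(zip(df["individual"].astype(str), df["population"].astype(str))))
    idx = {key: i for i, key in enumerate(inds)}
    lidx = {l: j for j, l in enumerate(loci)}
    calls = np.zeros((len(inds), len(loci), 2), dtype=np.int64)
    for r in df.itertuples(index=False):
        i = idx[(str(r.individual), str(r.population))]
        j = lidx[str(r.locus)]
        calls[i, j] = (int(r.allele1), int(r.allele2))
    return GenotypeTable(
        individual_ids=[k[0] for k in inds],
        population_ids=[k[1] for k in inds],
        loci=loci,
        calls=calls,
    )


def write_genotypes_csv(table: GenotypeTable, path) -> None:
    table.to_long_frame().to_csv(path, index=False)


def read_population_metadata(path) -> list[PopulationMeta]:
    """Population metadata CSV: population, taxon, host, site, latitude, longitude, year, n."""
    df = pd.read_csv(path)
    metas = []
    for r in df.itertuples(index=False):
        metas.append(
            PopulationMeta(
                population=str(r.population),
                taxon=str(getattr(r, "taxon", "")),
                host=str(getattr(r, "host", "")),
                site=str(getattr(r, "site", "")),
                latitude=float(getattr(r, "latitude", float("nan"))),
                longitude=float(getattr(r, "longitude", float("nan"))),
                year=int(r.year) if hasattr(r, "year") and pd.notna(r.year) else None,
                n=int(getattr(r, "n", 0)),
            )
        )
    return metas


def attach_metadata(table: GenotypeTable, metas: list[PopulationMeta]) -> GenotypeTable:
    by_pop = {m.population: m for m in metas}
    missing = [p for p in table.population_order if p not in by_pop]
    if missing:
        raise KeyError(f"metadata missing for populations {missing}")
    table.populations = [by_pop[p] for p in table.population_order]
    return table


# ---------------------------------------------------------------------------
# Statistics

def allele_frequencies(
    table: GenotypeTable, grouping: str = "population"
) -> AlleleFrequencyTable:
    """Allele frequencies per (group, locus) with gene-copy counts.

    grouping="population" groups by population id; "taxon" pools all
    populations of a taxon weighted by gene copies (i.e. raw pooled counts).
    """
    if grouping == "population":
        group_of = {p: p for p in table.population_order}
    elif grouping == "taxon":
        group_of = {m.population: m.taxon for m in table.populations}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    groups = list(dict.fromkeys(group_of[p] for p in table.population_order))
    ind_group = np.array([group_of[p] for p in table.population_ids])

    freqs: dict[tuple[str, str], dict[int, float]] = {}
    n_copies: dict[tuple[str, str], int] = {}
    undefined: set[tuple[str, str]] = set()
    for g in groups:
        sub = table.calls[ind_group == g]
        for j, locus in enumerate(table.loci):
            flat = sub[:, j, :].ravel()
            flat = flat[flat != MISSING]
            key = (g, locus)
            n_copies[key] = int(flat.size)
            if flat.size == 0:
                freqs[key] = {}
                undefined.add(key)
                continue
            vals, counts = np.unique(flat, return_counts=True)
            freqs[key] = {int(a): c / flat.size for a, c in zip(vals, counts)}
    return AlleleFrequencyTable(
        groups=groups, loci=list(table.loci), freqs=freqs, n_copies=n_copies, undefined=undefined
    )


def _locus_het(calls: np.ndarray) -> tuple[float, float, int] | None:
    """(H_obs, unbiased H_exp, n individuals) at one locus; None if monomorphic/empty."""
    ok = calls[:, 0] != MISSING
    sub = calls[ok]
    n = sub.shape[0]
    if n == 0:
        return None
    flat = sub.ravel()
    vals, counts = np.unique(flat, return_counts=True)
    if vals.size < 2:
        return None
    p = counts / flat.size
    h_exp = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2)))
    h_obs = float(np.mean(sub[:, 0] != sub[:, 1]))
    return h_obs, h_exp, n


def f_is(
    table: GenotypeTable,
    population: str,
    bootstrap_reps: int = 10_000,
    seed: int = 0,
) -> FisEstimate:
    """Inbreeding coefficient F_IS = 1 - H_obs/H_exp per locus and across loci.

    H_exp uses the small-sample (2n/(2n-1)) correction.  The across-loci value
    is one minus the ratio of summed observed to summed expected heterozygosity,
    and the 95% CI is a percentile bootstrap over loci.
    """
    mask = np.array(table.population_ids) == population
    if not mask.any():
        raise KeyError(population)
    calls = table.calls[mask]
    per_locus: dict[str, float] = {}
    excluded: list[str] = []
    hobs, hexp = [], []
    for j, locus in enumerate(table.loci):
        res = _locus_het(calls[:, j, :])
        if res is None:
            excluded.append(locus)
            continue
        ho, he, _ = res
        per_locus[locus] = 1.0 - ho / he
        hobs.append(ho)
        hexp.append(he)
    if len(hobs) < 2:
        raise ValueError("need >= 2 polymorphic loci for the across-loci estimate")
    hobs_a, hexp_a = np.array(hobs), np.array(hexp)
    overall = 1.0 - hobs_a.sum() / hexp_a.sum()
    rng = np.random.default_rng(seed)
    k = len(hobs)
    picks = rng.integers(0, k, size=(bootstrap_reps, k))
    boots = 1.0 - hobs_a[picks].sum(axis=1) / hexp_a[picks].sum(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FisEstimate(
        per_locus=per_locus,
        overall=float(overall),
        ci_low=float(lo),
        ci_high=float(hi),
        bootstrap_reps=bootstrap_reps,
        seed=seed,
        excluded_loci=excluded,
    )
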