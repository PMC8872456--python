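"""End-to-end orchestration: fixture or input data -> allele frequencies ->
diversity / differentiation / cline / selection / hybrid tables, with a
machine-readable run manifest.  Deterministic for fixed seeds."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, cline, distance, diversity, hybrids
from .genotypes import (
    GenotypeTable,
    allele_frequencies,
    attach_metadata,
    f_is,
    read_genotypes_csv,
    read_population_metadata,
)
from .selection import MigrationSelectionModel
from .simulate import make_radiation_fixture


@dataclass
class PairConfig:
    pair_id: str
    ancestral: str
    derived: str
    m: float


@dataclass
class PipelineConfig:
    output_dir: str = "sympop_out"
    genotypes_csv: str | None = None  # if None, the synthetic fixture is used
    metadata_csv: str | None = None
    seed: int = 1
    ancestral_taxon: str = "hawthorn"
    ancestral_taxa: list[str] = field(default_factory=lambda: ["hawthorn", "apple"])
    pairs: list[PairConfig] = field(default_factory=list)
    fis_reps: int = 2000
    bootstrap_reps: int = 200
    clinal_r_threshold: float = 0.8
    selection_convention: str = "compensatory"
    dominance: float = 0.5
    migration_prior: float = 0.01
    min_private_pops: int = 2
    run_hybrids: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pairs = [PairConfig(**p) for p in raw.pop("pairs", [])]
        return cls(pairs=pairs, **raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


def _load_table(cfg: PipelineConfig) -> tuple[GenotypeTable, list]:
    if cfg.genotypes_csv is None:
        fx = make_radiation_fixture(seed=cfg.seed)
        pairs = [PairConfig(pid, anc, der, m) for pid, anc, der, m in fx.pairs]
        return fx.table, cfg.pairs or pairs
    table = read_genotypes_csv(cfg.genotypes_csv)
    if cfg.metadata_csv:
        attach_metadata(table, read_population_metadata(cfg.metadata_csv))
    return table, cfg.pairs


def _validate(table: GenotypeTable, pairs: list[PairConfig]) -> None:
    pops = set(table.population_order)
    taxon_of = {m.population: m.taxon for m in table.populations}
    for p in pairs:
        for pop in (p.ancestral, p.derived):
            if pop not in pops:
                raise PipelineError("validate", f"pair {p.pair_id}: unknown population {pop}")
        if p.ancestral == p.derived:
            raise PipelineError("validate", f"pair {p.pair_id}: identical populations")
        ma, md = table.meta(p.ancestral), table.meta(p.derived)
        if (ma.taxon, ma.host) == (md.taxon, md.host):
            raise PipelineError(
                "validate",
                f"pair {p.pair_id}: populations share taxon and host "
                f"({ma.taxon!r}/{ma.host!r}); a pair must contrast an ancestral "
                "and a derived host association",
            )


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write CSV/Newick/JSON outputs; returns the paths."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, obj) -> None:
        path = out / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
        else:
            path.write_text(obj)
        written[name] = path

    table, pairs = _load_table(cfg)
    _validate(table, pairs)
    taxon_of = {m.population: m.taxon for m in table.populations}
    lat_of = {m.population: m.latitude for m in table.populations}

    # frequencies
    freqs = allele_frequencies(table, grouping="population")
    freqs.validate()
    emit("allele_frequencies.csv", freqs.to_frame())

    # F_IS per population
    fis_rows = []
    for k, pop in enumerate(table.population_order):
        est = f_is(table, pop, bootstrap_reps=cfg.fis_reps, seed=cfg.seed + k)
        fis_rows.append(
            {"population": pop, "f_is": est.overall, "ci_low": est.ci_low,
             "ci_high": est.ci_high, "n_loci": len(est.per_locus)}
        )
    emit("fis.csv", pd.DataFrame(fis_rows))

    # diversity: richness + private alleles
    rich = diversity.richness_by_population(freqs)
    rich["taxon"] = rich["population"].map(taxon_of)
    emit("richness.csv", rich)
    priv_frames = []
    ref = cfg.ancestral_taxa
    for taxon in sorted({t for t in taxon_of.values() if t not in set(ref)}):
        n_pops = sum(1 for t in taxon_of.values() if t == taxon)
        rep = diversity.private_alleles(
            freqs, taxon_of, taxon, ref, min_pops=min(cfg.min_private_pops, n_pops)
        )
        priv_frames.append(rep.to_frame())
    emit("private_alleles.csv", pd.concat(priv_frames, ignore_index=True))

    # differentiation: per-pair D_EST + NJ tree with supports
    dest_frames = []
    dest_results = {}
    for p in pairs:
        res = distance.dest_profile(freqs, p.ancestral, p.derived, pair_id=p.pair_id)
        dest_results[p.pair_id] = res
        df = res.per_locus.copy()
        df.insert(0, "pair", p.pair_id)
        dest_frames.append(df)
    emit("dest.csv", pd.concat(dest_frames, ignore_index=True))
    tree, _support = distance.bootstrap_support(
        freqs, reps=cfg.bootstrap_reps, seed=cfg.seed
    )
    emit("tree.nwk", str(tree))

    # clinal mosaic
    anc_pops = [p for p, t in taxon_of.items() if t == cfg.ancestral_taxon]
    latitudes = pd.Series(lat_of)
    pcas = []
    for locus in freqs.loci:
        mat = freqs.matrix(locus, anc_pops)
        pcas.append(cline.locus_pca(mat, latitudes, locus=locus))
    clin = cline.detect_clinal_loci(pcas, r_threshold=cfg.clinal_r_threshold)
    calls = []
    derived_taxa = sorted(
        {t for t in taxon_of.values() if t not in (cfg.ancestral_taxon, *cfg.ancestral_taxa)}
    )
    for pca, flag in zip(pcas, clin["clinal"]):
        if not flag:
            continue
        for taxon in derived_taxa:
            tpops = [p for p, t in taxon_of.items() if t == taxon]
            mat = freqs.matrix(pca.locus, tpops)
            call = cline.project_and_classify(
                pca, mat, latitudes, taxon=taxon, seed=cfg.seed
            )
            calls.append(
                {"locus": call.locus, "taxon": taxon, "mean_score": call.mean_score,
                 "ci_low": call.ci_low, "ci_high": call.ci_high,
                 "band_low": call.band_low, "band_high": call.band_high,
                 "classification": call.classification}
            )
    clin_out = clin.merge(pd.DataFrame(calls), on="locus", how="left") if calls else clin
    emit("clinal_report.csv", clin_out)

    # selection profiles + asymmetry tests
    sel_rows, test_rows = [], []
    for p in pairs:
        model = MigrationSelectionModel.from_frequencies(
            freqs, p.ancestral, p.derived, m=p.m, h=cfg.dominance, pair_id=p.pair_id
        )
        res = model.fit(convention=cfg.selection_convention)
        prof = res.profile.copy()
        prof.insert(0, "pair", p.pair_id)
        sel_rows.append(prof)
        tests = res.asymmetry_tests()
        test_rows.append({"pair": p.pair_id, "m": p.m, **{
            k: (v if not isinstance(v, tuple) else f"{v[0]},{v[1]}") for k, v in tests.items()
        }})
    emit("selection_profiles.csv", pd.concat(sel_rows, ignore_index=True))
    emit("selection_tests.csv", pd.DataFrame(test_rows))

    # hybrid posteriors (optional; leave-one-out scan over every pair member)
    if cfg.run_hybrids:
        hyb_frames = []
        for p in pairs:
            for natal, other in ((p.derived, p.ancestral), (p.ancestral, p.derived)):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    posts = hybrids.classify_individuals(
                        table, natal, other, migration_prior=cfg.migration_prior
                    )
                df = hybrids.posteriors_to_frame(posts)
                df.insert(0, "pair", p.pair_id)
                hyb_frames.append(df)
        emit("hybrid_posteriors.csv", pd.concat(hyb_frames, ignore_index=True))

    manifest = {
        "sympop_version": __version__,
        "seed": cfg.seed,
        "config": {**asdict(cfg), "pairs": [asdict(p) for p in pairs]},
        "n_individuals": len(table.individual_ids),
        "n_populations": len(table.population_order),
        "n_loci": len(table.loci),
        "outputs": sorted(written),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest.json"] = out / "manifest.json"
    return written
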