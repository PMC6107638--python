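"""End-to-end pipeline over a run directory, driven by one config.

Stages: simulate -> prep -> qc -> assoc (per callset) -> meta ->
conditional -> groups -> link -> abc -> burden -> extremes. Each stage
reads its inputs from and writes its outputs to the run directory, so
stages can be re-run individually; a run log records versions, seed,
thresholds and per-stage counts. All randomness flows from the single
config seed via named substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import lipidwgs
from lipidwgs import io as lio
from lipidwgs._rng import substream
from lipidwgs.assoc import assoc_scan, conditional_scan, genomic_lambda, ivw_meta
from lipidwgs.cohort import (BIN_SIZE, CohortConfig, LandscapeConfig, MonogenicGene,
                             simulate_cohort, write_cohort)
from lipidwgs.containers import GeneLink, VariantGroup, groups_to_frame, links_to_frame
from lipidwgs.extremes import (LDL_GENE_CONFIGS, build_score_lead, build_score_pt,
                               build_score_shrunk, apply_score, classify_monogenic,
                               classify_polygenic, define_extremes, extreme_association,
                               results_to_frame, select_best_score)
from lipidwgs.groups import (GroupingConfig, coding_groups, groups_from_links,
                             proximity_groups, sliding_windows, write_group_file)
from lipidwgs.linking import (ABC_DEFAULT_CUTOFF, CorrelationLinker, LinkingConfig,
                              abc_candidate_elements, abc_links)
from lipidwgs.phenotypes import prepare_phenotypes
from lipidwgs.qc import QcThresholds, filter_genotypes, filter_variants
from lipidwgs.skat import burden_scan, fit_null

log = logging.getLogger(__name__)

STAGES = ["simulate", "prep", "qc", "assoc", "meta", "conditional",
          "groups", "link", "abc", "burden", "extremes"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds and cohort parameters, with study defaults."""

    outdir: str = "runs/demo"
    seed: int = 0
    # cohort
    n_samples: dict = field(default_factory=lambda: {"EA": 1500, "AA": 900})
    n_variants: int = 250
    noise_sd: float = 15.0
    carrier_effect: float = 30.0
    carrier_frequency: float = 0.01
    chrom_length: int = 120_000
    n_cell_types: int = 40
    n_genes: int = 12
    # association
    maf_min: float = 0.001
    alpha_gw: float = 5e-8
    cond_stop_p: float = 1e-4
    # qc
    min_gq: float = 20.0
    min_dp: float = 10.0
    max_dp: float = 200.0
    max_missing: float = 0.05
    min_phwe: float = 1e-9
    # grouping / burden
    rare_maf_max: float = 0.01
    window_size: int = 3000
    window_step: int = 1500
    promoter_flank: int = 5000
    enhancer_flank: int = 20000
    skat_max_maf: float = 0.01
    family_alpha: float = 0.05
    # linking
    odds_threshold: float = 2.5
    abc_cutoff: float = ABC_DEFAULT_CUTOFF
    # extremes
    extreme_q: float = 0.05
    causal_fractions: tuple = (0.01, 0.1, 1.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_samples=dict(self.n_samples), n_variants=self.n_variants,
            noise_sd=self.noise_sd, chrom_length=self.chrom_length,
            monogenic=[MonogenicGene("LDLR", "dominant", self.carrier_effect,
                                     self.carrier_frequency)],
            seed=self.seed,
        )

    def landscape_config(self) -> LandscapeConfig:
        return LandscapeConfig(n_cell_types=self.n_cell_types, n_genes=self.n_genes,
                               n_bins=self.chrom_length // BIN_SIZE, seed=self.seed)

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(min_gq=self.min_gq, min_dp=self.min_dp, max_dp=self.max_dp,
                            max_missing=self.max_missing, min_phwe=self.min_phwe)

    def grouping_config(self) -> GroupingConfig:
        return GroupingConfig(rare_maf_max=self.rare_maf_max, window_size=self.window_size,
                              window_step=self.window_step, promoter_flank=self.promoter_flank,
                              enhancer_flank=self.enhancer_flank)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Run:
    """Shared state and file plumbing for one pipeline execution."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.dir = Path(config.outdir)
        self.dir.mkdir(parents=True, exist_ok=True)
        analytic = {f.name: getattr(config, f.name)
                    for f in dataclasses.fields(config) if f.name != "outdir"}
        self.meta = {"seed": config.seed, "config_hash": lio.config_hash(analytic)}
        self.counts: dict[str, dict] = {}
        self._cache: dict[str, object] = {}

    def path(self, name: str) -> Path:
        return self.dir / name

    def write(self, df: pd.DataFrame, name: str) -> None:
        lio.write_tsv(df, self.path(name), meta=self.meta)

    # cached loaders so stages can run standalone against the directory
    def genotypes(self, which: str = "qc"):
        key = f"gm_{which}"
        if key not in self._cache:
            name = "genotypes.qc.vcf" if which == "qc" else "cohort/genotypes.vcf"
            self._cache[key] = lio.read_vcf(self.path(name))
        return self._cache[key]

    def phenotypes(self) -> pd.DataFrame:
        if "pheno" not in self._cache:
            self._cache["pheno"] = lio.read_tsv(self.path("phenotypes.prepared.tsv"))
        return self._cache["pheno"]

    def covariates(self, pheno: pd.DataFrame, with_cohort: bool = True) -> pd.DataFrame:
        cov = pd.DataFrame({"age": pheno["age"], "age2": pheno["age"] ** 2,
                            "sex": pheno["sex"]})
        if with_cohort:
            cov["cohort"] = pheno["cohort"].astype(str)
            # ethnicity enters only where a cohort is multi-ethnic; otherwise
            # it is collinear with the cohort indicator
            if (pheno.groupby("cohort")["ancestry"].nunique() > 1).any():
                cov["ancestry"] = pheno["ancestry"].astype(str)
        return cov


def _stage_simulate(run: _Run) -> None:
    cohort = simulate_cohort(run.cfg.cohort_config(), run.cfg.landscape_config())
    write_cohort(cohort, run.path("cohort"))
    run._cache["cohort"] = cohort
    run.counts["simulate"] = {"n_samples": cohort.genotypes.n_samples,
                              "n_variants": cohort.genotypes.n_variants}


def _stage_prep(run: _Run) -> None:
    raw = lio.read_tsv(run.path("cohort/phenotypes.tsv"))
    prepared = prepare_phenotypes(raw)
    run.write(prepared, "phenotypes.prepared.tsv")
    run._cache["pheno"] = prepared
    run.counts["prep"] = {"n_samples": len(prepared),
                          "n_statin_adjusted": int(prepared["on_statin"].sum())}


def _stage_qc(run: _Run) -> None:
    gm = run.genotypes("raw")
    pheno = run.phenotypes()
    gm.samples = gm.samples.merge(pheno[["sample_id", "cohort", "callset", "ancestry"]],
                                  on="sample_id", how="left")
    t = run.cfg.qc_thresholds()
    gm = filter_genotypes(gm, t)
    gm, report = filter_variants(gm, t)
    lio.write_vcf(gm, run.path("genotypes.qc.vcf"))
    run.write(report, "qc_report.tsv")
    run._cache["gm_qc"] = gm
    run.counts["qc"] = {"n_variants_kept": gm.n_variants,
                        "n_variants_dropped": int((report["filter"] != "PASS").sum())}


def _split_callsets(gm, pheno):
    out = []
    for cs, idx in pheno.groupby("callset").groups.items():
        out.append((int(cs), gm.take_samples(np.asarray(idx)), pheno.iloc[np.asarray(idx)].reset_index(drop=True)))
    return out


def _stage_assoc(run: _Run) -> None:
    gm = run.genotypes("qc")
    pheno = run.phenotypes()
    per_callset = []
    for cs, sub_gm, sub_ph in _split_callsets(gm, pheno):
        cov = run.covariates(sub_ph)
        res = assoc_scan(sub_gm, sub_ph["ldl_adj"], cov, maf_min=run.cfg.maf_min)
        run.write(res, f"assoc.callset{cs}.tsv")
        per_callset.append(res)
    run._cache["assoc"] = per_callset
    run.counts["assoc"] = {"n_tests": int(sum(len(r) for r in per_callset))}


def _stage_meta(run: _Run) -> None:
    if "assoc" in run._cache:
        per_callset = run._cache["assoc"]
    else:
        per_callset = [lio.read_tsv(p) for p in sorted(run.dir.glob("assoc.callset*.tsv"))]
    meta = ivw_meta(per_callset)
    lam = genomic_lambda(meta["p"], min_n=1)
    meta.attrs["lambda"] = lam
    run.write(meta, "meta.tsv")
    run._cache["meta"] = meta
    run.counts["meta"] = {"n_variants": len(meta), "lambda_gc": lam,
                          "n_genomewide": int((meta["p"] < run.cfg.alpha_gw).sum())}


def _stage_conditional(run: _Run) -> None:
    meta = run._cache.get("meta")
    if meta is None:
        meta = lio.read_tsv(run.path("meta.tsv"))
    gm = run.genotypes("qc")
    pheno = run.phenotypes()
    cov = run.covariates(pheno)
    hits = meta[meta["p"] < run.cfg.alpha_gw]
    if hits.empty:
        signals = pd.DataFrame(columns=["vid", "beta", "se", "p", "order"])
    else:
        # one synthetic chromosome: the locus is the +/-1 Mb window round the lead
        lead = hits.loc[hits["p"].idxmin()]
        window = (gm.variants["pos"] - int(lead["pos"])).abs() <= 1_000_000
        locus = gm.take_variants(np.nonzero(window.to_numpy())[0])
        signals = conditional_scan(locus, pheno["ldl_adj"], cov,
                                   stop_p=run.cfg.cond_stop_p, maf_min=run.cfg.maf_min)
    run.write(signals, "conditional.tsv")
    run.counts["conditional"] = {"n_signals": len(signals)}


def _load_landscape(run: _Run):
    if "cohort" in run._cache:
        return run._cache["cohort"].landscape
    # rebuild deterministically from the seeded config
    from lipidwgs.cohort import simulate_regulatory_landscape
    return simulate_regulatory_landscape(run.cfg.landscape_config())


def _stage_groups(run: _Run) -> None:
    gm = run.genotypes("qc")
    ls = _load_landscape(run)
    gcfg = run.cfg.grouping_config()
    tss = ls.genes[["gene", "tss"]]

    built = []
    built += coding_groups(gm, gcfg)
    built += sliding_windows(gm, ls.intervals, gcfg)
    built += proximity_groups(gm, tss, ls.intervals, gcfg)
    run._cache["groups_basic"] = built
    run.write(groups_to_frame(built), "groups.tsv")
    write_group_file(built, run.path("groups.epacts.txt"))
    run.counts["groups"] = {"n_groups": len(built)}


def _stage_link(run: _Run) -> None:
    ls = _load_landscape(run)
    linker = CorrelationLinker(ls, LinkingConfig(odds_threshold=run.cfg.odds_threshold,
                                                 seed=run.cfg.seed))
    links = linker.score_links(cell_type_index=0)
    run._cache["links_corr"] = links
    run.write(links_to_frame(links), "links.correlation.tsv")
    run.counts["link"] = {"n_links": len(links)}


def _stage_abc(run: _Run) -> None:
    ls = _load_landscape(run)
    dhs = ls.intervals[ls.intervals["kind"] == "dhs"][["chrom", "start", "end"]]
    elements = abc_candidate_elements(dhs)
    # per-element activity from mean DNase / H3K27ac signal of covered bins
    dn, ac = [], []
    for _, e in elements.iterrows():
        lo, hi = int(e["start"]) // BIN_SIZE, max(int(e["start"]) // BIN_SIZE + 1,
                                                  int(e["end"]) // BIN_SIZE)
        hi = min(hi, ls.signal.shape[0])
        dn.append(float(ls.signal[lo:hi, 0, 4].mean()))  # DNase, first cell type
        ac.append(float(ls.signal[lo:hi, 0, 0].mean()))  # H3K27ac
    elements = elements.assign(dnase=dn, h3k27ac=ac)
    links = abc_links(elements, ls.genes, ls.contact, cutoff=run.cfg.abc_cutoff)
    run._cache["links_abc"] = links
    run.write(links_to_frame(links), "links.abc.tsv")
    run.counts["abc"] = {"n_links": len(links)}


def _links_from_frame(df: pd.DataFrame) -> list[GeneLink]:
    return [GeneLink(str(r.chrom), int(r.start), int(r.end), str(r.gene),
                     str(r.cell_type), str(r.method), float(r.score))
            for r in df.itertuples()]


def _stage_burden(run: _Run) -> None:
    gm = run.genotypes("qc")
    pheno = run.phenotypes()
    gcfg = run.cfg.grouping_config()

    groups: list[VariantGroup] = list(run._cache.get("groups_basic") or [])
    if not groups and run.path("groups.tsv").exists():
        df = lio.read_tsv(run.path("groups.tsv"))
        groups = [VariantGroup(gid, tuple(sub["vid"]), sub["method"].iloc[0])
                  for gid, sub in df.groupby("group_id")]
    for cache_key, fname, tag in [("links_corr", "links.correlation.tsv", "link"),
                                  ("links_abc", "links.abc.tsv", "abc")]:
        links = run._cache.get(cache_key)
        if links is None and run.path(fname).exists():
            links = _links_from_frame(lio.read_tsv(run.path(fname)))
        if links:
            groups += groups_from_links(gm, links, gcfg, method=tag)

    callsets = []
    for cs, sub_gm, sub_ph in _split_callsets(gm, pheno):
        cov = run.covariates(sub_ph)
        callsets.append((sub_gm, fit_null(sub_ph["ldl_adj"], cov)))
    results = burden_scan(groups, callsets, max_maf=run.cfg.skat_max_maf,
                          family_alpha=run.cfg.family_alpha)
    run.write(results, "burden.tsv")
    run.counts["burden"] = {"n_groups": len(groups),
                            "alpha": run.cfg.family_alpha / max(len(groups), 1),
                            "n_significant": int(results["significant"].sum())}


def _stage_extremes(run: _Run) -> None:
    gm = run.genotypes("qc")
    pheno = run.phenotypes()
    rng = substream(run.cfg.seed, "extremes-split")
    n = gm.n_samples
    train = np.zeros(n, dtype=bool)
    train[rng.choice(n, size=n // 2, replace=False)] = True

    gm_tr, gm_te = gm.take_samples(np.nonzero(train)[0]), gm.take_samples(np.nonzero(~train)[0])
    ph_tr = pheno[train].reset_index(drop=True)
    ph_te = pheno[~train].reset_index(drop=True)

    # discovery scan on the training half -> summary stats + in-sample LD
    cov_tr = run.covariates(ph_tr)
    stats_df = assoc_scan(gm_tr, ph_tr["ldl_adj"], cov_tr, maf_min=run.cfg.maf_min)
    stats_df["other_allele"] = stats_df["ref"]
    common = stats_df[stats_df["maf"] >= 0.01].reset_index(drop=True)
    cols = gm_tr.variant_index().get_indexer(common["vid"])
    from lipidwgs.assoc import mean_impute
    G = mean_impute(gm_tr.dosages[:, cols])
    r = np.corrcoef(G, rowvar=False)
    ld = pd.DataFrame(r ** 2, index=common["vid"], columns=common["vid"])

    models = []
    try:
        models.append(build_score_lead(common, ld, alpha=run.cfg.alpha_gw))
    except ValueError:
        log.info("no genome-wide-significant variant for the restricted score")
    models += build_score_pt(common, ld, p_grid=[1e-4, 1e-2, 1.0], r2_grid=[0.2, 0.8])
    models += build_score_shrunk(common, ld, list(run.cfg.causal_fractions),
                                 n_gwas=len(ph_tr))
    models = [m for m in models if m.n_variants > 0]
    best, r2_table = select_best_score(models, gm_tr, ph_tr["ldl_adj"])
    run.write(r2_table, "score_selection.tsv")
    run.write(best.table, "score_model.tsv")

    scores = apply_score(best, gm_te)
    flags = classify_polygenic(scores, ph_te["ancestry"], q=run.cfg.extreme_q)
    labels, cutoffs = define_extremes(ph_te["ldl_adj"], ph_te["ancestry"], q=run.cfg.extreme_q)
    carriers = classify_monogenic(gm_te, LDL_GENE_CONFIGS)
    cov_te = pd.DataFrame({"age": ph_te["age"], "age2": ph_te["age"] ** 2, "sex": ph_te["sex"]})
    results = extreme_association(
        (labels == "extreme_high").to_numpy(), carriers["carrier_raising"].to_numpy(),
        flags["high_score"].to_numpy(), cov_te, ph_te["ldl_adj"].to_numpy(),
        ph_te["ancestry"].to_numpy(), scores=scores)
    frame = results_to_frame(results)
    run.write(cutoffs, "extreme_cutoffs.tsv")
    run.write(frame, "extremes.tsv")
    run.counts["extremes"] = {"n_models": len(models),
                              "best_method": best.method,
                              "n_extreme_high": int((labels == "extreme_high").sum())}


_STAGE_FUNCS = {
    "simulate": _stage_simulate, "prep": _stage_prep, "qc": _stage_qc,
    "assoc": _stage_assoc, "meta": _stage_meta, "conditional": _stage_conditional,
    "groups": _stage_groups, "link": _stage_link, "abc": _stage_abc,
    "burden": _stage_burden, "extremes": _stage_extremes,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in canonical order; write a run log.

    Any stage failure raises :class:`PipelineError` naming the stage.
    Returns the run report (versions, seed, thresholds, per-stage
    counts).
    """
    wanted = STAGES if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    run = _Run(config)
    t0 = time.time()
    for stage in wanted:
        try:
            _STAGE_FUNCS[stage](run)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineError(stage, exc) from exc
    report = {
        "version": lipidwgs.__version__,
        "seed": config.seed,
        "config_hash": run.meta["config_hash"],
        "config": {f.name: getattr(config, f.name) for f in dataclasses.fields(config)},
        "stages": wanted,
        "counts": run.counts,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (run.dir / "run_log.json").write_text(json.dumps(report, indent=2, default=str))
    return report
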