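"""End-to-end orchestration of the discovery/replication analysis.

Chains phenotype derivation, per-cohort EWAS, inverse-variance
meta-analysis with the two-cohort replication rule, cross-generation
validation, cis-meQTL conditioning, eQTM scanning and BMI-stratified
mediation, on either simulated or user-supplied cohorts. Outputs are
deterministic for a fixed configuration and seed; every table carries a
provenance header with the tool version and configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ewas import run_ewas
from .genetics import (
    cis_meqtl_scan,
    conditional_association,
    select_top_variant,
    variant_qc,
)
from .io import write_table_tsv, _jsonable
from .mediation import (
    encode_covariates,
    eqtm_scan,
    fit_mediation_models,
    infer_mediation,
)
from .meta import cross_generation_summary, ivw_meta, replication_filter
from .phenotypes import derive_phenotypes
from .simulate import GeneratorConfig, generate_cohort, generate_three_generations

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline"]

EWAS_COVARIATES = [
    "age",
    "sex",
    "bmi",
    "smoking",
    "alcohol",
    "batch",
    # one cell type (granulocytes) dropped: proportions sum to 1
    "cell_cd4t",
    "cell_cd8t",
    "cell_bcell",
    "cell_mono",
    "cell_nk",
]
MEDIATION_COVARIATES = ["age", "sex", "smoking", "alcohol_mediation_cat"]


@dataclass
class PipelineConfig:
    """All thresholds and knobs of the full pipeline in one place."""

    outcomes: tuple[str, ...] = ("ggt", "fli")
    fdr_alpha: float = 0.05
    meqtl_sig: float = 5e-8
    maf_min: float = 0.02
    hwe_min: float = 1e-6
    missing_max: float = 0.05
    cis_window: int = 1_000_000
    eqtm_window: int = 100_000
    min_cohorts: int = 2
    inflation_trigger: float = 1.1
    n_technical_pcs_used: int = 5
    cohort_mean_ages: tuple[float, ...] = (42.0, 55.0, 62.0)
    generation_mean_ages: tuple[float, float, float] = (22.0, 50.0, 70.0)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0

    def validate(self) -> None:
        for name, val, lo, hi in [
            ("fdr_alpha", self.fdr_alpha, 0, 1),
            ("meqtl_sig", self.meqtl_sig, 0, 1),
            ("maf_min", self.maf_min, 0, 0.5),
            ("hwe_min", self.hwe_min, 0, 1),
            ("missing_max", self.missing_max, 0, 1),
        ]:
            if not lo < val <= hi:
                raise ValueError(f"{name}={val} outside ({lo}, {hi}]")
        if self.cis_window <= 0 or self.eqtm_window <= 0:
            raise ValueError("windows must be positive")
        if self.min_cohorts < 1:
            raise ValueError("min_cohorts must be >= 1")
        self.generator.validate()

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(_jsonable(d), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _ewas_covariate_table(cov: pd.DataFrame, n_pcs: int) -> pd.DataFrame:
    cols = EWAS_COVARIATES + [f"pc_{i + 1}" for i in range(n_pcs)]
    cols = [c for c in cols if c in cov.columns]
    return cov[cols].astype(float)


def run_full_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute every stage on freshly simulated cohorts.

    Returns a results bundle with the simulated cohorts, per-cohort
    EWAS, meta/replication tables, cross-generation summaries, meQTL
    conditional models and mediation reports, plus a stage-by-stage run
    log with row counts. When ``outdir`` is given all report tables are
    written beneath a directory named by the configuration hash.
    """
    config.validate()
    chash = config.config_hash()
    prov = f"liverewas {__version__} config={chash}"
    log: list[dict] = []

    def stage(name, **info):
        logger.info("stage %s: %s", name, info)
        log.append({"stage": name, **_jsonable(info)})

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(8)]

    # --- simulate discovery cohorts and the three-generation cohort ---
    cohorts = {}
    for i, mean_age in enumerate(config.cohort_mean_ages):
        name = f"cohort{i + 1}"
        cohorts[name] = generate_cohort(
            config.generator, mean_age, seeds[i], name=name
        )
    gen_cfg = dataclasses.replace(config.generator, seed=seeds[3])
    g2, g1, g0 = generate_three_generations(
        gen_cfg, mean_ages=config.generation_mean_ages
    )
    generations = {"G2": g2, "G1": g1, "G0": g0}
    stage(
        "simulate",
        n_cohorts=len(cohorts),
        n_samples=config.generator.n_samples_per_cohort,
        n_cpgs=config.generator.n_cpgs,
    )

    # --- derived phenotypes ---
    derived = {}
    for name, c in {**cohorts, **generations}.items():
        tab = c.covariates.join(c.phenotypes)
        derived[name] = derive_phenotypes(tab, tg_unit="mmol/l")
    stage("derive_phenotypes", cohorts=list(derived))

    # --- per-cohort EWAS ---
    ewas_results: dict[str, dict] = {o: {} for o in config.outcomes}
    for name, c in cohorts.items():
        cov = _ewas_covariate_table(derived[name], config.n_technical_pcs_used)
        for outcome in config.outcomes:
            y = derived[name][f"{outcome}_int"]
            y.name = outcome
            res = run_ewas(
                c.methylation,
                y,
                cov,
                inflation_trigger=config.inflation_trigger,
                fdr_alpha=config.fdr_alpha,
                seed=seeds[4],
            )
            ewas_results[outcome][name] = res
    stage(
        "ewas",
        outcomes=list(config.outcomes),
        lambdas={
            o: {n: round(r.lambda_raw, 3) for n, r in d.items()}
            for o, d in ewas_results.items()
        },
    )

    # --- meta-analysis + replication rule ---
    meta_tables, replication = {}, {}
    for outcome in config.outcomes:
        tabs = {n: r.table for n, r in ewas_results[outcome].items()}
        meta_tables[outcome] = ivw_meta(tabs, min_cohorts=config.min_cohorts)
        replication[outcome] = replication_filter(
            tabs, alpha=config.fdr_alpha, min_cohorts=config.min_cohorts
        )
    replicated_cpgs = sorted(
        set().union(
            *[
                set(rep.index[rep["replicated"]])
                for rep in replication.values()
            ]
        )
    )
    stage("meta_replication", n_replicated=len(replicated_cpgs))

    # --- cross-generation validation ---
    gen_ewas = {}
    for gname, gc in generations.items():
        cov = _ewas_covariate_table(derived[gname], config.n_technical_pcs_used)
        y = derived[gname]["ggt_int"]
        y.name = "ggt"
        gen_ewas[gname] = run_ewas(
            gc.methylation, y, cov, inflation_trigger=config.inflation_trigger,
            seed=seeds[4],
        )
    gen_summary = cross_generation_summary(
        {g: r.table for g, r in gen_ewas.items()},
        {g: generations[g].mean_age for g in generations},
        cpgs=replicated_cpgs if replicated_cpgs else None,
    )
    stage("cross_generation", n_cpgs=len(gen_summary))

    # --- meQTL conditioning on the first cohort ---
    base = cohorts[next(iter(cohorts))]
    base_name = base.name
    qc = variant_qc(
        base.genotypes,
        maf_min=config.maf_min,
        hwe_min=config.hwe_min,
        missing_max=config.missing_max,
    )
    passed = base.genotypes.loc[qc.index[qc["pass_qc"]]]
    meqtl_records = []
    conditional = []
    cov_ewas = _ewas_covariate_table(derived[base_name], config.n_technical_pcs_used)
    outcome_series = derived[base_name]["ggt_int"]
    for cpg in replicated_cpgs:
        if cpg not in base.methylation.index:
            continue
        pos = (
            base.cpg_positions.at[cpg, "chrom"],
            int(base.cpg_positions.at[cpg, "pos"]),
        )
        recs = cis_meqtl_scan(
            cpg,
            pos,
            base.methylation.loc[cpg],
            passed,
            base.snp_positions,
            window=config.cis_window,
            sig_threshold=config.meqtl_sig,
        )
        if len(recs):
            meqtl_records.append(recs)
        top = select_top_variant(recs) if len(recs) else None
        if top is None:
            continue
        cr = conditional_association(
            outcome_series,
            base.methylation.loc[cpg],
            base.genotypes.loc[top["variant"]],
            cov_ewas,
            cpg_id=cpg,
            variant_id=top["variant"],
        )
        conditional.append(dataclasses.asdict(cr))
    meqtl_table = (
        pd.concat(meqtl_records, ignore_index=True)
        if meqtl_records
        else pd.DataFrame()
    )
    conditional_table = pd.DataFrame(conditional)
    stage(
        "meqtl",
        n_variants_pass_qc=int(qc["pass_qc"].sum()),
        n_tested_cpgs=len(replicated_cpgs),
        n_conditional_models=len(conditional_table),
    )

    # --- eQTM + mediation (BMI-stratified) on the first cohort ---
    med_cov_raw = derived[base_name][MEDIATION_COVARIATES]
    med_cov = encode_covariates(med_cov_raw)
    fli_int = derived[base_name]["fli_int"]
    eqtm_records = []
    mediation_rows = []
    for cpg in replicated_cpgs:
        if cpg not in base.methylation.index:
            continue
        pos = (
            base.cpg_positions.at[cpg, "chrom"],
            int(base.cpg_positions.at[cpg, "pos"]),
        )
        eq = eqtm_scan(
            cpg,
            pos,
            base.methylation.loc[cpg],
            base.expression,
            base.gene_positions,
            med_cov,
            window=config.eqtm_window,
        )
        if len(eq):
            eqtm_records.append(eq)
        for _, row in eq[eq["candidate"]].iterrows():
            strata = derived[base_name]["bmi_stratum"]
            for label in ("normal_weight", "overweight_obese"):
                idx = strata.index[strata == label]
                if len(idx) < 50:
                    continue
                mr = fit_mediation_models(
                    fli_int.loc[idx],
                    base.methylation.loc[cpg, idx],
                    base.expression.loc[row["transcript"], idx],
                    med_cov.loc[idx],
                    stratum=label,
                )
                dec = infer_mediation(mr)
                rec = dataclasses.asdict(mr)
                rec.update(
                    cpg=cpg, transcript=row["transcript"], **dec
                )
                mediation_rows.append(rec)
    eqtm_table = (
        pd.concat(eqtm_records, ignore_index=True)
        if eqtm_records
        else pd.DataFrame()
    )
    mediation_table = pd.DataFrame(mediation_rows)
    stage(
        "eqtm_mediation",
        n_eqtm_pairs=len(eqtm_table),
        n_mediation_models=len(mediation_table),
    )

    bundle = {
        "config_hash": chash,
        "cohorts": cohorts,
        "generations": generations,
        "derived": derived,
        "ewas": ewas_results,
        "meta": meta_tables,
        "replication": replication,
        "replicated_cpgs": replicated_cpgs,
        "generation_ewas": gen_ewas,
        "generation_summary": gen_summary,
        "variant_qc": qc,
        "meqtl": meqtl_table,
        "conditional": conditional_table,
        "eqtm": eqtm_table,
        "mediation": mediation_table,
        "log": log,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir) / chash, prov, config)
    return bundle


def _write_bundle(bundle, rundir: Path, prov: str, config: PipelineConfig) -> None:
    rundir.mkdir(parents=True, exist_ok=True)
    for outcome, tabs in bundle["ewas"].items():
        for name, res in tabs.items():
            write_table_tsv(res.table, rundir / f"ewas_{outcome}_{name}.tsv", prov)
    for outcome, tab in bundle["meta"].items():
        write_table_tsv(tab, rundir / f"meta_{outcome}.tsv", prov)
    for outcome, tab in bundle["replication"].items():
        write_table_tsv(tab, rundir / f"replication_{outcome}.tsv", prov)
    write_table_tsv(bundle["generation_summary"], rundir / "generations.tsv", prov)
    write_table_tsv(bundle["variant_qc"], rundir / "variant_qc.tsv", prov)
    for key in ("meqtl", "conditional", "eqtm", "mediation"):
        tab = bundle[key]
        if len(tab):
            write_table_tsv(
                tab.reset_index(drop=True), rundir / f"{key}.tsv", prov
            )
    summary = {
        "version": __version__,
        "config_hash": bundle["config_hash"],
        "replicated_cpgs": bundle["replicated_cpgs"],
        "lambda": {
            o: {n: r.lambda_raw for n, r in d.items()}
            for o, d in bundle["ewas"].items()
        },
        "log": bundle["log"],
        "config": _jsonable(dataclasses.asdict(config)),
    }
    with open(rundir / "run_summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2)
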