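"""Synthetic multi-cohort, multigenerational methylation datasets.

Generates cohorts with the statistical structure the analysis pipeline
assumes: beta-distributed methylation with cell-type and batch
structure; age/sex/BMI-correlated, right-skewed liver phenotypes with
planted CpG effects whose magnitude grows with cohort mean age
(emulating an old > middle > young generational gradient); cis-SNPs
with additive effects on methylation; and nearby-gene expression that
is partly driven by methylation and partly drives the liver phenotype
(a planted mediation path). Every planted effect is recorded in a
ground-truth block for parameter-recovery tests.

Phenotypes are generated through a latent liver score L that enters
log(GGT) additively, so planted CpG slopes are exact on the log-GGT
scale and recoverable by linear regression; GGT itself is strictly
positive and right-skewed, as in real serum measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "GeneratorConfig",
    "SimulatedCohort",
    "beta_from_intensities",
    "generate_cohort",
    "generate_three_generations",
    "apply_qc_filters",
    "mendelian_consistent",
    "mendelian_consistency_rate",
    "simulate_mediation_dataset",
    "cohort_hash",
    "CELL_TYPES",
]

CELL_TYPES = ["gran", "cd4t", "cd8t", "bcell", "mono", "nk"]
# Dirichlet concentration for leukocyte proportions (granulocyte-dominated)
_CELL_ALPHA = np.array([33.0, 7.2, 4.8, 3.6, 4.8, 6.6])


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-cohort generator.

    Planted CpG slopes are expressed on the log-GGT scale per unit of
    methylation beta-value; ``age_modulation`` is the exponent k of the
    multiplicative scaling (cohort mean age / reference age)^k applied
    to the base slope, reproducing stronger associations in older
    cohorts.
    """

    n_samples_per_cohort: int = 500
    n_cpgs: int = 1000
    n_true_cpgs: int = 8
    n_snps: int = 60
    n_genes: int = 15
    n_meqtl_pairs: int = 3
    n_mediation_triplets: int = 2
    age_range_per_cohort: tuple[float, float] = (35.0, 60.0)
    reference_age: float = 45.0
    effect_size_base: float = 1.5
    age_modulation: float = 1.0
    mediation_a: float = -5.0
    mediation_b: float = -0.3
    mediation_c_direct: float = 1.0
    meqtl_effect: float = 0.05
    noise_sd: float = 0.5
    genotype_missing_rate: float = 0.01
    n_technical_pcs: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_true_cpgs > self.n_cpgs:
            raise ValueError("n_true_cpgs cannot exceed n_cpgs")
        planted = self.n_true_cpgs + self.n_mediation_triplets
        extra_meqtl = max(0, self.n_meqtl_pairs - planted)
        if planted + extra_meqtl > self.n_cpgs:
            raise ValueError("planted CpG sets exceed n_cpgs")
        if self.n_meqtl_pairs > self.n_snps:
            raise ValueError("n_meqtl_pairs cannot exceed n_snps")
        if self.n_mediation_triplets > self.n_genes:
            raise ValueError("n_mediation_triplets cannot exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.genotype_missing_rate < 1.0:
            raise ValueError("genotype_missing_rate must be in [0, 1)")


@dataclass
class SimulatedCohort:
    """One cohort's data matrices, covariates, phenotypes and ground truth."""

    name: str
    methylation: pd.DataFrame  # CpG x sample, beta-values in [0, 1]
    genotypes: pd.DataFrame  # SNP x sample, additive dosage {0,1,2}, NaN missing
    expression: pd.DataFrame  # gene x sample
    covariates: pd.DataFrame  # per-sample
    phenotypes: pd.DataFrame  # ggt/alt/ast (U/l), steatosis (0/1)
    cpg_positions: pd.DataFrame  # chrom, pos (1-based)
    snp_positions: pd.DataFrame
    gene_positions: pd.DataFrame
    truth: dict
    mean_age: float = float("nan")

    @property
    def samples(self) -> pd.Index:
        return self.methylation.columns


def beta_from_intensities(M, U, alpha_offset=100.0):
    """Methylation beta-value M / (M + U + alpha).

    The offset regularizes the ratio when both channel intensities are
    low; the result lies in [0, 1). Negative intensities are invalid.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    a = np.asarray(alpha_offset, dtype=float)
    if np.any(M < 0) or np.any(U < 0) or np.any(a < 0):
        raise ValueError("invalid intensity: M, U and alpha must be non-negative")
    denom = M + U + a
    if np.any(denom == 0):
        raise ValueError("invalid intensity: M + U + alpha must be positive")
    out = M / denom
    return float(out) if out.ndim == 0 else out


def _planted_slope(cfg: GeneratorConfig, mean_age: float) -> float:
    return cfg.effect_size_base * (mean_age / cfg.reference_age) ** cfg.age_modulation


def _draw_covariates(cfg: GeneratorConfig, mean_age: float, rng) -> pd.DataFrame:
    n = cfg.n_samples_per_cohort
    half = (cfg.age_range_per_cohort[1] - cfg.age_range_per_cohort[0]) / 2.0
    age = np.clip(rng.uniform(mean_age - half, mean_age + half, n), 3.0, 100.0)
    sex = rng.integers(0, 2, n)
    smoking = (rng.random(n) < 0.25).astype(int)
    bmi = np.clip(25.5 + 0.09 * (age - 40.0) + rng.normal(0, 4.0, n), 16.0, 55.0)
    waist = 3.5 * bmi + 6.0 + rng.normal(0, 6.0, n)
    alcohol = np.where(rng.random(n) < 0.3, 0.0, rng.gamma(2.0, 7.0, n))
    cells = rng.dirichlet(_CELL_ALPHA, n)
    pcs = rng.normal(0, 1, (n, cfg.n_technical_pcs))
    batch = rng.integers(0, 2, n)
    cov = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "waist": waist,
            "smoking": smoking,
            "alcohol": alcohol,
            "batch": batch,
        }
    )
    for i, ct in enumerate(CELL_TYPES):
        cov[f"cell_{ct}"] = cells[:, i]
    for i in range(cfg.n_technical_pcs):
        cov[f"pc_{i + 1}"] = pcs[:, i]
    return cov


def _draw_genotypes(cfg: GeneratorConfig, rng, allele_freqs=None):
    """True (no-missing) additive genotypes under HWE."""
    n = cfg.n_samples_per_cohort
    if allele_freqs is None:
        allele_freqs = rng.uniform(0.1, 0.5, cfg.n_snps)
    a1 = rng.random((cfg.n_snps, n)) < allele_freqs[:, None]
    a2 = rng.random((cfg.n_snps, n)) < allele_freqs[:, None]
    return (a1.astype(int) + a2.astype(int)), allele_freqs


def _mask_genotypes(cfg: GeneratorConfig, geno: np.ndarray, rng) -> np.ndarray:
    out = geno.astype(float)
    if cfg.genotype_missing_rate > 0:
        out[rng.random(geno.shape) < cfg.genotype_missing_rate] = np.nan
    return out


def _annotations(cfg: GeneratorConfig, rng, planted_sets):
    """CpG/SNP/gene coordinates on one chromosome; planted pairs in cis."""
    cpg_pos = 1_000_000 + np.arange(cfg.n_cpgs) * 10_000
    span = int(cpg_pos.max()) + 1_000_000
    snp_pos = rng.integers(1, span, cfg.n_snps)
    gene_pos = rng.integers(1, span, cfg.n_genes)
    for k, (snp_i, cpg_i) in enumerate(planted_sets["meqtl_pairs_idx"]):
        snp_pos[snp_i] = cpg_pos[cpg_i] + int(rng.integers(-100_000, 100_000))
    for k, (cpg_i, gene_i) in enumerate(planted_sets["mediation_pairs_idx"]):
        gene_pos[gene_i] = cpg_pos[cpg_i] + int(rng.integers(-50_000, 50_000))
    cpgs = pd.DataFrame(
        {"chrom": "1", "pos": cpg_pos},
        index=[f"cg{j:08d}" for j in range(cfg.n_cpgs)],
    )
    snps = pd.DataFrame(
        {"chrom": "1", "pos": snp_pos},
        index=[f"rs{j:06d}" for j in range(cfg.n_snps)],
    )
    genes = pd.DataFrame(
        {"chrom": "1", "pos": gene_pos},
        index=[f"tx{j:04d}" for j in range(cfg.n_genes)],
    )
    return cpgs, snps, genes


def generate_cohort(
    config: GeneratorConfig,
    cohort_mean_age: float | None = None,
    seed: int | None = None,
    name: str = "cohort",
    _true_genotypes: np.ndarray | None = None,
    _allele_freqs: np.ndarray | None = None,
) -> SimulatedCohort:
    """Generate one cohort; deterministic given (config, seed).

    Planted CpG slopes scale with ``cohort_mean_age`` through
    (mean age / reference age)^age_modulation. The truth block records
    planted CpG ids and log-GGT-scale slopes, meQTL (SNP, CpG) pairs
    with their per-allele beta-value shifts, and mediation
    (CpG, transcript) triplets with the generative path coefficients.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mean_age = (
        float(np.mean(cfg.age_range_per_cohort))
        if cohort_mean_age is None
        else float(cohort_mean_age)
    )
    n = cfg.n_samples_per_cohort
    samples = pd.Index([f"{name}_s{i:05d}" for i in range(n)], name="sample")
    cov = _draw_covariates(cfg, mean_age, rng)
    cov.index = samples

    # deterministic planted-index layout: phenotype CpGs first, then
    # mediation CpGs; meQTLs attach to mediation/phenotype CpGs first so
    # at least one CpG carries the full effect chain (phenotype
    # association + meQTL + mediation path) for end-to-end tracing.
    idx = np.arange(cfg.n_cpgs)
    planted_idx = idx[: cfg.n_true_cpgs]
    med_cpg_idx = idx[cfg.n_true_cpgs : cfg.n_true_cpgs + cfg.n_mediation_triplets]
    meqtl_candidates = np.concatenate(
        [med_cpg_idx, planted_idx, idx[cfg.n_true_cpgs + cfg.n_mediation_triplets :]]
    )
    meqtl_cpg_idx = meqtl_candidates[: cfg.n_meqtl_pairs]
    meqtl_snp_idx = np.arange(cfg.n_meqtl_pairs)
    med_gene_idx = np.arange(cfg.n_mediation_triplets)
    planted_sets = {
        "meqtl_pairs_idx": list(zip(meqtl_snp_idx, meqtl_cpg_idx)),
        "mediation_pairs_idx": list(zip(med_cpg_idx, med_gene_idx)),
    }
    cpg_ann, snp_ann, gene_ann = _annotations(cfg, rng, planted_sets)

    # --- genotypes (true, then MCAR-masked) ---
    if _true_genotypes is None:
        geno_true, freqs = _draw_genotypes(cfg, rng, _allele_freqs)
    else:
        geno_true, freqs = _true_genotypes, _allele_freqs
    geno = _mask_genotypes(cfg, geno_true, rng)

    # --- methylation: logit-scale baseline + cell/batch structure ---
    comp = rng.choice(3, cfg.n_cpgs, p=[0.3, 0.4, 0.3])
    mu_logit = np.array([-2.2, 0.0, 2.2])[comp] + rng.normal(0, 0.5, cfg.n_cpgs)
    special = np.unique(np.concatenate([planted_idx, meqtl_cpg_idx, med_cpg_idx]))
    mu_logit[special] = rng.normal(0, 0.2, special.size)  # mid-range for dynamic range
    cpg_sd = rng.uniform(0.25, 0.45, cfg.n_cpgs)
    cell_coef = np.where(rng.random(cfg.n_cpgs) < 0.3, rng.normal(0, 0.8, cfg.n_cpgs), 0.0)
    batch_coef = np.where(rng.random(cfg.n_cpgs) < 0.2, rng.normal(0, 0.3, cfg.n_cpgs), 0.0)
    gran = cov["cell_gran"].to_numpy()
    batch = cov["batch"].to_numpy()
    logit_m = (
        mu_logit[:, None]
        + cell_coef[:, None] * (gran - gran.mean())[None, :]
        + batch_coef[:, None] * (batch - 0.5)[None, :]
        + rng.normal(0, cpg_sd[:, None], (cfg.n_cpgs, n))
    )
    M = expit(logit_m)
    for snp_i, cpg_i in planted_sets["meqtl_pairs_idx"]:
        M[cpg_i] = np.clip(
            M[cpg_i] + cfg.meqtl_effect * geno_true[snp_i], 1e-6, 1.0 - 1e-6
        )
    methylation = pd.DataFrame(M, index=cpg_ann.index, columns=samples)

    # --- expression: baseline + mediation first path a * (m - 0.5) ---
    E = 7.0 + 0.01 * (cov["age"].to_numpy() - 45.0) + rng.normal(
        0, 1.0, (cfg.n_genes, n)
    )
    for cpg_i, gene_i in planted_sets["mediation_pairs_idx"]:
        E[gene_i] = E[gene_i] + cfg.mediation_a * (M[cpg_i] - 0.5)
    expression = pd.DataFrame(E, index=gene_ann.index, columns=samples)

    # --- latent liver score -> phenotypes ---
    slope = _planted_slope(cfg, mean_age)
    L = (
        0.015 * (cov["age"].to_numpy() - 45.0)
        + 0.2 * cov["sex"].to_numpy()
        + 0.04 * (cov["bmi"].to_numpy() - 26.0)
        + 0.15 * cov["smoking"].to_numpy()
        + 0.006 * cov["alcohol"].to_numpy()
    )
    for j in planted_idx:
        L = L + slope * (M[j] - 0.5)
    for cpg_i, gene_i in planted_sets["mediation_pairs_idx"]:
        L = L + cfg.mediation_c_direct * (M[cpg_i] - 0.5)
        L = L + cfg.mediation_b * (E[gene_i] - 7.0)
    L = L + rng.normal(0, cfg.noise_sd, n)
    ggt = np.exp(3.1 + L)
    alt = np.exp(3.0 + 0.6 * L + rng.normal(0, 0.3, n))
    ast = np.exp(2.9 + 0.5 * L + rng.normal(0, 0.3, n))
    tg_mgdl = np.exp(
        4.55 + 0.035 * (cov["bmi"].to_numpy() - 26.0) + rng.normal(0, 0.4, n)
    )
    cov["triglycerides"] = tg_mgdl / 88.57  # stored in mmol/l
    p_ste = expit(-1.8 + 1.0 * L + 0.08 * (cov["bmi"].to_numpy() - 26.0))
    steatosis = (rng.random(n) < p_ste).astype(int)
    phenotypes = pd.DataFrame(
        {"ggt": ggt, "alt": alt, "ast": ast, "steatosis": steatosis}, index=samples
    )

    truth = {
        "mean_age": mean_age,
        "planted_cpgs": list(cpg_ann.index[planted_idx]),
        "log_ggt_slope": slope,
        "meqtl_pairs": [
            {
                "snp": snp_ann.index[si],
                "cpg": cpg_ann.index[ci],
                "per_allele_effect": cfg.meqtl_effect,
            }
            for si, ci in planted_sets["meqtl_pairs_idx"]
        ],
        "mediation_triplets": [
            {
                "cpg": cpg_ann.index[ci],
                "transcript": gene_ann.index[gi],
                "a": cfg.mediation_a,
                "b": cfg.mediation_b,
                "c_direct": cfg.mediation_c_direct,
                "indirect": cfg.mediation_a * cfg.mediation_b,
            }
            for ci, gi in planted_sets["mediation_pairs_idx"]
        ],
        "allele_freqs": freqs.tolist(),
    }
    geno_df = pd.DataFrame(geno, index=snp_ann.index, columns=samples)
    return SimulatedCohort(
        name=name,
        methylation=methylation,
        genotypes=geno_df,
        expression=expression,
        covariates=cov,
        phenotypes=phenotypes,
        cpg_positions=cpg_ann,
        snp_positions=snp_ann,
        gene_positions=gene_ann,
        truth=truth,
        mean_age=mean_age,
    )


def _transmit(parent_geno: np.ndarray, rng) -> np.ndarray:
    """One allele per SNP transmitted from a parent's true genotype."""
    # P(transmit alt) = dosage / 2
    return (rng.random(parent_geno.shape) < parent_geno / 2.0).astype(int)


def generate_three_generations(
    config: GeneratorConfig,
    mean_ages: tuple[float, float, float] = (22.0, 50.0, 70.0),
) -> tuple[SimulatedCohort, SimulatedCohort, SimulatedCohort]:
    """Three cohorts (G2 young, G1 middle, G0 old) with shared genetics.

    Each G1 sample is the child of a G0 couple (one transmitted allele
    per parent), and each G2 sample the child of a G1 parent and an
    unobserved mate drawn from the population allele frequencies, so
    parent-offspring trios are Mendelian-consistent by construction.
    Planted effect sizes scale with each generation's mean age.
    """
    config.validate()
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]
    rng_gen = np.random.default_rng(seeds[3])
    n = cfg.n_samples_per_cohort
    freqs = rng_gen.uniform(0.1, 0.5, cfg.n_snps)
    g0_true, _ = _draw_genotypes(cfg, rng_gen, freqs)
    n_couples = n // 2
    fathers = np.arange(n_couples) * 2
    mothers = fathers + 1
    couple_of_child = np.arange(n) % n_couples
    g1_true = _transmit(g0_true[:, fathers[couple_of_child]], rng_gen) + _transmit(
        g0_true[:, mothers[couple_of_child]], rng_gen
    )
    mate_allele = (rng_gen.random((cfg.n_snps, n)) < freqs[:, None]).astype(int)
    g2_true = _transmit(g1_true, rng_gen) + mate_allele

    age_g2, age_g1, age_g0 = mean_ages
    g2 = generate_cohort(cfg, age_g2, seeds[0], "G2", g2_true, freqs)
    g1 = generate_cohort(cfg, age_g1, seeds[1], "G1", g1_true, freqs)
    g0 = generate_cohort(cfg, age_g0, seeds[2], "G0", g0_true, freqs)
    trios = [
        {
            "father": g0.samples[fathers[couple_of_child[i]]],
            "mother": g0.samples[mothers[couple_of_child[i]]],
            "child": g1.samples[i],
        }
        for i in range(n)
    ]
    for c in (g0, g1, g2):
        c.truth["trios_g0_g1"] = trios
    return g2, g1, g0


def mendelian_consistent(father: float, mother: float, child: float) -> bool:
    """Is a child's dosage attainable from one allele per parent?

    Missing (NaN) genotypes make the trio vacuously consistent.
    """
    if any(not np.isfinite(v) for v in (father, mother, child)):
        return True
    alleles = {0: (0,), 1: (0, 1), 2: (1,)}
    possible = {
        af + am for af in alleles[int(father)] for am in alleles[int(mother)]
    }
    return int(child) in possible


def mendelian_consistency_rate(
    g0: SimulatedCohort, g1: SimulatedCohort
) -> float:
    """Fraction of (trio, SNP) genotype triples that are Mendelian-consistent."""
    trios = g0.truth["trios_g0_g1"]
    ok = 0
    total = 0
    for t in trios:
        f = g0.genotypes[t["father"]].to_numpy()
        m = g0.genotypes[t["mother"]].to_numpy()
        c = g1.genotypes[t["child"]].to_numpy()
        for fa, mo, ch in zip(f, m, c):
            total += 1
            ok += mendelian_consistent(fa, mo, ch)
    return ok / total


def apply_qc_filters(
    detection_p: pd.DataFrame,
    methylation: pd.DataFrame | None = None,
    detection_p_threshold: float = 1e-15,
    max_probe_fail_fraction: float = 0.01,
    call_rate_threshold: float = 0.95,
):
    """Probe/sample QC on detection p-values and sample call rates.

    A sample's call rate is its fraction of probes with detection
    p <= threshold; samples with call rate below ``call_rate_threshold``
    are removed. A probe is removed when its detection p exceeds the
    threshold in more than ``max_probe_fail_fraction`` of the retained
    samples. Returns (filtered methylation or None, report dict). An
    empty post-filter matrix yields a warning entry in the report, not
    an error.
    """
    dp = detection_p
    if ((dp < 0) | (dp > 1)).any().any():
        raise ValueError("detection p-values must lie in [0, 1]")
    called = dp <= detection_p_threshold
    call_rate = called.mean(axis=0)
    keep_samples = call_rate.index[call_rate >= call_rate_threshold]
    failed = (~called[keep_samples]).mean(axis=1) if len(keep_samples) else (
        ~called
    ).mean(axis=1)
    keep_probes = failed.index[failed <= max_probe_fail_fraction]
    report = {
        "n_samples_in": dp.shape[1],
        "n_samples_removed": dp.shape[1] - len(keep_samples),
        "n_probes_in": dp.shape[0],
        "n_probes_removed": dp.shape[0] - len(keep_probes),
        "call_rate_threshold": call_rate_threshold,
        "detection_p_threshold": detection_p_threshold,
        "max_probe_fail_fraction": max_probe_fail_fraction,
        "probe_rule": "fraction-of-samples above detection-p threshold "
        f"(> {max_probe_fail_fraction:g} of samples)",
        "warning": None,
    }
    if len(keep_probes) == 0 or len(keep_samples) == 0:
        report["warning"] = "all probes or samples removed by QC"
    if methylation is None:
        return None, report
    return methylation.loc[keep_probes, keep_samples], report


def simulate_mediation_dataset(
    n: int,
    a: float = 0.5,
    b: float = 0.4,
    c_direct: float = 0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Standardized single-mediator dataset for recovery experiments.

    exposure x ~ N(0,1); mediator ge = a*x + 0.2*age + e1;
    outcome y = c_direct*x + b*ge + 0.2*age + 0.1*sex + e2, with
    independent N(0, noise_sd) errors. The true indirect effect is a*b
    and the true total effect c_direct + a*b.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    age = rng.normal(0, 1, n)
    sex = rng.integers(0, 2, n).astype(float)
    ge = a * x + 0.2 * age + rng.normal(0, noise_sd, n)
    y = c_direct * x + b * ge + 0.2 * age + 0.1 * sex + rng.normal(0, noise_sd, n)
    return pd.DataFrame(
        {"y": y, "x": x, "ge": ge, "age": age, "sex": sex},
        index=[f"s{i:05d}" for i in range(n)],
    )


def cohort_hash(cohort: SimulatedCohort) -> str:
    """Deterministic content hash over all data matrices of a cohort."""
    import hashlib

    h = hashlib.sha256()
    for df in (
        cohort.methylation,
        cohort.genotypes,
        cohort.expression,
        cohort.covariates,
        cohort.phenotypes,
    ):
        h.update(np.ascontiguousarray(df.to_numpy(dtype=float)).tobytes())
        h.update(",".join(map(str, df.index)).encode())
        h.update(",".join(map(str, df.columns)).encode())
    return h.hexdigest()
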