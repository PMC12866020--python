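"""Genotype QC and cis-meQTL analysis.

Variants pass QC on minor allele frequency, an exact Hardy-Weinberg
test and missingness; cis-meQTL scans regress CpG methylation on
additive dosage within a symmetric window around the CpG, the top
variant is the lowest-p genome-wide-significant hit, and conditional
models ask whether the CpG-phenotype association survives adjusting
for that variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ewas import fit_cpg_model

logger = logging.getLogger(__name__)

__all__ = [
    "hwe_exact_test",
    "variant_qc",
    "cis_meqtl_scan",
    "select_top_variant",
    "conditional_association",
    "ConditionalResult",
    "dosage_summary",
]

GWAS_SIG = 5e-8
CIS_WINDOW = 1_000_000
MAF_MIN = 0.02
HWE_MIN = 1e-6
MISSING_MAX = 0.05


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose likelihood under HWE does not exceed
    the observed one (the standard exact test; no mid-p adjustment).
    Monomorphic tables return p = 1 by convention.
    """
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        logger.debug("monomorphic variant: HWE p = 1 by convention")
        return 1.0
    # log-probability of each feasible heterozygote count given allele totals
    hets = np.arange(rare % 2, rare + 1, 2)
    n_hom_rare = (rare - hets) // 2
    n_hom_common = (2 * n - rare - hets) // 2
    from scipy.special import gammaln

    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_common + 1)
        - (gammaln(2 * n + 1) - gammaln(n_a + 1) - gammaln(n_b + 1))
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.flatnonzero(hets == n_ab)[0]]
    p = float(prob[prob <= obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def dosage_summary(dosages) -> dict:
    """MAF, HWE p and missingness of one variant's additive dosages."""
    d = np.asarray(dosages, dtype=float)
    miss = float(np.mean(~np.isfinite(d)))
    obs = d[np.isfinite(d)]
    if obs.size == 0:
        return {"maf": np.nan, "hwe_p": np.nan, "missingness": miss}
    n_bb = int(np.sum(obs == 2))
    n_ab = int(np.sum(obs == 1))
    n_aa = int(np.sum(obs == 0))
    af = (2 * n_bb + n_ab) / (2.0 * obs.size)
    maf = min(af, 1.0 - af)
    return {
        "maf": maf,
        "hwe_p": hwe_exact_test(n_aa, n_ab, n_bb),
        "missingness": miss,
    }


def variant_qc(
    genotypes: pd.DataFrame,
    maf_min: float = MAF_MIN,
    hwe_min: float = HWE_MIN,
    missing_max: float = MISSING_MAX,
) -> pd.DataFrame:
    """Per-variant QC report for a SNP x sample dosage matrix.

    A variant passes iff MAF >= ``maf_min`` AND HWE p >= ``hwe_min``
    AND missingness < ``missing_max`` (thresholds as in standard
    meQTL pipelines: 0.02 / 1e-6 / 0.05). Returns a DataFrame with the
    statistics, per-rule flags and the overall ``pass_qc`` flag.
    """
    rows = []
    for vid in genotypes.index:
        s = dosage_summary(genotypes.loc[vid].to_numpy())
        s["variant"] = vid
        rows.append(s)
    rep = pd.DataFrame(rows).set_index("variant")
    rep["pass_maf"] = rep["maf"] >= maf_min
    rep["pass_hwe"] = rep["hwe_p"] >= hwe_min
    rep["pass_missing"] = rep["missingness"] < missing_max
    rep["pass_qc"] = rep["pass_maf"] & rep["pass_hwe"] & rep["pass_missing"]
    return rep


def _additive_fit(m: np.ndarray, d: np.ndarray, covariates=None):
    """Regress methylation on dosage (plus optional covariates)."""
    keep = np.isfinite(m) & np.isfinite(d)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        keep &= np.all(np.isfinite(C), axis=1)
        C = C[keep]
    else:
        C = None
    m, d = m[keep], d[keep]
    if m.size < 10 or np.std(d) < 1e-12:
        return None
    return fit_cpg_model(m, d, C)


def cis_meqtl_scan(
    cpg_id: str,
    cpg_pos: tuple[str, int],
    methylation_row: pd.Series,
    genotypes: pd.DataFrame,
    variant_positions: pd.DataFrame,
    window: int = CIS_WINDOW,
    sig_threshold: float = GWAS_SIG,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Test every QC-passed variant within +/- ``window`` bp of a CpG.

    ``cpg_pos`` is (chromosome, 1-based position); ``variant_positions``
    holds columns ``chrom`` and ``pos`` indexed by variant id. The
    window is closed (distance exactly equal to ``window`` is in). Each
    in-window variant is tested with an additive linear model of
    methylation on dosage (no covariates by default); hits with
    p < ``sig_threshold`` are flagged genome-wide significant.
    """
    chrom, pos = cpg_pos
    vp = variant_positions
    inwin = vp.index[
        (vp["chrom"] == chrom) & ((vp["pos"] - pos).abs() <= window)
    ]
    inwin = inwin.intersection(genotypes.index)
    rows = []
    samples = methylation_row.index.intersection(genotypes.columns)
    m = methylation_row.loc[samples].to_numpy(dtype=float)
    C = covariates.loc[samples] if covariates is not None else None
    for vid in sorted(inwin):
        d = genotypes.loc[vid, samples].to_numpy(dtype=float)
        fit = _additive_fit(m, d, C)
        if fit is None:
            continue
        rows.append(
            {
                "cpg": cpg_id,
                "variant": vid,
                "chrom": chrom,
                "pos": int(vp.at[vid, "pos"]),
                "distance": int(vp.at[vid, "pos"] - pos),
                "effect": fit["effect"],
                "se": fit["se"],
                "p": fit["p"],
                "n": fit["n"],
                "significant": fit["p"] < sig_threshold,
            }
        )
    cols = [
        "cpg", "variant", "chrom", "pos", "distance",
        "effect", "se", "p", "n", "significant",
    ]
    return pd.DataFrame(rows, columns=cols)


def select_top_variant(records: pd.DataFrame) -> pd.Series | None:
    """The significant record with the lowest p.

    Ties are broken by smaller |distance| to the CpG, then by
    lexicographic variant id. Returns None (with a logged note) when no
    record is genome-wide significant.
    """
    sig = records[records["significant"]] if "significant" in records else records
    if len(sig) == 0:
        logger.info("no genome-wide-significant meQTL record to select")
        return None
    ordered = sig.assign(_absdist=sig["distance"].abs()).sort_values(
        ["p", "_absdist", "variant"], kind="mergesort"
    )
    top = ordered.iloc[0].drop("_absdist")
    top = top.copy()
    top["is_top"] = True
    return top


@dataclass
class ConditionalResult:
    """Nested liver-phenotype models with and without the top meQTL."""

    cpg: str
    variant: str
    cpg_effect_marginal: float
    cpg_p_marginal: float
    cpg_effect_conditional: float
    cpg_p_conditional: float
    snp_effect: float
    snp_p: float
    n: int
    collinear_flag: bool = False


def conditional_association(
    outcome: pd.Series,
    cpg_values: pd.Series,
    snp_dosages: pd.Series,
    covariates: pd.DataFrame,
    cpg_id: str = "cpg",
    variant_id: str = "snp",
) -> ConditionalResult:
    """Does the CpG-phenotype association survive conditioning on the SNP?

    Fits ``outcome ~ CpG + covariates`` and
    ``outcome ~ CpG + SNP + covariates`` on the identical complete-case
    sample and reports the CpG effect/p in both models plus the SNP's
    own effect/p in the joint model. High CpG-SNP collinearity is
    flagged but both models are still attempted.
    """
    samples = outcome.index
    df = pd.DataFrame(
        {
            "y": outcome,
            "cpg": cpg_values.reindex(samples),
            "snp": snp_dosages.reindex(samples),
        }
    ).join(covariates.reindex(samples))
    df = df.dropna()
    n = len(df)
    covcols = [c for c in df.columns if c not in ("y", "cpg", "snp")]
    r = np.corrcoef(df["cpg"], df["snp"])[0, 1] if df["snp"].std() > 0 else 0.0
    collinear = bool(abs(r) > 0.99)
    if collinear:
        logger.warning(
            "CpG %s and variant %s nearly collinear (r=%.3f)", cpg_id, variant_id, r
        )
    marg = fit_cpg_model(df["y"], df["cpg"], df[covcols])
    cond_cov = df[["snp"] + covcols]
    cond = fit_cpg_model(df["y"], df["cpg"], cond_cov, column_names=["snp"] + covcols)
    snp_fit = fit_cpg_model(df["y"], df["snp"], df[["cpg"] + covcols],
                            column_names=["cpg"] + covcols)
    return ConditionalResult(
        cpg=cpg_id,
        variant=variant_id,
        cpg_effect_marginal=marg["effect"],
        cpg_p_marginal=marg["p"],
        cpg_effect_conditional=cond["effect"],
        cpg_p_conditional=cond["p"],
        snp_effect=snp_fit["effect"],
        snp_p=snp_fit["p"],
        n=n,
        collinear_flag=collinear,
    )
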