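"""eQTM scanning and product-of-coefficients mediation.

The mediation question: is the association between a CpG's methylation
(exposure) and the fatty liver index (outcome) carried by the
expression of a nearby gene (mediator)? Three nested linear models are
fitted on identical rows:

    FLI = eta0  + eta1 * DNAm                + eta2' C     (total)
    FLI = gamma0 + gamma1 * DNAm + gamma2*GE + gamma3' C   (direct)
    GE  = beta0 + beta1 * DNAm               + beta2' C    (first path)

The indirect effect is beta1 * gamma2 (product of coefficients) with a
first-order multivariate-Delta standard error; the proportion mediated
is indirect/total with a Delta SE for the ratio. Mediation is inferred
when the 95% CI of the indirect effect excludes zero. Valid causal
reading additionally requires the usual exchangeability (no-unmeasured-
confounding) conditions, which are assumptions, not testable here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MediationResult",
    "eqtm_scan",
    "fit_mediation_models",
    "indirect_effect_delta",
    "proportion_mediated",
    "infer_mediation",
    "stratified_mediation",
    "bootstrap_indirect_se",
]

EQTM_WINDOW = 100_000
Z95 = stats.norm.ppf(0.975)


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS coefficients and standard errors (classical, homoskedastic)."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = y.size - X.shape[1]
    if df <= 0:
        raise ValueError("not enough observations for the design")
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p


@dataclass
class MediationResult:
    total: float
    total_se: float
    direct: float
    direct_se: float
    b_exposure_mediator: float  # beta1: DNAm -> GE
    b_exposure_mediator_se: float
    b_mediator_outcome: float  # gamma2: GE -> FLI given DNAm
    b_mediator_outcome_se: float
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    proportion_mediated: float | None
    proportion_se: float | None
    proportion_ci: tuple[float, float] | None
    proportion_note: str | None
    n: int
    stratum: str | None = None

    @property
    def identity_gap(self) -> float:
        """total - (direct + indirect); ~0 for OLS on shared rows."""
        return self.total - (self.direct + self.indirect)


def eqtm_scan(
    cpg_id: str,
    cpg_pos: tuple[str, int],
    methylation_row: pd.Series,
    expression: pd.DataFrame,
    gene_positions: pd.DataFrame,
    covariates: pd.DataFrame,
    window: int = EQTM_WINDOW,
    candidate_alpha: float = 0.05,
) -> pd.DataFrame:
    """Associate one CpG with every transcript within the cis window.

    ``gene_positions`` (indexed by transcript id) needs columns
    ``chrom`` and ``pos`` (transcript anchor, 1-based). For each
    transcript with |pos - CpG pos| <= ``window`` fits
    ``expression ~ methylation + covariates`` (age, sex, BMI, smoking,
    alcohol by convention) and reports nominal p; pairs with
    p < ``candidate_alpha`` are flagged as mediation candidates.
    """
    chrom, pos = cpg_pos
    gp = gene_positions
    inwin = gp.index[(gp["chrom"] == chrom) & ((gp["pos"] - pos).abs() <= window)]
    inwin = inwin.intersection(expression.index)
    samples = methylation_row.index.intersection(expression.columns)
    samples = samples.intersection(covariates.index)
    m = methylation_row.loc[samples].to_numpy(dtype=float)
    C = covariates.loc[samples].to_numpy(dtype=float)
    rows = []
    for tid in sorted(inwin):
        e = expression.loc[tid, samples].to_numpy(dtype=float)
        keep = np.isfinite(e) & np.isfinite(m) & np.all(np.isfinite(C), axis=1)
        if keep.sum() < C.shape[1] + 5:
            continue
        X = np.column_stack([np.ones(keep.sum()), m[keep], C[keep]])
        beta, se, p = _ols(e[keep], X)
        rows.append(
            {
                "cpg": cpg_id,
                "transcript": tid,
                "distance": int(gp.at[tid, "pos"] - pos),
                "effect": beta[1],
                "se": se[1],
                "p": p[1],
                "n": int(keep.sum()),
                "candidate": p[1] < candidate_alpha,
            }
        )
    cols = ["cpg", "transcript", "distance", "effect", "se", "p", "n", "candidate"]
    return pd.DataFrame(rows, columns=cols)


def indirect_effect_delta(beta1, var_beta1, gamma2, var_gamma2):
    """Delta-method SE of the product beta1 * gamma2.

    First-order expansion with zero cross-model covariance (the two
    coefficients come from separate regressions):
    SE = sqrt(gamma2^2 var(beta1) + beta1^2 var(gamma2)).
    """
    if var_beta1 < 0 or var_gamma2 < 0:
        raise ValueError("variances must be non-negative")
    return float(np.sqrt(gamma2**2 * var_beta1 + beta1**2 * var_gamma2))


def proportion_mediated(
    indirect: float,
    total: float,
    var_indirect: float,
    var_total: float,
    cov: float = 0.0,
    total_tol: float = 1e-8,
):
    """Proportion mediated = indirect/total with a Delta-method SE.

    Gradient (1/total, -indirect/total^2) applied to the 2x2 covariance
    of (indirect, total); ``cov`` defaults to the plug-in zero
    cross-covariance. When |total| falls below ``total_tol`` the ratio
    is unstable and (None, None, None, reason) is returned instead of a
    number.
    """
    if var_indirect < 0 or var_total < 0:
        raise ValueError("variances must be non-negative")
    if abs(total) < total_tol:
        return None, None, None, "total effect too close to zero (ratio unstable)"
    est = indirect / total
    g = np.array([1.0 / total, -indirect / total**2])
    V = np.array([[var_indirect, cov], [cov, var_total]])
    se = float(np.sqrt(g @ V @ g))
    ci = (est - Z95 * se, est + Z95 * se)
    return est, se, ci, None


def fit_mediation_models(
    outcome: pd.Series,
    exposure: pd.Series,
    mediator: pd.Series,
    covariates: pd.DataFrame,
    stratum: str | None = None,
) -> MediationResult:
    """Three-model product-of-coefficients mediation decomposition.

    All three regressions are fitted on the identical complete-case
    rows (a row mismatch is a hard error, since the in-sample identity
    total = direct + indirect would silently break otherwise).
    ``covariates`` should already be numeric (categorical covariates
    such as the 3-level alcohol category dummy-coded by the caller or
    via :func:`encode_covariates`).
    """
    df = pd.DataFrame({"y": outcome, "x": exposure, "m": mediator}).join(
        covariates, how="inner"
    )
    before = len(df)
    df = df.dropna()
    if len(df) == 0:
        raise ValueError("no complete-case rows for mediation models")
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids would break row alignment")
    if before != len(df):
        logger.info("mediation: dropped %d incomplete rows", before - len(df))
    y = df["y"].to_numpy(dtype=float)
    x = df["x"].to_numpy(dtype=float)
    m = df["m"].to_numpy(dtype=float)
    C = df.drop(columns=["y", "x", "m"]).to_numpy(dtype=float)
    n = y.size
    ones = np.ones(n)
    X_tot = np.column_stack([ones, x, C])
    X_dir = np.column_stack([ones, x, m, C])
    X_med = np.column_stack([ones, x, C])
    b_tot, se_tot, _ = _ols(y, X_tot)
    b_dir, se_dir, _ = _ols(y, X_dir)
    b_med, se_med, _ = _ols(m, X_med)
    eta1, eta1_se = b_tot[1], se_tot[1]
    gamma1, gamma1_se = b_dir[1], se_dir[1]
    gamma2, gamma2_se = b_dir[2], se_dir[2]
    beta1, beta1_se = b_med[1], se_med[1]
    indirect = beta1 * gamma2
    ind_se = indirect_effect_delta(beta1, beta1_se**2, gamma2, gamma2_se**2)
    ci = (indirect - Z95 * ind_se, indirect + Z95 * ind_se)
    prop, prop_se, prop_ci, note = proportion_mediated(
        indirect, eta1, ind_se**2, eta1_se**2
    )
    return MediationResult(
        total=float(eta1),
        total_se=float(eta1_se),
        direct=float(gamma1),
        direct_se=float(gamma1_se),
        b_exposure_mediator=float(beta1),
        b_exposure_mediator_se=float(beta1_se),
        b_mediator_outcome=float(gamma2),
        b_mediator_outcome_se=float(gamma2_se),
        indirect=float(indirect),
        indirect_se=float(ind_se),
        indirect_ci=ci,
        proportion_mediated=prop,
        proportion_se=prop_se,
        proportion_ci=prop_ci,
        proportion_note=note,
        n=n,
        stratum=stratum,
    )


def infer_mediation(result: MediationResult) -> dict:
    """Decide mediated / not_mediated from the indirect-effect 95% CI.

    Mediated iff the CI excludes zero. An ``inconsistent_sign`` flag is
    raised when direct and indirect effects point in opposite
    directions, which suggests a mechanism other than straightforward
    expression regulation by methylation.
    """
    lo, hi = result.indirect_ci
    if not (lo <= hi):
        raise ValueError("indirect-effect CI bounds are not ordered")
    mediated = not (lo <= 0.0 <= hi)
    inconsistent = (
        mediated
        and result.direct != 0
        and np.sign(result.direct) != np.sign(result.indirect)
    )
    return {
        "decision": "mediated" if mediated else "not_mediated",
        "inconsistent_sign": bool(inconsistent),
    }


def encode_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code any non-numeric covariate columns (drop-first)."""
    out = pd.get_dummies(df, drop_first=True)
    return out.astype(float)


def stratified_mediation(
    outcome: pd.Series,
    exposure: pd.Series,
    mediator: pd.Series,
    covariates: pd.DataFrame,
    strata: pd.Series,
    min_n: int = 100,
) -> dict[str, MediationResult]:
    """Full mediation decomposition separately per stratum (e.g. BMI).

    Strata below ``min_n`` complete samples are skipped with a warning.
    """
    out: dict[str, MediationResult] = {}
    for label in pd.unique(strata.dropna()):
        idx = strata.index[strata == label]
        idx = idx.intersection(outcome.index)
        if len(idx) < min_n:
            logger.warning("stratum %r skipped (n=%d < %d)", label, len(idx), min_n)
            continue
        out[str(label)] = fit_mediation_models(
            outcome.loc[idx],
            exposure.loc[idx],
            mediator.loc[idx],
            covariates.loc[idx],
            stratum=str(label),
        )
    return out


def bootstrap_indirect_se(
    outcome: pd.Series,
    exposure: pd.Series,
    mediator: pd.Series,
    covariates: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Nonparametric bootstrap SE of the indirect effect and proportion.

    Resamples rows with replacement; serves as an independent
    cross-check of the Delta-method standard errors.
    """
    df = pd.DataFrame({"y": outcome, "x": exposure, "m": mediator}).join(
        covariates, how="inner"
    ).dropna()
    y = df["y"].to_numpy(dtype=float)
    x = df["x"].to_numpy(dtype=float)
    m = df["m"].to_numpy(dtype=float)
    C = df.drop(columns=["y", "x", "m"]).to_numpy(dtype=float)
    n = y.size
    ones = np.ones(n)
    rng = np.random.default_rng(seed)
    ind = np.empty(n_boot)
    prop = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yy, xx, mm, CC = y[idx], x[idx], m[idx], C[idx]
        o = np.ones(n)
        bd, _, _ = _ols(yy, np.column_stack([o, xx, mm, CC]))
        bm, _, _ = _ols(mm, np.column_stack([o, xx, CC]))
        bt, _, _ = _ols(yy, np.column_stack([o, xx, CC]))
        ind[b] = bm[1] * bd[2]
        if abs(bt[1]) > 1e-8:
            prop[b] = ind[b] / bt[1]
    return {
        "indirect_se": float(np.std(ind, ddof=1)),
        "proportion_se": float(np.nanstd(prop, ddof=1)),
        "n_boot": n_boot,
        "n": n,
    }
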