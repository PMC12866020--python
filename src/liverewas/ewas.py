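"""Per-CpG association testing with covariate adjustment.

Each CpG is tested with an ordinary-least-squares model
``outcome ~ CpG + covariates`` (binary outcomes use the same linear
contract on the 0/1 indicator — a linear probability model — with a
logistic option). Study-level diagnostics cover genomic inflation
(lambda) and an empirical-null correction that estimates bias and
inflation of the z-score distribution from a three-component Gaussian
mixture and rescales the statistics, followed by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EwasResult",
    "EmpiricalNull",
    "fit_cpg_model",
    "run_ewas",
    "stratified_ewas",
    "genomic_inflation_lambda",
    "empirical_null_correct",
    "benjamini_hochberg",
]

# median of the 1-df chi-square distribution, the null reference for lambda
_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)


@dataclass
class EmpiricalNull:
    """Estimated empirical-null parameters of a z-score vector."""

    bias: float
    inflation: float
    prop_null: float
    converged: bool
    n_iter: int
    z_corrected: np.ndarray | None = None
    p_corrected: np.ndarray | None = None


@dataclass
class EwasResult:
    """Per-CpG association table plus study-level inflation diagnostics."""

    table: pd.DataFrame
    outcome: str
    n_samples: int
    lambda_raw: float
    lambda_corrected: float | None = None
    empirical_null: EmpiricalNull | None = None
    correction_applied: bool = False
    notes: dict = field(default_factory=dict)


def _design_matrix(x: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = x.shape[0]
    cols = [np.ones(n), x]
    if covariates is not None and covariates.size:
        cols.extend(np.asarray(covariates, dtype=float).T)
    return np.column_stack(cols)


def fit_cpg_model(
    y,
    x,
    covariates=None,
    binary: bool | None = None,
    link: str = "linear",
    column_names=None,
):
    """Fit one CpG's association model and return effect, SE, z, p, n.

    ``y`` is the outcome (continuous, typically inverse-normal
    transformed, or a 0/1 indicator), ``x`` the CpG beta-values and
    ``covariates`` an optional n x p array/DataFrame. Rows with any
    missing value are dropped. With ``link="linear"`` (default) the
    binary case is a linear probability model; ``link="logistic"``
    scores a logistic regression instead.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            column_names = column_names or list(covariates.columns)
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        keep = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(C), axis=1)
        C = C[keep]
    else:
        C = None
        keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    n = y.shape[0]
    X = _design_matrix(x, C)
    k = X.shape[1]
    if n <= k + 2:
        raise ValueError(f"too few complete cases (n={n}) for {k} predictors")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        names = ["intercept", "cpg"] + list(
            column_names or [f"cov{i}" for i in range(k - 2)]
        )
        # identify columns whose removal restores full rank
        offending = []
        for j in range(k):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                offending.append(names[j])
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {k}); "
            f"collinear columns involve: {offending}"
        )
    if link == "logistic" or (binary and link == "logistic"):
        import statsmodels.api as sm

        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        effect, se = fit.params[1], fit.bse[1]
        z = effect / se
        p = 2.0 * stats.norm.sf(abs(z))
        return {"effect": effect, "se": se, "z": z, "p": p, "n": n}
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = resid @ resid / df
    se = float(np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1]))
    effect = float(beta[1])
    t = effect / se
    p = float(np.clip(2.0 * stats.t.sf(abs(t), df), 1e-320, 1.0))
    z = _z_from_p(p, effect)
    return {"effect": effect, "se": se, "z": z, "p": p, "n": n}


def _z_from_p(p, effect):
    """Signed normal quantile of a two-sided p (METAL-style z)."""
    p = np.clip(p, 1e-320, 1.0)
    return np.sign(effect) * stats.norm.isf(p / 2.0)


def genomic_inflation_lambda(z=None, p=None, min_tests: int = 100) -> float:
    """Genomic inflation factor lambda = median(z^2) / median(chi^2_1).

    Accepts either z-scores or two-sided p-values; equals 1 in
    expectation under the null.
    """
    if z is None:
        if p is None:
            raise ValueError("provide z-scores or p-values")
        p = np.asarray(p, dtype=float)
        p = p[np.isfinite(p)]
        chi2 = stats.chi2.isf(p, 1)
    else:
        z = np.asarray(z, dtype=float)
        z = z[np.isfinite(z)]
        chi2 = z**2
    if chi2.size < min_tests:
        raise ValueError(f"need at least {min_tests} tests to estimate lambda")
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def benjamini_hochberg(p):
    """Benjamini-Hochberg step-up FDR q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over ranked p-values; monotone
    non-decreasing in ranked p and >= p elementwise after the
    cumulative-minimum step. Input values must lie in (0, 1].
    """
    arr = np.asarray(p, dtype=float)
    flat = arr.ravel()
    finite = np.isfinite(flat)
    vals = flat[finite]
    if np.any((vals <= 0) | (vals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = vals.size
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order]
    q = ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.full(flat.shape, np.nan)
    idx = np.flatnonzero(finite)[order]
    out[idx] = q
    out = out.reshape(arr.shape)
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


def _em_gmm3(z, mu0, sd0, pi0, rng, max_iter=5000, tol=1e-9):
    """Constrained EM for a 3-component Gaussian mixture.

    Component 0 is the central null; components 1 and 2 model left and
    right tail associations. Constraints keep the decomposition
    identifiable on (near-)pure-Gaussian input: tail means stay at
    least 3 null-SDs away from the null mean, tail SDs are at least
    the null SD, and the null weight is bounded below at 0.5. Returns
    (means, sds, weights, loglik, converged, n_iter).
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    lo, hi = np.quantile(z, [0.01, 0.99])
    mu = np.array([mu0, min(lo, mu0 - 2.0), max(hi, mu0 + 2.0)])
    sd = np.array([sd0, 2.0 * sd0, 2.0 * sd0])
    w = np.array([pi0, (1 - pi0) / 2, (1 - pi0) / 2])
    if rng is not None:
        mu = mu + rng.normal(0, 0.05, 3)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = np.empty((3, n))
        for k in range(3):
            dens[k] = w[k] * stats.norm.pdf(z, mu[k], sd[k])
        tot = np.maximum(dens.sum(axis=0), 1e-300)
        resp = dens / tot
        ll = float(np.sum(np.log(tot)))
        nk = np.maximum(resp.sum(axis=1), 1e-12)
        mu = resp @ z / nk
        for k in range(3):
            sd[k] = np.sqrt(resp[k] @ (z - mu[k]) ** 2 / nk[k])
        sd = np.maximum(sd, 1e-3)
        w = nk / n
        # identifiability constraints (empirical-null style priors)
        mu[1] = min(mu[1], mu[0] - 3.0 * sd[0])
        mu[2] = max(mu[2], mu[0] + 3.0 * sd[0])
        sd[1] = max(sd[1], sd[0])
        sd[2] = max(sd[2], sd[0])
        if w[0] < 0.5:
            w[0] = 0.5
            rest = w[1] + w[2]
            w[1:] = 0.5 * w[1:] / rest if rest > 0 else 0.25
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_old = ll
    return mu, sd, w, ll, converged, it


def empirical_null_correct(
    z,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 2000,
    min_tests: int = 100,
):
    """Estimate bias and inflation of the empirical null and rescale z.

    A three-component Gaussian mixture (one dominant central null plus a
    left and a right tail component for true associations) is fitted by
    expectation-maximization, initialized at (mean 0, SD 1, weight 0.9)
    with seeded random restarts. The null component's mean is the bias
    and its SD the inflation; corrected statistics are
    ``(z - bias) / inflation`` with two-sided normal p-values. If EM
    fails to converge the raw statistics are returned with a warning and
    ``converged=False``.
    """
    z = np.asarray(z, dtype=float)
    zin = z[np.isfinite(z)]
    if zin.size < min_tests:
        raise ValueError(f"need at least {min_tests} z-scores")
    best = None
    rng = np.random.default_rng(seed)
    for r in range(max(1, n_restarts)):
        mu, sd, w, ll, conv, it = _em_gmm3(
            zin, 0.0, 1.0, 0.9, rng if r > 0 else None, max_iter=max_iter
        )
        if best is None or ll > best[3]:
            best = (mu, sd, w, ll, conv, it)
    mu, sd, w, ll, conv, it = best
    null_k = int(np.argmax(w))
    bias = float(mu[null_k])
    inflation = float(sd[null_k])
    prop_null = float(w[null_k])
    if not conv:
        logger.warning("empirical-null EM did not converge after %d iterations; "
                       "returning raw statistics", it)
        zc = z.copy()
    else:
        zc = (z - bias) / inflation
    pc = 2.0 * stats.norm.sf(np.abs(zc))
    pc = np.clip(pc, np.nextafter(0, 1), 1.0)
    return EmpiricalNull(
        bias=bias,
        inflation=inflation,
        prop_null=prop_null,
        converged=conv,
        n_iter=it,
        z_corrected=zc,
        p_corrected=pc,
    )


def _residualize(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of the columns of A after OLS projection on C."""
    coef, *_ = np.linalg.lstsq(C, A, rcond=None)
    return A - C @ coef


def run_ewas(
    methylation: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    binary: bool = False,
    link: str = "linear",
    inflation_trigger: float = 1.1,
    correction_min_tests: int = 1000,
    min_cpgs: int = 100,
    fdr_alpha: float = 0.05,
    seed: int = 0,
) -> EwasResult:
    """Epigenome-wide scan of one outcome across all CpGs.

    ``methylation`` is a CpG x sample DataFrame of beta-values;
    ``outcome`` and ``covariates`` are indexed by sample. Fits
    ``outcome ~ CpG + covariates`` per CpG, computes the genomic
    inflation factor, applies the empirical-null correction when the raw
    lambda exceeds ``inflation_trigger`` (and enough tests are
    available), and attaches BH q-values computed from the final
    p-vector. Binary outcomes additionally get ``delta_beta``, the crude
    case-minus-control difference in mean beta-value.
    """
    if methylation.shape[0] < min_cpgs:
        raise ValueError(f"need at least {min_cpgs} CpGs (got {methylation.shape[0]})")
    samples = methylation.columns.intersection(outcome.index)
    if covariates is not None:
        samples = samples.intersection(covariates.index)
    y = outcome.loc[samples].to_numpy(dtype=float)
    C = (
        covariates.loc[samples].to_numpy(dtype=float)
        if covariates is not None
        else np.empty((len(samples), 0))
    )
    keep = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    y, C = y[keep], C[keep]
    M = methylation.loc[:, samples].to_numpy(dtype=float)[:, keep]
    n = y.size
    Cd = np.column_stack([np.ones(n), C])
    p_cov = Cd.shape[1]

    eff = np.full(M.shape[0], np.nan)
    se = np.full(M.shape[0], np.nan)
    pvals = np.full(M.shape[0], np.nan)
    nobs = np.full(M.shape[0], n, dtype=int)

    complete = np.all(np.isfinite(M), axis=1)
    if complete.any():
        # Frisch-Waugh-Lovell: residualize outcome and CpGs on covariates,
        # then per-CpG simple regression — identical to the full OLS fit.
        ry = _residualize(y[:, None], Cd)[:, 0]
        RX = _residualize(M[complete].T, Cd)
        rxx = np.einsum("ij,ij->j", RX, RX)
        ok = rxx > 1e-12
        b = np.full(RX.shape[1], np.nan)
        b[ok] = (RX.T @ ry)[ok] / rxx[ok]
        df = n - p_cov - 1
        rss = (ry @ ry) - b**2 * rxx
        sig2 = rss / df
        s = np.sqrt(np.where(ok, sig2 / np.where(ok, rxx, 1.0), np.nan))
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = b / s
        pv = np.clip(2.0 * stats.t.sf(np.abs(tstat), df), 1e-320, 1.0)
        idx = np.flatnonzero(complete)
        eff[idx], se[idx], pvals[idx] = b, s, pv
    for i in np.flatnonzero(~complete):
        xi = M[i]
        m = np.isfinite(xi)
        nobs[i] = int(m.sum())
        if nobs[i] <= p_cov + 3 or np.nanstd(xi) < 1e-12:
            continue
        try:
            fit = fit_cpg_model(y[m], xi[m], C[m] if C.size else None, link=link)
        except (ValueError, np.linalg.LinAlgError):
            continue
        eff[i], se[i], pvals[i] = fit["effect"], fit["se"], fit["p"]

    z = _z_from_p(pvals, eff)
    lam_raw = genomic_inflation_lambda(z=z[np.isfinite(z)])
    table = pd.DataFrame(
        {
            "effect": eff,
            "se": se,
            "z": z,
            "p": pvals,
            "n": nobs,
        },
        index=methylation.index,
    )
    result = EwasResult(
        table=table,
        outcome=getattr(outcome, "name", "outcome") or "outcome",
        n_samples=n,
        lambda_raw=lam_raw,
    )
    final_p = pvals
    zin = z[np.isfinite(z)]
    if lam_raw > inflation_trigger and zin.size >= correction_min_tests:
        en = empirical_null_correct(z[np.isfinite(z)], seed=seed)
        zc = np.full_like(z, np.nan)
        pc = np.full_like(z, np.nan)
        zc[np.isfinite(z)] = en.z_corrected
        pc[np.isfinite(z)] = en.p_corrected
        table["z_corrected"] = zc
        table["p_corrected"] = pc
        result.empirical_null = en
        result.correction_applied = en.converged
        if en.converged:
            final_p = pc
            result.lambda_corrected = genomic_inflation_lambda(
                z=zc[np.isfinite(zc)]
            )
    fin = np.isfinite(final_p)
    q = np.full_like(final_p, np.nan)
    if fin.any():
        q[fin] = benjamini_hochberg(final_p[fin])
    table["q"] = q
    if binary:
        cases = y == 1
        mc = np.nanmean(M[:, cases], axis=1)
        mn = np.nanmean(M[:, ~cases], axis=1)
        table["delta_beta"] = mc - mn
        result.notes["n_cases"] = int(cases.sum())
        result.notes["n_controls"] = int((~cases).sum())
    result.notes["n_failed_cpgs"] = int(np.sum(~np.isfinite(pvals)))
    return result


def stratified_ewas(
    methylation: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None,
    strata: pd.Series,
    min_n: int = 50,
    **kwargs,
) -> dict[str, EwasResult]:
    """Independent EWAS per stratum of a per-sample stratifier.

    Strata with fewer than ``min_n`` samples are skipped with a logged
    warning. Returns a mapping stratum label -> EwasResult.
    """
    out: dict[str, EwasResult] = {}
    for label in pd.unique(strata.dropna()):
        samples = strata.index[strata == label]
        samples = methylation.columns.intersection(samples)
        if len(samples) < min_n:
            logger.warning(
                "stratum %r skipped: n=%d below minimum %d", label, len(samples), min_n
            )
            continue
        res = run_ewas(
            methylation.loc[:, samples],
            outcome.loc[samples],
            covariates.loc[samples] if covariates is not None else None,
            **kwargs,
        )
        res.notes["stratum"] = label
        res.notes["stratum_n"] = int(len(samples))
        out[str(label)] = res
    return out
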