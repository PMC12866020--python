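"""Inverse-variance-weighted fixed-effect meta-analysis and replication.

Per-cohort EWAS summary statistics are pooled with weights 1/SE^2; the
replication rule keeps CpGs that are FDR-significant in at least two
cohorts. Cross-generation summaries order effects by cohort mean age to
flag age-monotone association patterns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = ["ivw_meta", "replication_filter", "cross_generation_summary"]


def _direction_char(effect: float) -> str:
    if not np.isfinite(effect):
        return "?"
    return "+" if effect > 0 else ("-" if effect < 0 else "0")


def ivw_meta(
    cohort_tables: dict[str, pd.DataFrame],
    min_cohorts: int = 2,
    fdr: bool = True,
) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis across cohorts.

    ``cohort_tables`` maps cohort name -> per-CpG DataFrame with columns
    ``effect`` and ``se`` (CpG ids as index). For each CpG present with
    finite effect and positive SE in at least ``min_cohorts`` cohorts:
    weights w_i = 1/SE_i^2, pooled effect = sum(w_i b_i)/sum(w_i),
    pooled SE = sum(w_i)^(-1/2), Z = effect/SE with a two-sided normal
    p. The direction string carries one sign character per cohort in the
    (fixed) input order, "?" where a cohort is missing. Cochran's Q and
    I^2 heterogeneity diagnostics are reported as extensions.
    """
    names = list(cohort_tables)
    if len(names) < 2:
        raise ValueError("meta-analysis requires at least two cohorts")
    for name, tab in cohort_tables.items():
        if (tab["se"] <= 0).any():
            raise ValueError(f"cohort {name!r} contains non-positive SEs")
    all_cpgs = pd.Index([])
    for tab in cohort_tables.values():
        all_cpgs = all_cpgs.union(tab.index)
    B = pd.DataFrame(
        {n: t["effect"].reindex(all_cpgs) for n, t in cohort_tables.items()}
    )
    S = pd.DataFrame({n: t["se"].reindex(all_cpgs) for n, t in cohort_tables.items()})
    ok = np.isfinite(B.to_numpy()) & np.isfinite(S.to_numpy()) & (S.to_numpy() > 0)
    k = ok.sum(axis=1)
    usable = k >= min_cohorts
    dropped = int((~usable).sum())
    if dropped:
        logger.info("%d CpGs excluded: present in fewer than %d cohorts",
                    dropped, min_cohorts)
    W = np.where(ok, 1.0 / np.square(S.to_numpy()), 0.0)
    Bv = np.where(ok, B.to_numpy(), 0.0)
    wsum = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = (W * Bv).sum(axis=1) / wsum
        pooled_se = 1.0 / np.sqrt(wsum)
    zscore = pooled / pooled_se
    pval = 2.0 * stats.norm.sf(np.abs(zscore))
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    # Cochran's Q / I^2 (diagnostic extension, not part of the selection rule)
    with np.errstate(invalid="ignore"):
        q_het = np.nansum(W * (Bv - pooled[:, None]) ** 2 * ok, axis=1)
        i2 = np.where(k > 1, np.maximum(0.0, (q_het - (k - 1)) / np.maximum(q_het, 1e-300)), np.nan)
    direction = [
        "".join(
            _direction_char(B.iloc[i, j]) if ok[i, j] else "?"
            for j in range(len(names))
        )
        for i in range(len(all_cpgs))
    ]
    out = pd.DataFrame(
        {
            "effect": pooled,
            "se": pooled_se,
            "z": zscore,
            "p": pval,
            "direction": direction,
            "n_cohorts": k,
            "q_het": q_het,
            "i2": i2,
        },
        index=all_cpgs,
    )
    out = out[usable]
    if fdr and len(out):
        out["q"] = benjamini_hochberg(out["p"])
    return out


def replication_filter(
    cohort_tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    min_cohorts: int = 2,
    require_same_direction: bool = False,
) -> pd.DataFrame:
    """CpGs FDR-significant (q < alpha) in at least ``min_cohorts`` cohorts.

    ``cohort_tables`` maps cohort -> DataFrame with columns ``q`` and
    ``effect``. A CpG missing from a cohort counts as non-significant
    there. Returns one row per CpG with the per-cohort significance
    pattern, the significant-cohort count and the ``replicated`` flag;
    direction consistency is optional (off by default).
    """
    names = list(cohort_tables)
    all_cpgs = pd.Index([])
    for tab in cohort_tables.values():
        all_cpgs = all_cpgs.union(tab.index)
    Q = pd.DataFrame({n: t["q"].reindex(all_cpgs) for n, t in cohort_tables.items()})
    B = pd.DataFrame(
        {n: t["effect"].reindex(all_cpgs) for n, t in cohort_tables.items()}
    )
    missing = Q.isna().sum().sum()
    if missing:
        logger.info("%d cohort x CpG cells missing; counted as non-significant",
                    int(missing))
    sig = (Q < alpha).fillna(False)
    count = sig.sum(axis=1)
    replicated = count >= min_cohorts
    if require_same_direction:
        signs = np.sign(B.where(sig))
        consistent = signs.apply(
            lambda r: len({s for s in r if np.isfinite(s)}) <= 1, axis=1
        )
        replicated = replicated & consistent
    pattern = sig.apply(lambda r: "".join("S" if v else "." for v in r), axis=1)
    out = pd.DataFrame(
        {
            "pattern": pattern,
            "cohorts_significant": count,
            "replicated": replicated,
            "direction": [
                "".join(_direction_char(B.loc[c, n]) for n in names)
                for c in all_cpgs
            ],
        },
        index=all_cpgs,
    )
    return out


def cross_generation_summary(
    generation_tables: dict[str, pd.DataFrame],
    mean_ages: dict[str, float],
    cpgs=None,
) -> pd.DataFrame:
    """Per-CpG effects across generations with an age-trend flag.

    ``generation_tables`` maps generation label -> EWAS table (columns
    ``effect``, ``se``, ``p``); ``mean_ages`` gives each generation's
    mean age. Rows are emitted for every requested CpG even when a
    generation lacks it (missing cells, not dropped). The trend flag is
    "monotone_with_age" when |effect| increases strictly with
    generation age, else "non_monotone".
    """
    order = sorted(generation_tables, key=lambda g: mean_ages[g])
    if cpgs is None:
        cpgs = pd.Index([])
        for tab in generation_tables.values():
            cpgs = cpgs.union(tab.index)
    rows = []
    for cpg in cpgs:
        row: dict = {"cpg": cpg}
        absmag = []
        for gen in order:
            tab = generation_tables[gen]
            if cpg in tab.index:
                row[f"effect_{gen}"] = tab.at[cpg, "effect"]
                row[f"se_{gen}"] = tab.at[cpg, "se"]
                row[f"p_{gen}"] = tab.at[cpg, "p"]
                absmag.append(abs(tab.at[cpg, "effect"]))
            else:
                row[f"effect_{gen}"] = np.nan
                row[f"se_{gen}"] = np.nan
                row[f"p_{gen}"] = np.nan
                absmag.append(np.nan)
        finite = [v for v in absmag if np.isfinite(v)]
        if len(finite) == len(absmag) and all(
            b > a for a, b in zip(absmag, absmag[1:])
        ):
            row["trend"] = "monotone_with_age"
        else:
            row["trend"] = "non_monotone"
        rows.append(row)
    return pd.DataFrame(rows).set_index("cpg")
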