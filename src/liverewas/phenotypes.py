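"""Derivation of analysis phenotypes.

Fatty liver index (FLI), rank-based inverse-normal transformation of
skewed liver variables (GGT, ALT, AST, FLI), alcohol-consumption
categories and BMI strata used to stratify downstream models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fatty_liver_index",
    "inverse_normal_transform",
    "categorize_alcohol_mediation",
    "classify_alcohol_consumption",
    "bmi_strata",
    "MMOL_TO_MGDL_TG",
]

# triglyceride unit conversion: 1 mmol/l = 88.57 mg/dl
MMOL_TO_MGDL_TG = 88.57

# alcohol: one standard drink = 12 g pure ethanol
GRAMS_PER_DRINK = 12.0
# weekly moderate-consumption ceilings (g/week)
MODERATE_WEEKLY_G = {"female": 350.0, "male": 420.0}


def fatty_liver_index(
    triglycerides,
    bmi,
    ggt,
    waist,
    tg_unit: str = "mg/dl",
):
    """Fatty liver index on the 0-100 scale.

    FLI = 100 * e^L / (1 + e^L) with
    L = 0.953*ln(TG) + 0.139*BMI + 0.718*ln(GGT) + 0.053*waist - 15.745,
    TG in mg/dl, BMI in kg/m^2, GGT in U/l, waist in cm. Values above 60
    are conventionally taken to suggest hepatic steatosis.

    Parameters
    ----------
    triglycerides : array-like
        Serum triglycerides; unit controlled by ``tg_unit``
        ("mg/dl" or "mmol/l"; mmol/l is converted with the factor 88.57).
    bmi, ggt, waist : array-like
        Body mass index, gamma-glutamyltransferase, waist circumference.
    """
    tg = np.asarray(triglycerides, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    ggt = np.asarray(ggt, dtype=float)
    waist = np.asarray(waist, dtype=float)
    if tg_unit == "mmol/l":
        tg = tg * MMOL_TO_MGDL_TG
    elif tg_unit != "mg/dl":
        raise ValueError(f"unknown triglyceride unit: {tg_unit!r}")
    if np.any(tg <= 0) or np.any(ggt <= 0):
        raise ValueError("triglycerides and GGT must be strictly positive (log undefined)")
    if np.any(bmi <= 0) or np.any(waist <= 0):
        raise ValueError("BMI and waist circumference must be strictly positive")
    L = 0.953 * np.log(tg) + 0.139 * bmi + 0.718 * np.log(ggt) + 0.053 * waist - 15.745
    out = 100.0 * stats.logistic.cdf(L)
    if out.ndim == 0:
        return float(out)
    return out


def inverse_normal_transform(values, offset: float = 3.0 / 8.0):
    """Rank-based inverse-normal transformation.

    Maps values to Phi^-1((r - c) / (n - 2c + 1)) where r is the
    (average, tie-aware) rank among non-missing entries and c is the
    rank offset (Blom's c = 3/8 by default; c = 1/2 gives Tukey, c = 0
    the plain ECDF variant). Missing values propagate as NaN.
    """
    x = np.asarray(values, dtype=float)
    index = values.index if isinstance(values, pd.Series) else None
    flat = x.ravel()
    mask = np.isfinite(flat)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values to rank-transform")
    obs = flat[mask]
    if np.all(obs == obs[0]):
        raise ValueError("all values identical: no rank information to transform")
    ranks = stats.rankdata(obs, method="average")
    scores = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    out = np.full(flat.shape, np.nan)
    out[mask] = scores
    out = out.reshape(x.shape)
    if index is not None:
        return pd.Series(out, index=index, name=getattr(values, "name", None))
    return out


def categorize_alcohol_mediation(grams_per_day: float) -> str:
    """Three-level alcohol category used as a mediation covariate.

    0 g/day -> "none"; up to one standard drink (12 g) -> "up_to_one";
    above one drink -> "more_than_one". The boundary of exactly one
    drink per day falls in "up_to_one".
    """
    g = float(grams_per_day)
    if g < 0:
        raise ValueError("alcohol intake cannot be negative")
    if g == 0:
        return "none"
    if g <= GRAMS_PER_DRINK:
        return "up_to_one"
    return "more_than_one"


def classify_alcohol_consumption(grams_per_day: float, sex: str | int) -> str:
    """Weekly-consumption class: none / moderate / excess.

    Moderate means a weekly intake of at most 350 g for females and
    420 g for males; anything above is excess. ``sex`` accepts
    "female"/"male" or the codes 0 (female) / 1 (male).
    """
    g = float(grams_per_day)
    if g < 0:
        raise ValueError("alcohol intake cannot be negative")
    if isinstance(sex, str):
        key = sex.lower()
    elif sex in (0, 1):
        key = "female" if sex == 0 else "male"
    else:
        key = str(sex)
    if key not in MODERATE_WEEKLY_G:
        raise ValueError(f"unknown sex code: {sex!r}")
    if g == 0:
        return "none"
    weekly = 7.0 * g
    return "moderate" if weekly <= MODERATE_WEEKLY_G[key] else "excess"


def bmi_strata(bmi: float) -> str:
    """BMI stratum: "normal_weight" below 25 kg/m^2, else "overweight_obese"."""
    b = float(bmi)
    if b <= 0:
        raise ValueError("BMI must be positive")
    return "normal_weight" if b < 25.0 else "overweight_obese"


def derive_phenotypes(covariates: pd.DataFrame, tg_unit: str = "mmol/l") -> pd.DataFrame:
    """Append derived phenotype columns to a per-sample covariate table.

    Expects columns ``triglycerides`` (unit per ``tg_unit``), ``bmi``,
    ``ggt``, ``waist``, ``alcohol`` (g/day) and ``sex`` (0/1). Adds
    ``fli``, inverse-normal transformed ``*_int`` columns for every
    liver variable present, ``alcohol_mediation_cat``,
    ``alcohol_class`` and ``bmi_stratum``.
    """
    out = covariates.copy()
    out["fli"] = fatty_liver_index(
        out["triglycerides"], out["bmi"], out["ggt"], out["waist"], tg_unit=tg_unit
    )
    for col in ("ggt", "alt", "ast", "fli"):
        if col in out:
            out[f"{col}_int"] = inverse_normal_transform(out[col])
    out["alcohol_mediation_cat"] = [
        categorize_alcohol_mediation(g) for g in out["alcohol"]
    ]
    out["alcohol_class"] = [
        classify_alcohol_consumption(g, s) for g, s in zip(out["alcohol"], out["sex"])
    ]
    out["bmi_stratum"] = [bmi_strata(b) for b in out["bmi"]]
    return out
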