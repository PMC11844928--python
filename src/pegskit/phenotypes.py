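"""Cardiometabolic trait derivation and covariate coding.

Builds the analysis sample table from raw measurements:

* blood pressure: per-reading censoring (SBP > 250 mmHg, DBP < 40 mmHg
  removed, each channel independently), then the mean of surviving readings;
* BMI = weight (kg) / height (m)²;
* LDL-C by the Friedewald formula (TC − HDL-C − TG/5), defined only when
  TG < 400 mg/dL;
* CRP, HDL-C, TG and fasting glucose natural-log-transformed; glucose is
  restricted to self-reported fasting samples;
* every trait winsorized at mean ± 5 SD on its analysis scale;
* NIAAA drinking categories from drinks/day (weekly units / 7), smoking and
  education dichotomies for the moderation analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SBP_CENSOR_ABOVE = 250.0  # mmHg; readings strictly above are artifacts
DBP_CENSOR_BELOW = 40.0   # mmHg; readings strictly below are artifacts
FRIEDEWALD_TG_MAX = 400.0  # mg/dL; formula invalid at or above
WINSOR_SD = 5.0

SEXES = ("male", "female")
RACE_LEVELS = ("nh_white", "nh_black", "hispanic", "other")
EDUCATION3_LEVELS = ("lt_hs", "hs", "college")
SMOKING3_LEVELS = ("never", "former", "current")
DRINKER3_LEVELS = ("nondrinker", "moderate", "heavy")


@dataclass(frozen=True)
class TraitInfo:
    """Analysis metadata for one cardiometabolic trait."""

    key: str
    column: str          # analysis-scale column in the sample table
    label: str
    ln_scale: bool       # modeled on the natural-log scale
    medication: str | None   # relevant medication-use covariate
    fasting_adjust: bool     # model adjusts for fasting status
    fasting_only: bool = False   # measured only in fasting samples


TRAITS: dict[str, TraitInfo] = {
    "sbp": TraitInfo("sbp", "sbp", "SBP (mmHg)", False, "htn_med", False),
    "dbp": TraitInfo("dbp", "dbp", "DBP (mmHg)", False, "htn_med", False),
    "bmi": TraitInfo("bmi", "bmi", "BMI (kg/m2)", False, None, False),
    "crp": TraitInfo("crp", "ln_crp", "ln(CRP mg/L)", True, None, False),
    "hdl": TraitInfo("hdl", "ln_hdl", "ln(HDL-C mg/dL)", True, "lipid_med", False),
    "ldl": TraitInfo("ldl", "ldl", "LDL-C (mg/dL)", False, "lipid_med", True),
    "tg": TraitInfo("tg", "ln_tg", "ln(TG mg/dL)", True, "lipid_med", True),
    "glucose": TraitInfo(
        "glucose", "ln_glucose", "ln(fasting glucose mg/dL)", True, "diab_med",
        False, fasting_only=True,
    ),
}


def process_blood_pressure(
    readings: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Censor artifact readings and average the survivors per channel.

    SBP readings exceeding 250 mmHg and DBP readings below 40 mmHg are removed
    independently; the mean of the remaining readings is returned per channel.
    A channel with no surviving readings is NaN.  Values exactly at the
    thresholds are kept (censoring is strict).
    """
    if not readings:
        raise ValueError("at least one blood-pressure reading is required")
    sbp = [s for s, _ in readings if not math.isnan(s) and s <= SBP_CENSOR_ABOVE]
    dbp = [d for _, d in readings if not math.isnan(d) and d >= DBP_CENSOR_BELOW]
    sbp_mean = float(np.mean(sbp)) if sbp else float("nan")
    dbp_mean = float(np.mean(dbp)) if dbp else float("nan")
    return sbp_mean, dbp_mean


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight in kg divided by height in meters squared."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m**2


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """Friedewald LDL-C (mg/dL): TC − HDL-C − TG/5, valid only for TG < 400.

    Returns NaN when TG >= 400 mg/dL (strict boundary: 400 itself excluded)
    or when any input is missing.
    """
    if any(pd.isna(x) for x in (tc, hdl, tg)):
        return float("nan")
    if min(tc, hdl, tg) < 0:
        raise ValueError("lipid inputs must be nonnegative")
    if tg >= FRIEDEWALD_TG_MAX:
        return float("nan")
    return tc - hdl - tg / 5.0


def classify_drinker(drinks_per_week: float, age: float, sex: str) -> str:
    """NIAAA drinking category from weekly units, age at blood draw and sex.

    Drinks/day = weekly units / 7.  Heavy: >2/day (men aged 65 or younger),
    >1/day (women 65 or younger, and everyone older than 65).  Zero drinks is
    a nondrinker; anything positive below the heavy cutoff is moderate.
    """
    if drinks_per_week < 0:
        raise ValueError("drinks_per_week must be nonnegative")
    if sex not in SEXES:
        raise ValueError(f"unknown sex level {sex!r}")
    per_day = drinks_per_week / 7.0
    if per_day == 0:
        return "nondrinker"
    cutoff = 2.0 if (age <= 65 and sex == "male") else 1.0
    return "heavy" if per_day > cutoff else "moderate"


def winsorize(values: pd.Series, n_sd: float = WINSOR_SD) -> pd.Series:
    """Clip values beyond ``n_sd`` sample SDs from the mean to that fence.

    The fence uses the pre-winsorization mean and SD over non-missing values,
    in a single pass.
    """
    x = pd.to_numeric(values, errors="coerce")
    mu, sd = x.mean(), x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return x
    return x.clip(lower=mu - n_sd * sd, upper=mu + n_sd * sd)


def _safe_log(x: pd.Series, name: str) -> pd.Series:
    x = pd.to_numeric(x, errors="coerce")
    bad = x.notna() & (x <= 0)
    if bad.any():
        logger.warning(
            "%s: %d nonpositive values set to missing before log", name, int(bad.sum())
        )
        x = x.mask(bad)
    return np.log(x)


def transform_and_winsorize_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Apply log transforms, the fasting restriction, and 5-SD winsorization.

    Expects raw-scale columns ``sbp``, ``dbp``, ``bmi``, ``crp``, ``hdl``,
    ``ldl``, ``tg``, ``glucose`` and boolean ``fasting``.  Adds the
    log-scale columns (``ln_crp``, ``ln_hdl``, ``ln_tg``, ``ln_glucose``) and
    winsorizes every trait on its analysis scale.  Glucose is set missing for
    non-fasting samples before transformation.
    """
    out = table.copy()
    glucose = pd.to_numeric(out["glucose"], errors="coerce")
    out["glucose"] = glucose.where(out["fasting"].astype(bool))
    out["ln_crp"] = _safe_log(out["crp"], "CRP")
    out["ln_hdl"] = _safe_log(out["hdl"], "HDL-C")
    out["ln_tg"] = _safe_log(out["tg"], "TG")
    out["ln_glucose"] = _safe_log(out["glucose"], "glucose")
    for info in TRAITS.values():
        out[info.column] = winsorize(out[info.column])
    return out


def code_modifier_dichotomies(table: pd.DataFrame) -> pd.DataFrame:
    """Derive the dichotomous effect modifiers from their 3-level parents.

    current_smoker: current vs not; ever_smoker: former or current vs never;
    heavy_drinker: heavy vs nondrinker/moderate; hs_or_more: high school
    degree or above vs less than high school.
    """
    out = table.copy()
    for col, levels in (
        ("smoking3", SMOKING3_LEVELS),
        ("drinker3", DRINKER3_LEVELS),
        ("education3", EDUCATION3_LEVELS),
    ):
        unknown = set(out[col].dropna().unique()) - set(levels)
        if unknown:
            raise ValueError(f"unknown {col} levels: {sorted(unknown)}")
    out["current_smoker"] = out["smoking3"] == "current"
    out["ever_smoker"] = out["smoking3"].isin(["former", "current"])
    out["heavy_drinker"] = out["drinker3"] == "heavy"
    out["hs_or_more"] = out["education3"].isin(["hs", "college"])
    return out


def build_analysis_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive the full analysis table from raw measurements.

    Expects (per sample): paired BP readings ``sbp1/dbp1``, ``sbp2/dbp2``
    (NaN allowed), ``weight_kg``/``height_m``, lipid panel ``tc``/``hdl``/
    ``tg``, ``crp``, ``glucose``, ``fasting``, ``drinks_per_week``, ``age``,
    ``sex``, ``race``, ``education3``, ``smoking3``, ``physically_active``,
    medication flags ``htn_med``/``lipid_med``/``diab_med`` and optionally
    ``sample_weight``.
    """
    out = raw.copy()
    bp = [
        process_blood_pressure([(r.sbp1, r.dbp1), (r.sbp2, r.dbp2)])
        for r in out[["sbp1", "dbp1", "sbp2", "dbp2"]].itertuples()
    ]
    out["sbp"] = [b[0] for b in bp]
    out["dbp"] = [b[1] for b in bp]
    out["bmi"] = [
        compute_bmi(w, h) if (w > 0 and h > 0) else float("nan")
        for w, h in zip(out["weight_kg"], out["height_m"])
    ]
    out["ldl"] = [
        friedewald_ldl(tc, hdl, tg)
        for tc, hdl, tg in zip(out["tc"], out["hdl"], out["tg"])
    ]
    out["drinks_per_day"] = out["drinks_per_week"] / 7.0
    out["drinker3"] = [
        classify_drinker(w, a, s)
        for w, a, s in zip(out["drinks_per_week"], out["age"], out["sex"])
    ]
    out = code_modifier_dichotomies(out)
    out = transform_and_winsorize_traits(out)
    return out
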