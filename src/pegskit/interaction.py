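"""PEGS × modifier interaction models with simple slopes and Johnson–Neyman.

Each moderation model adds an effect modifier and its product with the score
to the Model 2 covariates:

    trait ~ PEGS + modifier + PEGS×modifier + Model-2 covariates

Modifiers are centered age (continuous), sex (female vs male), a high-school
dichotomy of education, two smoking dichotomies (current, ever), heavy
drinking and physical activity.  A modifier that is itself a Model 2
covariate — or a dichotomization of one — enters the model exactly once (the
dichotomy replaces its 3-level parent).  P-values for the 7 interaction tests
per trait are Benjamini–Hochberg adjusted as one family.

The conditional (simple) slope of the score at modifier value x is
``b_PEGS + b_int·x`` with variance ``V11 + 2x·V13 + x²·V33`` from the
coefficient covariance.  The Johnson–Neyman region of significance solves
``(b_PEGS + b_int·x)² = t²_crit · (V11 + 2x·V13 + x²·V33)`` for x, a
quadratic with 0–2 real roots, and classifies the observed modifier range by
whether the conditional slope is significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import _complete_cases, attach_pegs, covariate_terms
from .phenotypes import TRAITS
from .scores import PEGSVector

logger = logging.getLogger(__name__)

#: the moderation family examined for every PEGS–trait pair
MODIFIERS = (
    "age_centered",
    "sex",
    "education2",
    "current_smoker",
    "ever_smoker",
    "heavy_drinker",
    "physically_active",
)


@dataclass
class InteractionFit:
    """One PEGS × modifier model: key coefficients, covariance block, fit."""

    trait: str
    modifier: str
    n: int
    beta_pegs: float      # PEGS slope at modifier reference/zero
    beta_mod: float       # modifier main effect
    beta_int: float       # change in PEGS slope per modifier unit
    cov: np.ndarray = field(repr=False)   # 3×3 for (pegs, mod, pegs:mod)
    p_pegs: float = float("nan")
    p_mod: float = float("nan")
    p_int: float = float("nan")
    df_resid: float = float("nan")
    modifier_center: float = 0.0   # offset subtracted from a continuous modifier
    q_int: float = float("nan")    # BH-FDR adjusted within the trait's family
    result: object = field(default=None, repr=False)
    data: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance block must be symmetric 3×3")


@dataclass
class JNRegion:
    """Johnson–Neyman region of significance for a continuous modifier."""

    trait: str
    modifier: str
    boundaries: list[float]          # real roots, original modifier scale
    significant_intervals: list[tuple[float, float]]   # within observed range
    observed_range: tuple[float, float]
    alpha: float = 0.05

    @property
    def significant_side(self) -> str:
        if not self.significant_intervals:
            return "nowhere in the observed range"
        lo, hi = self.observed_range
        parts = []
        for a, b in self.significant_intervals:
            if (a, b) == (lo, hi):
                return "the entire observed range"
            parts.append(f"[{a:.2f}, {b:.2f}]")
        return " and ".join(parts)


def _modifier_column(
    table: pd.DataFrame, modifier: str
) -> tuple[pd.Series, float]:
    """Numeric modifier column and its centering offset (0 for dichotomies)."""
    if modifier == "age_centered":
        return pd.to_numeric(table["age"], errors="coerce"), float("nan")
    if modifier == "sex":
        return (table["sex"] == "female").astype(float), 0.0  # reference: male
    if modifier == "education2":
        return table["hs_or_more"].astype(float), 0.0
    if modifier in ("current_smoker", "ever_smoker", "heavy_drinker",
                    "physically_active"):
        return table[modifier].astype(float), 0.0
    raise ValueError(f"unknown modifier {modifier!r}")


def _interaction_terms(trait_info, modifier: str) -> list[str]:
    """Model 2 covariates with the modifier entering exactly once.

    Dichotomous modifiers that re-code a 3-level Model 2 covariate replace
    that covariate; modifiers already in Model 2 (age, sex, physical
    activity) are dropped from the covariate list because they enter via the
    interaction main-effect term.
    """
    drop = {
        "age_centered": "age",
        "sex": "C(sex)",
        "education2": "C(education3)",
        "current_smoker": "C(smoking3)",
        "ever_smoker": "C(smoking3)",
        "heavy_drinker": "C(drinker3)",
        "physically_active": "physically_active",
    }[modifier]
    terms = covariate_terms(trait_info, "model2")
    return [t for t in terms if t != drop]


def fit_interaction(
    trait: str, modifier: str, pegs: PEGSVector, table: pd.DataFrame
) -> InteractionFit:
    """Fit the Model 2 moderation model for one trait and modifier.

    Age is centered at the analysis-sample mean; dichotomous modifiers are
    coded 0/1 with the reference at 0 (male for sex, the "no"/lower level
    otherwise).  The full coefficient covariance is retained for simple
    slopes and the Johnson–Neyman procedure.
    """
    if modifier not in MODIFIERS:
        raise ValueError(f"unknown modifier {modifier!r}; expected {MODIFIERS}")
    info = TRAITS[trait]
    df = attach_pegs(table, pegs)
    mod_col, center = _modifier_column(df, modifier)
    df = df.copy()
    df["mod"] = mod_col
    terms = _interaction_terms(info, modifier)
    df = _complete_cases(df, info.column, terms, extra=["mod"])
    if df["mod"].nunique() <= 1:
        raise ValueError(f"{trait}×{modifier}: modifier is constant in sample")
    if modifier == "age_centered":
        center = float(df["mod"].mean())
        df["mod"] = df["mod"] - center
    rhs = " + ".join(["pegs * mod"] + terms)
    fit = smf.ols(f"{info.column} ~ {rhs}", data=df).fit()
    names = ["pegs", "mod", "pegs:mod"]
    cov_full = pd.DataFrame(
        fit.cov_params(), index=fit.params.index, columns=fit.params.index
    )
    return InteractionFit(
        trait=trait,
        modifier=modifier,
        n=int(fit.nobs),
        beta_pegs=float(fit.params["pegs"]),
        beta_mod=float(fit.params["mod"]),
        beta_int=float(fit.params["pegs:mod"]),
        cov=cov_full.loc[names, names].to_numpy(),
        p_pegs=float(fit.pvalues["pegs"]),
        p_mod=float(fit.pvalues["mod"]),
        p_int=float(fit.pvalues["pegs:mod"]),
        df_resid=float(fit.df_resid),
        modifier_center=center,
        result=fit,
        data=df,
    )


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values for one family of tests."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def interaction_scan(
    trait: str,
    pegs: PEGSVector,
    table: pd.DataFrame,
    modifiers: Sequence[str] = MODIFIERS,
) -> list[InteractionFit]:
    """Fit every modifier for one trait and BH-adjust p_int as one family."""
    fits = [fit_interaction(trait, m, pegs, table) for m in modifiers]
    qvals = fdr_adjust([f.p_int for f in fits])
    for f, q in zip(fits, qvals):
        f.q_int = float(q)
    return fits


def interaction_table(fits: Sequence[InteractionFit]) -> pd.DataFrame:
    """Tidy moderation results (trait, modifier, betas, p-values, FDR-q)."""
    return pd.DataFrame(
        [
            {
                "trait": f.trait,
                "modifier": f.modifier,
                "n": f.n,
                "beta_pegs": f.beta_pegs,
                "p_pegs": f.p_pegs,
                "beta_mod": f.beta_mod,
                "p_mod": f.p_mod,
                "beta_int": f.beta_int,
                "p_int": f.p_int,
                "q_int": f.q_int,
            }
            for f in fits
        ]
    )


def simple_slope(
    fit: InteractionFit, level: float
) -> tuple[float, float, float]:
    """Conditional PEGS slope, SE and p-value at a modifier value.

    ``level`` is on the model's modifier scale (centered for age; pass
    ``age − fit.modifier_center`` to evaluate at a raw age).  Degrees of
    freedom are the residual df of the fitted model.
    """
    v11, v13, v33 = fit.cov[0, 0], fit.cov[0, 2], fit.cov[2, 2]
    slope = fit.beta_pegs + fit.beta_int * level
    var = v11 + 2.0 * level * v13 + level**2 * v33
    se = float(np.sqrt(var))
    t = slope / se
    p = float(2.0 * stats.t.sf(abs(t), fit.df_resid))
    return float(slope), se, p


def johnson_neyman(
    fit: InteractionFit,
    modifier_range: tuple[float, float],
    alpha: float = 0.05,
) -> JNRegion:
    """Region of the modifier where the conditional PEGS slope is significant.

    Solves the boundary quadratic analytically with the two-sided t critical
    value at ``alpha`` and the model's residual df, then classifies
    sub-intervals of the observed range.  ``modifier_range`` and the reported
    boundaries are on the original (uncentered) modifier scale.
    """
    lo, hi = modifier_range
    if lo > hi:
        raise ValueError("modifier_range must be (min, max)")
    center = fit.modifier_center if np.isfinite(fit.modifier_center) else 0.0
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, fit.df_resid)
    b1, b3 = fit.beta_pegs, fit.beta_int
    v11, v13, v33 = fit.cov[0, 0], fit.cov[0, 2], fit.cov[2, 2]
    a = b3**2 - tcrit**2 * v33
    b = 2.0 * (b1 * b3 - tcrit**2 * v13)
    c = b1**2 - tcrit**2 * v11

    roots: list[float] = []
    if a == 0.0 and b == 0.0:
        pass  # constant test statistic: sign of c decides everywhere
    elif a == 0.0:
        roots = [-c / b]
    else:
        disc = b**2 - 4.0 * a * c
        if disc > 0:
            sq = np.sqrt(disc)
            roots = sorted([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
        elif disc == 0:
            roots = [-b / (2 * a)]

    # classify sub-intervals of the observed (centered) range at midpoints
    lo_c, hi_c = lo - center, hi - center
    cuts = [lo_c] + [r for r in roots if lo_c < r < hi_c] + [hi_c]
    intervals: list[tuple[float, float]] = []
    for a_c, b_c in zip(cuts[:-1], cuts[1:]):
        _, _, p_mid = simple_slope(fit, (a_c + b_c) / 2.0)
        if p_mid < alpha:
            if intervals and intervals[-1][1] == a_c + center:
                intervals[-1] = (intervals[-1][0], b_c + center)
            else:
                intervals.append((a_c + center, b_c + center))
    return JNRegion(
        trait=fit.trait,
        modifier=fit.modifier,
        boundaries=sorted(r + center for r in roots),
        significant_intervals=intervals,
        observed_range=(lo, hi),
        alpha=alpha,
    )


def predicted_values(
    fit: InteractionFit,
    pegs_grid: Sequence[float],
    modifier_levels: Sequence[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Predicted trait values over a score grid at fixed modifier levels.

    Remaining covariates are fixed at their sample means (continuous) or
    reference level (categorical/boolean); the pointwise CI comes from the
    full coefficient covariance.  Levels are on the model's modifier scale.
    Returns a tidy frame (modifier_level, pegs, predicted, lower, upper).
    """
    df = fit.data
    base: dict = {}
    for col in df.columns:
        if col in (TRAITS[fit.trait].column, "pegs", "mod"):
            continue
        s = df[col]
        if s.dtype.kind in "fiu" and s.dtype.kind != "b":
            base[col] = float(s.mean())
        elif s.dtype.kind == "b":
            base[col] = False
        else:
            base[col] = sorted(s.dropna().unique())[0]  # reference level
    rows = []
    for level in modifier_levels:
        for g in pegs_grid:
            rows.append({**base, "pegs": float(g), "mod": float(level)})
    new = pd.DataFrame(rows)
    pred = fit.result.get_prediction(new).summary_frame(alpha=alpha)
    out = pd.DataFrame(
        {
            "modifier_level": new["mod"].to_numpy(),
            "pegs": new["pegs"].to_numpy(),
            "predicted": pred["mean"].to_numpy(),
            "lower": pred["mean_ci_lower"].to_numpy(),
            "upper": pred["mean_ci_upper"].to_numpy(),
        }
    )
    return out
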