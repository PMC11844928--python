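"""PEGS–trait association models.

Each trait is regressed on its standardized score plus covariates:

* Model 1: age, sex, race/ethnicity, educational attainment (3 levels), and
  relevant medication use (antihypertensives for SBP/DBP, lipid-lowering for
  HDL/LDL/TG, diabetes medication for fasting glucose; none for BMI and CRP);
* Model 2: Model 1 plus smoking status, alcohol-consumption status and
  physical activity.

LDL-C and TG models additionally adjust for fasting status.  The PEGS
coefficient is the change in the trait (on its analysis scale) per 1-SD
increase in the score; incremental R² is the gain in R² over the
covariate-only model on the identical complete-case sample.  Log-scale
coefficients are converted to raw units at the sample mean via
``mean × (exp(β) − 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .phenotypes import RACE_LEVELS, TRAITS, TraitInfo
from .scores import PEGSVector

logger = logging.getLogger(__name__)

COVARIATE_SETS = ("model1", "model2")


@dataclass
class ModelSpec:
    """Configuration of one association fit."""

    trait: str
    covariate_set: str = "model2"
    stratum: str | None = None          # race/ethnicity level, or None
    weights: str | np.ndarray | None = None   # column name or per-sample array

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(f"unknown covariate set {self.covariate_set!r}")


@dataclass
class AssociationResult:
    """PEGS term estimate with the supporting model fit."""

    trait: str
    covariate_set: str
    stratum: str | None
    n: int
    beta: float
    se: float
    p: float
    r2_full: float
    r2_reduced: float
    r2_incremental: float
    params: pd.Series = field(repr=False)
    cov: pd.DataFrame = field(repr=False)
    df_resid: float = field(repr=False, default=float("nan"))

    def summary_row(self) -> dict:
        return {
            "trait": self.trait,
            "model": self.covariate_set,
            "stratum": self.stratum or "all",
            "n": self.n,
            "beta": self.beta,
            "se": self.se,
            "r2_incremental": self.r2_incremental,
            "p": self.p,
        }


def covariate_terms(
    info: TraitInfo,
    covariate_set: str,
    include_race: bool = True,
) -> list[str]:
    """Covariate formula terms for a trait under Model 1 or Model 2."""
    terms = ["age", "C(sex)"]
    if include_race:
        terms.append("C(race)")
    terms.append("C(education3)")
    if info.medication:
        terms.append(info.medication)
    if covariate_set == "model2":
        terms += ["C(smoking3)", "C(drinker3)", "physically_active"]
    if info.fasting_adjust:
        terms.append("fasting")
    return terms


def _formula_columns(terms: Sequence[str]) -> list[str]:
    cols = []
    for t in terms:
        name = t[2:-1] if t.startswith("C(") and t.endswith(")") else t
        cols.append(name.split(",")[0].strip())
    return cols


def attach_pegs(table: pd.DataFrame, pegs: PEGSVector) -> pd.DataFrame:
    """Join the standardized score onto the sample table as column ``pegs``."""
    df = table.copy()
    df["pegs"] = pegs.as_series().reindex(df.index)
    return df


def _complete_cases(
    table: pd.DataFrame, ycol: str, terms: Sequence[str], extra: Sequence[str] = ()
) -> pd.DataFrame:
    cols = [ycol, "pegs"] + _formula_columns(terms) + list(extra)
    cols = list(dict.fromkeys(cols))
    return table[cols].dropna()


def fit_association(
    spec: ModelSpec,
    pegs: PEGSVector,
    table: pd.DataFrame,
    robust: bool = False,
) -> AssociationResult:
    """Fit trait ~ PEGS + covariates by OLS (or WLS when weights are given).

    Complete-case analysis; categorical covariates are reference-coded.  The
    reported incremental R² is R²(covariates + PEGS) − R²(covariates only) on
    the same complete-case sample.
    """
    info = TRAITS[spec.trait]
    df = attach_pegs(table, pegs)
    if spec.stratum is not None:
        if spec.stratum not in RACE_LEVELS:
            raise ValueError(f"unknown race/ethnicity stratum {spec.stratum!r}")
        df = df[df["race"] == spec.stratum]
    terms = covariate_terms(
        info, spec.covariate_set, include_race=spec.stratum is None
    )
    wcol: list[str] = []
    if isinstance(spec.weights, str):
        wcol = [spec.weights]
    elif spec.weights is not None:
        df = df.copy()
        df["_w"] = np.asarray(spec.weights, dtype=float)
        wcol = ["_w"]
    df = _complete_cases(df, info.column, terms, extra=wcol)
    if wcol:
        df = df[df[wcol[0]] > 0]
        if df.empty or (df[wcol[0]] <= 0).all():
            raise ValueError("no positive sample weights")
    n_design = 2 + len(terms)  # intercept + pegs + covariates (lower bound)
    if len(df) < n_design + 2:
        raise ValueError(
            f"{spec.trait}: only {len(df)} complete cases for >= {n_design} "
            "design columns"
        )
    if df["pegs"].nunique() <= 1:
        raise ValueError(f"{spec.trait}: PEGS is constant in the analysis sample")

    rhs_full = " + ".join(["pegs"] + terms)
    rhs_red = " + ".join(terms)
    kwargs = {"data": df}
    model_fn = smf.ols
    if wcol:
        model_fn = smf.wls
        kwargs["weights"] = df[wcol[0]]
    full_model = model_fn(f"{info.column} ~ {rhs_full}", **kwargs)
    if np.linalg.matrix_rank(full_model.exog) < full_model.exog.shape[1]:
        logger.warning(
            "%s: rank-deficient design; aliased columns handled by "
            "minimum-norm fit", spec.trait,
        )
    fit_kwargs = {"cov_type": "HC1"} if robust else {}
    full = full_model.fit(**fit_kwargs)
    reduced = model_fn(f"{info.column} ~ {rhs_red}", **kwargs).fit()
    r2_full, r2_red = float(full.rsquared), float(reduced.rsquared)
    return AssociationResult(
        trait=spec.trait,
        covariate_set=spec.covariate_set,
        stratum=spec.stratum,
        n=len(df),
        beta=float(full.params["pegs"]),
        se=float(full.bse["pegs"]),
        p=float(full.pvalues["pegs"]),
        r2_full=r2_full,
        r2_reduced=r2_red,
        r2_incremental=r2_full - r2_red,
        params=full.params,
        cov=pd.DataFrame(
            full.cov_params(), index=full.params.index, columns=full.params.index
        ),
        df_resid=float(full.df_resid),
    )


def incremental_r2(
    spec: ModelSpec, pegs: PEGSVector, table: pd.DataFrame
) -> float:
    """Variance in the trait attributable to the PEGS beyond the covariates."""
    return fit_association(spec, pegs, table).r2_incremental


def back_transform_effect(beta_ln: float, sample_mean: float) -> float:
    """Raw-scale change per 1-SD PEGS for a sample-mean individual.

    For a trait modeled as ln(Y), a coefficient ``beta_ln`` multiplies Y by
    ``exp(beta_ln)``; at the sample mean the absolute change is
    ``sample_mean × (exp(beta_ln) − 1)``.
    """
    return sample_mean * (np.exp(beta_ln) - 1.0)


def stratified_associations(
    spec: ModelSpec,
    pegs: PEGSVector,
    table: pd.DataFrame,
    strata: Sequence[str] = RACE_LEVELS,
    min_n: int = 30,
) -> list[AssociationResult]:
    """Refit the association within each race/ethnicity stratum.

    Race/ethnicity is dropped from the covariates within strata.  Strata with
    too few complete cases are skipped with a warning.
    """
    results = []
    for level in strata:
        sub = ModelSpec(
            trait=spec.trait,
            covariate_set=spec.covariate_set,
            stratum=level,
            weights=spec.weights,
        )
        try:
            if (table["race"] == level).sum() < min_n:
                raise ValueError(f"stratum {level} below minimum size {min_n}")
            results.append(fit_association(sub, pegs, table))
        except ValueError as exc:
            logger.warning("stratified_associations: skipping %s (%s)", level, exc)
    return results


def weighted_association(
    spec: ModelSpec, pegs: PEGSVector, table: pd.DataFrame
) -> AssociationResult:
    """Sample-weighted fit: WLS point estimates with sandwich (HC1) SEs.

    Approximates a design-based analysis with weights only; zero-weight
    samples are excluded.
    """
    if spec.weights is None:
        raise ValueError("weighted_association requires spec.weights")
    return fit_association(spec, pegs, table, robust=True)


def correlation_matrices(
    table: pd.DataFrame, pegs_set: Mapping[str, PEGSVector]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrices among traits and among PEGS.

    Pairwise-complete observations; pairs with fewer than 3 complete cases
    are left missing.
    """
    trait_cols = {k: TRAITS[k].column for k in pegs_set if k in TRAITS}
    trait_df = table[[c for c in trait_cols.values()]]
    pegs_df = pd.DataFrame(
        {k: v.as_series().reindex(table.index) for k, v in pegs_set.items()}
    )
    return (
        trait_df.corr(method="pearson", min_periods=3),
        pegs_df.corr(method="pearson", min_periods=3),
    )


def association_table(
    results: Sequence[AssociationResult],
) -> pd.DataFrame:
    """Tidy results table (trait, model, stratum, n, beta, SE, R², P)."""
    return pd.DataFrame([r.summary_row() for r in results])
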