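"""Methylation matrix preparation: mean imputation and batch/cell residualization.

The scoring step consumes a post-QC beta matrix (samples × CpGs, values in
[0,1]).  Before scoring, each CpG is (1) mean-imputed and (2) pre-adjusted for
technical batch factors (plate, plate row, plate column) and estimated white
blood cell proportions (NK, B, CD4, CD8, MO from reference-based
deconvolution), since both are well-known confounders of blood methylation.
Adjustment replaces each CpG's values with OLS residuals plus the CpG's grand
mean, keeping adjusted values on an interpretable beta-value-like scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELL_TYPES = ("NK", "B", "CD4", "CD8", "MO")
BATCH_FACTORS = ("plate", "plate_row", "plate_column")


@dataclass
class MethylationMatrix:
    """Samples × CpGs beta values with batch and cell-composition metadata.

    ``values`` is a DataFrame indexed by sample id with CpG ids as columns;
    missing values are NaN.  ``batch`` holds the three categorical batch
    factors and ``cell_props`` the five estimated cell proportions, both
    indexed identically to ``values``.
    """

    values: pd.DataFrame
    batch: pd.DataFrame
    cell_props: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        for df, what, cols in (
            (self.batch, "batch", BATCH_FACTORS),
            (self.cell_props, "cell_props", CELL_TYPES),
        ):
            missing_cols = [c for c in cols if c not in df.columns]
            if missing_cols:
                raise ValueError(f"{what} lacks columns {missing_cols}")
            if not df.index.equals(self.values.index):
                raise ValueError(f"{what} index does not match sample ids")
        cp = self.cell_props[list(CELL_TYPES)].to_numpy(dtype=float)
        if np.isnan(cp).any() or cp.min() < 0 or cp.max() > 1:
            raise ValueError("cell proportions must be present and in [0, 1]")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def cpg_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class AdjustedMatrix:
    """Residualized methylation values, same shape as the imputed source.

    Values are unbounded reals (residual + per-CpG grand mean).
    ``adjustment_meta`` records the design columns used and any aliased
    columns dropped by the fit.  Batch and cell metadata are carried along so
    the adjustment can be re-applied (a no-op) or inspected.
    """

    values: pd.DataFrame
    batch: pd.DataFrame = None
    cell_props: pd.DataFrame = None
    adjustment_meta: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def cpg_ids(self) -> list:
        return list(self.values.columns)


def read_methylation(
    matrix_path,
    metadata_path,
    orientation: str = "samples_by_cpgs",
    sep: str = "\t",
    na_values: str | list[str] | None = None,
) -> MethylationMatrix:
    """Load a beta matrix and its sample metadata from delimited files.

    ``orientation`` declares the matrix layout (``samples_by_cpgs`` or
    ``cpgs_by_samples``; the latter is transposed on load).  The metadata
    table must be keyed by sample id and contain the three batch factors and
    the five cell-proportion columns.
    """
    if orientation not in ("samples_by_cpgs", "cpgs_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    values = pd.read_csv(matrix_path, sep=sep, index_col=0, na_values=na_values)
    if orientation == "cpgs_by_samples":
        values = values.T
    meta = pd.read_csv(metadata_path, sep=sep, index_col=0)
    meta = meta.loc[values.index]
    return MethylationMatrix(
        values=values.astype(float),
        batch=meta[list(BATCH_FACTORS)],
        cell_props=meta[list(CELL_TYPES)].astype(float),
    )


def impute_missing(m: MethylationMatrix) -> MethylationMatrix:
    """Replace each missing beta value with its CpG's mean over observed samples.

    A CpG with no observed values has no defined mean and raises, naming the
    probe.  Imputation preserves each CpG's mean exactly.
    """
    vals = m.values
    all_missing = vals.columns[vals.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"CpGs with all values missing cannot be imputed: {list(all_missing)}"
        )
    n_missing = int(vals.isna().to_numpy().sum())
    if n_missing == 0:
        return m
    filled = vals.fillna(vals.mean(axis=0))
    logger.info("impute_missing: filled %d missing cells", n_missing)
    return MethylationMatrix(values=filled, batch=m.batch, cell_props=m.cell_props)


def _design_matrix(
    m: "MethylationMatrix | AdjustedMatrix",
) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded batch indicators + cell proportions."""
    parts = [pd.Series(1.0, index=m.values.index, name="intercept")]
    for fac in BATCH_FACTORS:
        dummies = pd.get_dummies(
            m.batch[fac].astype("category"), prefix=fac, drop_first=True, dtype=float
        )
        parts.append(dummies)
    parts.append(m.cell_props[list(CELL_TYPES)].astype(float))
    X = pd.concat(parts, axis=1)
    return X.to_numpy(dtype=float), list(X.columns)


def residualize_cpgs(m: "MethylationMatrix | AdjustedMatrix") -> AdjustedMatrix:
    """Adjust every CpG for batch factors and cell proportions by OLS.

    Each CpG's values are regressed on plate, plate-row and plate-column
    indicators plus the five cell proportions; the adjusted value is the OLS
    residual plus the CpG's grand mean.  Residuals are orthogonal to every
    design column, so the operation is idempotent.  Requires an imputed matrix
    (no missing cells).

    Rank-deficient designs (aliased batch levels, compositional collinearity
    among cell proportions) are handled by a minimum-norm least-squares fit,
    which is equivalent to dropping aliased columns; a warning is logged.
    """
    if m.values.isna().to_numpy().any():
        raise ValueError("matrix has missing values; run impute_missing first")
    X, colnames = _design_matrix(m)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if n <= rank:
        raise ValueError(
            f"cannot residualize: {n} samples for a rank-{rank} design"
        )
    if rank < p:
        logger.warning(
            "residualize_cpgs: design rank %d < %d columns; aliased columns "
            "are effectively dropped",
            rank,
            p,
        )
    Y = m.values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    adjusted = resid + Y.mean(axis=0, keepdims=True)
    values = pd.DataFrame(adjusted, index=m.values.index, columns=m.values.columns)
    meta = {"design_columns": colnames, "design_rank": int(rank)}
    return AdjustedMatrix(
        values=values, batch=m.batch, cell_props=m.cell_props, adjustment_meta=meta
    )
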