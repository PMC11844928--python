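"""EWAS weight catalogs and the orientation transformation.

A poly-epigenetic score (PEGS) is a weighted sum of methylation beta values at
trait-associated CpGs, with per-CpG weights taken from an external
epigenome-wide association study (EWAS).  Source EWAS differ in orientation:
some regress the trait on methylation (``meth_independent``), others regress
methylation on the trait (``meth_dependent``).  For the latter, the reported
coefficient must be converted so that it represents the effect of methylation
on the trait before it can be used as a score weight:

    R² = Z² / (Z² + N − 1)
    β* = β · (1 − R²) / ((N − 1) · SE²)

where Z, β, SE and N are the reported association statistics of the source
EWAS.  β* recovers the slope of the reverse regression (trait on methylation)
up to a factor (N−2)/(N−1), which is negligible at EWAS sample sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ORIENTATIONS = ("meth_dependent", "meth_independent")

#: logical column -> default physical column name in a catalog file
DEFAULT_COLUMNS: dict[str, str] = {
    "cpg": "cpg",
    "beta": "beta",
    "se": "se",
    "z": "z",
    "n": "n",
    "orientation": "orientation",
    "significant": "significant",
}

REQUIRED_FIELDS = ("cpg", "beta", "se", "n")


class CatalogConfigError(ValueError):
    """Raised when a weight catalog or manifest is misconfigured."""


@dataclass(frozen=True)
class EWASWeightRecord:
    """One CpG's summary statistics from a source EWAS.

    Parameters
    ----------
    cpg_id : probe identifier (e.g. ``cg00000029``).
    beta : reported regression coefficient.  Trait units per beta-value when the
        EWAS modeled the trait as outcome, beta-value per trait unit otherwise.
    se : standard error of ``beta`` (must be positive).
    z : Z-score of the association; computed as ``beta/se`` when not reported.
    n : source EWAS sample size.
    orientation : ``"meth_dependent"`` if the EWAS modeled methylation as the
        dependent variable, ``"meth_independent"`` otherwise.
    bonferroni_significant : whether the EWAS reported the CpG as significant
        after Bonferroni correction.
    """

    cpg_id: str
    beta: float
    se: float
    n: int
    orientation: str
    z: float = None  # type: ignore[assignment]
    bonferroni_significant: bool = True

    def __post_init__(self) -> None:
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(f"{self.cpg_id}: se must be positive, got {self.se}")
        if self.n < 2:
            raise ValueError(f"{self.cpg_id}: n must be >= 2, got {self.n}")
        if self.orientation not in ORIENTATIONS:
            raise CatalogConfigError(
                f"{self.cpg_id}: unknown orientation {self.orientation!r}; "
                f"expected one of {ORIENTATIONS}"
            )
        if self.z is None:
            object.__setattr__(self, "z", self.beta / self.se)
        elif self.beta != 0 and self.z * self.beta < 0:
            raise ValueError(
                f"{self.cpg_id}: z ({self.z}) and beta ({self.beta}) disagree in sign"
            )


@dataclass(frozen=True)
class TransformedWeight:
    """Final external weight for one CpG, on the trait-per-beta-value scale."""

    cpg_id: str
    r2: float
    w: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 < 1.0):
            raise ValueError(f"{self.cpg_id}: r2 out of [0,1): {self.r2}")
        if not math.isfinite(self.w):
            raise ValueError(f"{self.cpg_id}: non-finite weight")


def compute_r2(z: float, n: int) -> float:
    """Coefficient of determination of a single-predictor association.

    ``r2 = z² / (z² + n − 1)``; strictly increasing in ``|z|`` and, for
    ``z != 0``, strictly decreasing in ``n``.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    z2 = float(z) * float(z)
    return z2 / (z2 + n - 1)


def transform_weight(rec: EWASWeightRecord) -> TransformedWeight:
    """Convert a methylation-as-outcome coefficient to a score weight.

    Applies ``β* = β (1 − R²) / ((N − 1) SE²)``, which recovers the slope of
    the reverse regression (trait on methylation).  Only valid for
    ``meth_dependent`` records.
    """
    if rec.orientation != "meth_dependent":
        raise ValueError(
            f"{rec.cpg_id}: transform_weight requires meth_dependent orientation"
        )
    r2 = compute_r2(rec.z, rec.n)
    w = rec.beta * (1.0 - r2) / ((rec.n - 1) * rec.se**2)
    return TransformedWeight(cpg_id=rec.cpg_id, r2=r2, w=w)


def finalize_weights(records: Sequence[EWASWeightRecord]) -> list[TransformedWeight]:
    """Produce the final per-CpG external weights for a selected catalog.

    ``meth_independent`` coefficients already measure trait change per unit
    methylation and pass through unchanged (R² is still computed and reported);
    ``meth_dependent`` coefficients are transformed.
    """
    if not records:
        raise ValueError("no records to finalize; did CpG selection leave any?")
    out: list[TransformedWeight] = []
    for rec in records:
        if rec.orientation == "meth_dependent":
            out.append(transform_weight(rec))
        else:
            out.append(
                TransformedWeight(
                    cpg_id=rec.cpg_id, r2=compute_r2(rec.z, rec.n), w=rec.beta
                )
            )
    return out


def select_cpgs(
    records: Sequence[EWASWeightRecord], available: Iterable[str]
) -> list[EWASWeightRecord]:
    """Keep CpGs that are Bonferroni-significant and measured on the array.

    Order is preserved; the number of dropped records is logged.  An empty
    result is an error because the score would be undefined.
    """
    avail = set(available)
    if not avail:
        raise ValueError("available CpG set is empty")
    kept = [
        r for r in records if r.bonferroni_significant and r.cpg_id in avail
    ]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("select_cpgs: dropped %d of %d records", dropped, len(records))
    if not kept:
        raise ValueError(
            "no CpGs survive selection (significant and present on array); "
            "score is undefined"
        )
    return kept


def read_weight_catalog(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str = "\t",
    default_orientation: str | None = None,
) -> list[EWASWeightRecord]:
    """Read a delimited EWAS weight catalog into records.

    Parameters
    ----------
    path : catalog file (TSV by default).
    columns : mapping from logical field names (``cpg``, ``beta``, ``se``,
        ``n``, ``z``, ``orientation``, ``significant``) to the file's column
        names.  Unmapped fields use the logical name itself.
    default_orientation : orientation applied when the file has no orientation
        column (catalogs from a single EWAS usually share one orientation).

    Rows whose numeric fields fail to parse are dropped with a warning naming
    the row indices.  Duplicate CpG ids are a hard error: weight provenance
    must be unambiguous.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"empty weight catalog: {path}")
    for field_name in REQUIRED_FIELDS:
        if colmap[field_name] not in df.columns:
            raise CatalogConfigError(
                f"catalog {path} lacks required column "
                f"{colmap[field_name]!r} (logical field {field_name!r})"
            )
    has_orient = colmap["orientation"] in df.columns
    if not has_orient and default_orientation is None:
        raise CatalogConfigError(
            f"catalog {path} has no orientation column and no default was given"
        )

    numeric = pd.DataFrame(index=df.index)
    for field_name in ("beta", "se", "n", "z"):
        col = colmap[field_name]
        if col in df.columns:
            numeric[field_name] = pd.to_numeric(df[col], errors="coerce")
    bad = numeric[["beta", "se", "n"]].isna().any(axis=1)
    if bad.any():
        idx = list(df.index[bad])
        logger.warning(
            "read_weight_catalog: rejected %d rows with unparseable numerics "
            "at indices %s",
            len(idx),
            idx,
        )
        df = df[~bad]
        numeric = numeric[~bad]
    if df.empty:
        raise ValueError(f"no parseable rows in weight catalog: {path}")

    cpg_col = df[colmap["cpg"]]
    dupes = cpg_col[cpg_col.duplicated()]
    if len(dupes):
        raise ValueError(f"duplicated cpg_id in catalog {path}: {sorted(set(dupes))}")

    records = []
    for i in df.index:
        orientation = (
            df.loc[i, colmap["orientation"]] if has_orient else default_orientation
        )
        sig = True
        if colmap["significant"] in df.columns:
            sig = str(df.loc[i, colmap["significant"]]).strip().lower() in (
                "1", "true", "t", "yes", "y",
            )
        z_val = numeric["z"][i] if "z" in numeric.columns else float("nan")
        records.append(
            EWASWeightRecord(
                cpg_id=str(cpg_col[i]),
                beta=float(numeric["beta"][i]),
                se=float(numeric["se"][i]),
                n=int(numeric["n"][i]),
                orientation=str(orientation),
                z=None if pd.isna(z_val) else float(z_val),
                bonferroni_significant=sig,
            )
        )
    return records


@dataclass
class ManifestEntry:
    """One trait's weight catalog: path, orientation, column mapping, units."""

    trait: str
    catalog: Path
    orientation: str | None = None
    columns: dict[str, str] = field(default_factory=dict)
    sep: str = "\t"
    units: str = ""


def read_manifest(path: str | Path) -> dict[str, ManifestEntry]:
    """Read a YAML manifest mapping trait name -> catalog configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise CatalogConfigError(f"manifest {path} must map trait -> config")
    entries = {}
    for trait, cfg in raw.items():
        if not isinstance(cfg, dict) or "catalog" not in cfg:
            raise CatalogConfigError(f"manifest entry {trait!r} lacks 'catalog'")
        orientation = cfg.get("orientation")
        if orientation is not None and orientation not in ORIENTATIONS:
            raise CatalogConfigError(
                f"manifest entry {trait!r}: unknown orientation {orientation!r}"
            )
        entries[trait] = ManifestEntry(
            trait=trait,
            catalog=path.parent / cfg["catalog"],
            orientation=orientation,
            columns=dict(cfg.get("columns", {})),
            sep=cfg.get("sep", "\t"),
            units=cfg.get("units", ""),
        )
    return entries


def load_trait_weights(
    entry: ManifestEntry, available: Iterable[str]
) -> list[TransformedWeight]:
    """Read, select and finalize one trait's weights from a manifest entry."""
    records = read_weight_catalog(
        entry.catalog,
        columns=entry.columns,
        sep=entry.sep,
        default_orientation=entry.orientation,
    )
    return finalize_weights(select_cpgs(records, available))
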