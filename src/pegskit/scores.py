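"""Poly-epigenetic score construction.

For trait ``t`` with selected CpGs ``k = 1..K`` and final external weights
``w_k``, the raw score of sample ``i`` is the weighted sum

    PEGS_i = Σ_k w_k · m_ik

over the adjusted methylation values ``m_ik``.  Raw scores are then
standardized over the full analysis sample and winsorized at ±5 SD
(standardize first, then clip, without re-standardizing — so the 5-SD fence
refers to the original distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import AdjustedMatrix
from .weights import TransformedWeight

logger = logging.getLogger(__name__)

WINSOR_SD = 5.0


@dataclass
class PEGSVector:
    """Per-sample score for one trait.

    ``raw`` is the weighted sum on trait-weight units; ``z`` (when present)
    is the standardized, winsorized score in SD units with ``|z| <= 5``.
    """

    trait: str
    sample_ids: list
    raw: np.ndarray
    n_cpgs_used: int
    z: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Score table: one row per sample (raw, z, n_cpgs_used)."""
        df = pd.DataFrame({"raw": self.raw}, index=pd.Index(self.sample_ids, name="sample_id"))
        if self.z is not None:
            df["z"] = self.z
        df["n_cpgs_used"] = self.n_cpgs_used
        return df

    def as_series(self) -> pd.Series:
        """Standardized score as a Series named ``pegs`` keyed by sample id."""
        if self.z is None:
            raise ValueError("score not yet standardized")
        return pd.Series(self.z, index=pd.Index(self.sample_ids, name="sample_id"), name="pegs")


def compute_pegs(
    adj: AdjustedMatrix, weights: Sequence[TransformedWeight], trait: str
) -> PEGSVector:
    """Raw weighted-sum score over exactly the given weight list."""
    if not weights:
        raise ValueError(f"{trait}: empty weight list")
    wanted = [w.cpg_id for w in weights]
    missing = [c for c in wanted if c not in adj.values.columns]
    if missing:
        raise ValueError(
            f"{trait}: weight CpGs absent from adjusted matrix: {missing}"
        )
    W = np.array([w.w for w in weights], dtype=float)
    M = adj.values[wanted].to_numpy(dtype=float)
    raw = M @ W
    return PEGSVector(
        trait=trait, sample_ids=adj.sample_ids, raw=raw, n_cpgs_used=len(weights)
    )


def standardize_winsorize(v: PEGSVector, limit: float = WINSOR_SD) -> PEGSVector:
    """Standardize the raw score and clip at ±``limit`` SD.

    z = (raw − mean)/SD over all samples (sample SD, ddof=1), then values with
    |z| > limit are set to ±limit.  No re-standardization after clipping.
    """
    raw = np.asarray(v.raw, dtype=float)
    if raw.size < 2:
        raise ValueError(f"{v.trait}: need >= 2 samples to standardize")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{v.trait}: raw score has zero variance")
    z = (raw - raw.mean()) / sd
    n_clipped = int((np.abs(z) > limit).sum())
    if n_clipped:
        logger.info(
            "standardize_winsorize[%s]: clipped %d samples at ±%g SD",
            v.trait, n_clipped, limit,
        )
    z = np.clip(z, -limit, limit)
    return PEGSVector(
        trait=v.trait,
        sample_ids=v.sample_ids,
        raw=v.raw,
        n_cpgs_used=v.n_cpgs_used,
        z=z,
    )
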