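"""End-to-end orchestration: weights → preprocessing → scores → analysis table."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .phenotypes import build_analysis_table
from .preprocess import AdjustedMatrix, MethylationMatrix, impute_missing, residualize_cpgs
from .scores import PEGSVector, compute_pegs, standardize_winsorize
from .simulate import SimulatedStudy
from .weights import EWASWeightRecord, finalize_weights, select_cpgs


@dataclass
class PipelineResult:
    """Analysis-ready products of one run."""

    adjusted: AdjustedMatrix
    pegs: dict[str, PEGSVector]
    table: pd.DataFrame          # analysis sample table

    def score_table(self) -> pd.DataFrame:
        frames = []
        for trait, v in self.pegs.items():
            df = v.to_frame()
            df.insert(0, "trait", trait)
            frames.append(df.reset_index())
        return pd.concat(frames, ignore_index=True)


def build_scores(
    matrix: MethylationMatrix,
    catalogs: Mapping[str, Sequence[EWASWeightRecord]],
) -> tuple[AdjustedMatrix, dict[str, PEGSVector]]:
    """Impute, residualize and score every trait's catalog."""
    adjusted = residualize_cpgs(impute_missing(matrix))
    available = set(adjusted.cpg_ids)
    pegs = {}
    for trait, records in catalogs.items():
        weights = finalize_weights(select_cpgs(list(records), available))
        pegs[trait] = standardize_winsorize(compute_pegs(adjusted, weights, trait))
    return adjusted, pegs


def run_pipeline(study: SimulatedStudy) -> PipelineResult:
    """Run the full pipeline on a simulated study."""
    adjusted, pegs = build_scores(study.methylation, study.catalogs)
    table = build_analysis_table(study.samples)
    return PipelineResult(adjusted=adjusted, pegs=pegs, table=table)
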