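import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pegskit as pk

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_study() -> pk.SimulatedStudy:
    """A small two-trait study shared by read-only tests."""
    cfg = pk.GeneratorConfig(
        seed=7, n_samples=800, n_cpgs_per_trait=10, traits=("bmi", "tg")
    )
    return pk.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_result(small_study) -> pk.PipelineResult:
    return pk.run_pipeline(small_study)


@pytest.fixture()
def tiny_matrix() -> pk.MethylationMatrix:
    """Four samples, three CpGs, two plates, one missing cell."""
    idx = pd.Index([f"s{i}" for i in range(4)], name="sample_id")
    values = pd.DataFrame(
        {
            "cg1": [0.2, np.nan, 0.4, 0.6],
            "cg2": [0.5, 0.5, 0.5, 0.5],
            "cg3": [0.1, 0.2, 0.3, 0.4],
        },
        index=idx,
    )
    batch = pd.DataFrame(
        {
            "plate": ["A", "A", "B", "B"],
            "plate_row": ["r1"] * 4,
            "plate_column": ["c1"] * 4,
        },
        index=idx,
    )
    cells = pd.DataFrame(
        {c: [0.1, 0.1, 0.1, 0.1] for c in ("NK", "B", "CD4", "CD8", "MO")},
        index=idx,
    )
    return pk.MethylationMatrix(values=values, batch=batch, cell_props=cells)
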