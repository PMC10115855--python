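import numpy as np
import pandas as pd
import pytest

from convsig import (
    DrugResponseTable,
    ExpressionMatrix,
    simulate_cellline_panel,
    simulate_clinical_cohort,
)
from convsig.simulate import SyntheticConfig


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Scaled-down study conditions used across unit tests."""
    return SyntheticConfig(n_lines=120, n_genes=400, n_program_genes=15, seed=1)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_cellline_panel(small_cfg)


@pytest.fixture(scope="session")
def small_clinical(small_cfg, small_panel):
    _, _, _, truth = small_panel
    return simulate_clinical_cohort(small_cfg, truth)


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """Deterministic 6-gene x 8-sample matrix."""
    rng = np.random.default_rng(11)
    frame = pd.DataFrame(
        rng.normal(7, 1, size=(6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(8)],
    )
    return ExpressionMatrix(frame)


@pytest.fixture
def toy_response() -> DrugResponseTable:
    vals = pd.Series(
        [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
        index=[f"s{i}" for i in range(10)],
    )
    return DrugResponseTable(vals)
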