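import numpy as np
import pandas as pd
import pytest

from m6ascore.dataio import ClinicalTable, ExpressionMatrix
from m6ascore.syndata import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-cohort, 300-gene synthetic dataset with clear cluster structure."""
    cfg = SimulationConfig(
        n_samples=60, n_cohorts=2, n_genes=300, n_deg=30,
        cluster_shift=2.0, batch_shift=1.0, hazard_ratio_true=2.0, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def toy_expression():
    """Deterministic 5-gene x 6-sample matrix (no batch structure)."""
    rng = np.random.default_rng(3)
    data = pd.DataFrame(
        rng.normal(8, 1, (5, 6)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(data)


def make_clinical(times, events, index=None, **extra):
    index = index if index is not None else [f"s{i}" for i in range(len(times))]
    return ClinicalTable(pd.DataFrame(
        {"os_time": times, "os_event": events, **extra}, index=index
    ))
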