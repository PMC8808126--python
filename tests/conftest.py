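import numpy as np
import pandas as pd
import pytest

from lnc_immunotype import (
    ExpressionMatrix,
    PipelineConfig,
    SimulationParams,
    generate_cohort,
    generate_worked_toy,
)


@pytest.fixture(scope="session")
def toy():
    """Hand-checkable micro-cohort (8 tumor / 4 normal, 6 lncRNAs, 30 mRNAs)."""
    return generate_worked_toy()


@pytest.fixture(scope="session")
def cohort():
    """One default-parameter synthetic cohort with planted ground truth."""
    return generate_cohort(SimulationParams(seed=1))


@pytest.fixture()
def config():
    return PipelineConfig(rng_seed=1)


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.uniform(0, 50, size=(5, 4)),
        index=[f"G{i}" for i in range(5)],
        columns=[f"S{i}" for i in range(4)],
    )
    return ExpressionMatrix(values)
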