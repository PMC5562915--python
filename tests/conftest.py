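import numpy as np
import pandas as pd
import pytest

from secpath.simulate import SimulationPlan, simulate, tiny_plan
from secpath.types import ExpressionMatrix


@pytest.fixture(scope="session")
def default_sim():
    """One default-plan simulation shared by read-only tests."""
    return simulate(SimulationPlan(seed=11))


@pytest.fixture(scope="session")
def tiny_sim():
    return simulate(tiny_plan(seed=7))


@pytest.fixture()
def toy_matrix():
    """3 genes x 4 tissues with simple hand-checkable values."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [2.0, 4.0, 6.0, 8.0],
         [5.0, 5.0, 5.0, 5.0]],
        index=["g1", "g2", "g3"],
        columns=["liver", "pancreas", "testis", "brain"],
    )
    return ExpressionMatrix("toy", df)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
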