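import numpy as np
import pandas as pd
import pytest

from cnascape.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared across read-only tests."""
    cfg = SimulationConfig(seed=42, n_samples=120, n_genes=400, n_chromosomes=4, n_segments=20)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def expr_3x2():
    return pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["G1", "G2", "G3"],
        columns=["S1", "S2"],
    )
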