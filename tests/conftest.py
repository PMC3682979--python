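import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from devotf import simulate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_pair():
    """Default two-species simulation (the bundled study conditions)."""
    return simulate.simulate_species_pair(simulate.SimConfig(), seed=0)


@pytest.fixture(scope="session")
def small_pair():
    """A fast, small simulated pair for I/O and CLI tests."""
    cfg = simulate.SimConfig(n_genes=120, n_orthologs=40)
    return simulate.simulate_species_pair(cfg, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_expression():
    """4 genes x 4 time points with known dynamic ranges."""
    from devotf.containers import ExpressionTimeCourse

    df = pd.DataFrame(
        {
            "t0": [5.0, 5.0, 0.0, 2.0],
            "t1": [5.3, 5.5, 0.0, 4.0],
            "t2": [5.9, 6.0, 0.1, 6.0],
            "t3": [5.1, 5.2, 0.0, 3.0],
        },
        index=["constantish", "range_one", "silent", "dynamic"],
    )
    return ExpressionTimeCourse("toy", df)
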