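import numpy as np
import pandas as pd
import pytest

from elevcomm.simulate import (
    SimConfig,
    generate_community,
    generate_design,
    generate_environment,
)


@pytest.fixture(scope="session")
def small_tables():
    """A reduced synthetic dataset shared across tests (20 species)."""
    cfg = SimConfig(seed=11, n_species=20)
    plots = generate_design(cfg)
    env = generate_environment(plots, cfg)
    counts = generate_community(plots, env, cfg)
    return plots, env, counts


@pytest.fixture()
def toy_counts():
    """Fixed 6-plot, 5-species count matrix used for frozen oracles."""
    data = [
        [5, 0, 3, 1, 0],
        [4, 1, 2, 0, 0],
        [0, 6, 1, 2, 1],
        [0, 5, 0, 3, 2],
        [1, 1, 4, 4, 0],
        [2, 0, 0, 5, 3],
    ]
    return pd.DataFrame(
        data,
        index=[f"p{i}" for i in range(6)],
        columns=[f"sp{j}" for j in range(5)],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
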