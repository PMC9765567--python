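import numpy as np
import pandas as pd
import pytest

from aleomics.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One default six-strain synthetic dataset shared across tests."""
    return generate_dataset(seed=3)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down simulation for fast per-test regeneration."""
    return SimulationConfig(n_genes=300, expression_noise_sd=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_expression():
    """3-gene x 4-sample log-TPM frame with two replicate pairs."""
    return pd.DataFrame(
        {
            "s1_r1": [1.0, 5.0, 3.0],
            "s1_r2": [1.1, 5.2, 2.9],
            "s2_r1": [2.0, 4.0, 6.0],
            "s2_r2": [2.1, 3.9, 6.2],
        },
        index=["gA", "gB", "gC"],
    )
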