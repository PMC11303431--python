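import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def tiny_expression():
    """4 samples x 3 features with simple, hand-checkable structure."""
    return pd.DataFrame(
        [[1.0, 2.0, 1.0],
         [2.0, 4.0, 1.5],
         [3.0, 6.0, 0.5],
         [4.0, 8.0, 2.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["gA", "gB", "gC"],
    )


@pytest.fixture
def small_cohort():
    """Seeded planted-module cohort small enough for per-test use."""
    from coexmod import generate_modular_expression

    return generate_modular_expression(
        n_samples=40, module_sizes=(50, 50), loading=0.8, noise_sd=0.6,
        n_noise_features=100, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
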