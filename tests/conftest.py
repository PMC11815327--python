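import numpy as np
import pandas as pd
import pytest

from comethnet.types import ModuleSpec, ResidualMatrix, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_residual_matrix(values: np.ndarray, prefix: str = "cg") -> ResidualMatrix:
    """Wrap a raw array as a ResidualMatrix with synthetic ids."""
    p, n = values.shape
    return ResidualMatrix(
        np.asarray(values, dtype=float),
        pd.Index([f"{prefix}{i:05d}" for i in range(p)]),
        pd.Index([f"S{j:04d}" for j in range(n)]),
    )


@pytest.fixture
def small_cohort():
    """A small planted cohort shared by several module-statistics tests."""
    from comethnet.preprocess import residualize
    from comethnet.simulate import simulate_cohort

    config = SimulationConfig(
        n_samples=80,
        n_cpgs=700,
        module_spec=[ModuleSpec(120, 0.7, 0.9), ModuleSpec(150, 0.7, 0.0)],
        seed=7,
    )
    beta, samples, truth = simulate_cohort(config)
    resid = residualize(beta, samples[["age", "sex", "braak", "prop_neuron", "plate"]])
    return resid, samples, truth
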