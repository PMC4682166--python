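import numpy as np
import pandas as pd
import pytest

from methmediate import MethylationMatrix, SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down cohort for fast unit tests."""
    return SimulationConfig(
        n_population=1_500,
        n_pairs=50,
        n_probes=40,
        n_responsive_probes=6,
        n_discriminating_probes=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from methmediate import simulate_population

    return simulate_population(small_config)


@pytest.fixture()
def toy_matrix() -> MethylationMatrix:
    """10 probes x 10 samples, fully observed, values strictly in (0,1)."""
    rng = np.random.default_rng(5)
    values = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(10, 10)),
        index=[f"cg{i:03d}" for i in range(10)],
        columns=[f"S{j}" for j in range(10)],
    )
    return MethylationMatrix(values)
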