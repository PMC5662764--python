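import numpy as np
import pytest

from sigres.synthetic_data import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale design: 2 lines x 6 drugs x 3 classes, one time point."""
    return SimulationConfig(
        n_genes=60,
        n_cell_lines=2,
        n_drugs=6,
        n_classes=3,
        J=3,
        N=6,
        time_points=(24.0,),
        effect_size=2.0,
        noise_sd=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_expression(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def unit_rows(rng: np.random.Generator, n: int, g: int) -> np.ndarray:
    """n random unit vectors in g dimensions."""
    x = rng.standard_normal((n, g))
    return x / np.linalg.norm(x, axis=1, keepdims=True)
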