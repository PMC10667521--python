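import numpy as np
import pytest

from condmix.config import SimulationConfig, Species


@pytest.fixture
def small_ternary_config():
    """A tiny three-species config for fast structural tests."""
    return SimulationConfig(
        lattice_size=14,
        species=[Species("whi3", 3, "whi3"),
                 Species("rna1", 4, "rna1"),
                 Species("rna2", 4, "rna2")],
        molecule_counts=[6, 4, 4],
        t_EQ=200, t_total=400, f_data=100, R_B=None,
        rng_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
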