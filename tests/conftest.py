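import numpy as np
import pytest

from slicephys.synthetic_data import SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """A fast cohort: 8 channels, 30 one-second traces, 20 kHz."""
    return SimConfig(
        n_animals_per_genotype=2,
        n_slices_per_animal=2,
        n_channels=8,
        n_traces=30,
        seed=123,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(987)
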