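import numpy as np
import pytest

from tremornet import BoldRun, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_run(rng):
    """A 5x5x5 grid, 60-volume run of band-unrestricted white noise."""
    data = rng.standard_normal((5, 5, 5, 60))
    return BoldRun(data=data, mask=np.ones((5, 5, 5), dtype=bool), tr=2.0)


@pytest.fixture
def tiny_config():
    """A fast-to-generate cohort: 4+4 subjects, 6x6x6 grid, 2 regions."""
    return SyntheticConfig(
        n_group_a=4,
        n_group_b=4,
        grid_shape=(6, 6, 6),
        n_volumes=120,
        n_regions=2,
        base_cov=np.array([[1.0, 0.4], [0.4, 1.0]]),
        effect_delta=np.array([[0.0, 0.2], [0.2, 0.0]]),
        seed=7,
    )
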