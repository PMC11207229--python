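import numpy as np
import pytest

from swsal.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_volumes():
    """A small fixed-seed phantom batch shared by read-only tests."""
    cfg = PhantomConfig(n_cases=3, slices_per_case=6, height=48, width=48, rng_seed=11)
    return generate_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
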