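import numpy as np
import pytest

from lungshrink.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def uniform_phantom():
    """64^3 pair with a spatially uniform 6% linear contraction (s = 0.94)."""
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        shrink_amplitude=0.06,
        basal_gradient=0.0,
        noise_sd=8.0,
        seed=1,
        scenario="deteriorate",
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def basal_phantom():
    """48^3 pair whose contraction strengthens toward the lung base."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 48),
        shrink_amplitude=0.08,
        basal_gradient=1.5,
        noise_sd=8.0,
        seed=3,
        scenario="deteriorate",
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def stable_phantom():
    spec = PhantomSpec(
        grid_shape=(48, 48, 48), noise_sd=8.0, seed=2, scenario="stable"
    )
    return spec, generate_phantom(spec)
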