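import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fpsense

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=20,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """The bench-protocol synthetic experiment (two sensors, three loads)."""
    return fpsense.simulate_experiment(fpsense.default_config(seed=1))


@pytest.fixture(scope="session")
def tracked_series(default_dataset):
    """Demodulated cavity-length series per channel for the default run."""
    return {
        ch: fpsense.track(frames) for ch, frames in default_dataset.frames.items()
    }


@pytest.fixture
def cavity_300():
    return fpsense.FPCavityParams(d_um=300.0)


@pytest.fixture
def spectrum_300(cavity_300):
    return fpsense.generate_spectrum(cavity_300)


def odd_order_resonances(d_um, n=1.0, wl_min=1510.0, wl_max=1590.0):
    """Independent oracle: wavelengths 4 n d / m for odd m inside the span."""
    d_nm = d_um * 1e3
    out = []
    m = 1
    while True:
        lam = 4.0 * n * d_nm / m
        if lam < wl_min:
            break
        if lam <= wl_max and m % 2 == 1:
            out.append(lam)
        m += 1
    return np.sort(np.array(out))
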