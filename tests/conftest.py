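"""Shared fixtures: a small-detector instrument for fast unit tests.

The small configuration keeps the full paraxial magnification chain
(f_tube/f_col = 16.67) but uses a 0.2 mm source on an 800 px detector, so a
frame is 25x cheaper to render than the full-size default geometry.
"""

import numpy as np
import pytest

from fieldfocus import OpticsConfig


def small_kwargs(**overrides):
    base = dict(
        source_width=0.2,
        detector_side=4.0,
        detector_pixels=800,
        beta=0.2,
        z_range=(-50.0, 50.0),
    )
    base.update(overrides)
    return base


@pytest.fixture(scope="session")
def small_config() -> OpticsConfig:
    return OpticsConfig(**small_kwargs())


@pytest.fixture(scope="session")
def quiet_small_config() -> OpticsConfig:
    return OpticsConfig(**small_kwargs(noise_sd=0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240510)
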