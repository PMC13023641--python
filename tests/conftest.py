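import math

import numpy as np
import pytest

from thermosar import CoilGeometry, DEFAULT_COIL, measured_series


@pytest.fixture(scope="session")
def coil() -> CoilGeometry:
    """Fixture coil geometry used across field tests."""
    return DEFAULT_COIL


@pytest.fixture(scope="session")
def implant_table():
    """Published 0.75 A implant-vs-nonimplant rise summary."""
    return measured_series("0.75A")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def single_loop():
    """Near-degenerate single-turn cone approximating a circular loop
    of radius 0.05 m (loop-width/radius = 1e-4)."""
    alpha = math.pi / 4
    radius = 0.05
    s_bar = radius / math.sin(alpha)
    width = s_bar * 1e-4
    geom = CoilGeometry(alpha, s_bar - width / 2, s_bar + width / 2,
                        n_turns=1, current=1.0)
    return geom, radius, s_bar * math.cos(alpha)
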