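import numpy as np
import pytest
from hypothesis import settings

import cardiolead as cl
from cardiolead.pipeline import ExperimentAssets

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny():
    return cl.make_fixture("tiny")


@pytest.fixture(scope="session")
def small():
    return cl.make_fixture("small")


@pytest.fixture(scope="session")
def cset():
    return cl.ConductivitySet()


@pytest.fixture(scope="session")
def small_assets():
    """Operators, electrodes, leads and lead fields on the small phantom."""
    return ExperimentAssets(cl.fixtures.SMALL_CONFIG, need_coarse=True)


@pytest.fixture(scope="session")
def tiny_assets():
    return ExperimentAssets(cl.fixtures.TINY_CONFIG, need_coarse=True)


@pytest.fixture(scope="session")
def small_wave(small_assets):
    """Planar-wave Vm movie on the small phantom (x-propagating)."""
    return cl.planar_wave_series(
        small_assets.mesh,
        small_assets.nodes,
        direction=(1.0, 0.0, 0.0),
        speed_mm_ms=1.0,
        front_width_mm=12.0,
        duration_ms=80.0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
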