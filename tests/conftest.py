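import numpy as np
import pytest

from phosim.geometry import DisplayModel
from phosim.patterns import TIERS, calibrate_profile, generate_pattern


@pytest.fixture(scope="session")
def display() -> DisplayModel:
    return DisplayModel()


@pytest.fixture(scope="session")
def small_display() -> DisplayModel:
    """Quarter-ish scale display with the same angular extent; keeps
    renderer tests cheap without changing the geometry semantics."""
    return DisplayModel(width_px=192, height_px=108)


@pytest.fixture(scope="session")
def profile_fit():
    return calibrate_profile()


@pytest.fixture(scope="session")
def profile(profile_fit):
    return profile_fit.profile


@pytest.fixture(scope="session")
def tier_patterns(profile):
    """Twenty patterns per tier over fixed seeds."""
    return {
        tier: [generate_pattern(tier, profile, seed=s) for s in range(20)]
        for tier in TIERS
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
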