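import numpy as np
import pytest

from eafit.fmap_core import (
    BUILTIN_PROFILES,
    DeviceProfile,
    load_profile,
    make_exploration_domain,
)


@pytest.fixture(params=BUILTIN_PROFILES)
def any_profile(request):
    """Each shipped device profile in turn."""
    return load_profile(request.param)


@pytest.fixture
def medel():
    return load_profile("medel12")


@pytest.fixture
def medel_domain(medel):
    return make_exploration_domain(medel)


@pytest.fixture
def toy_profile():
    """Small hand-checkable device: 3 electrodes, 1 Hz grid, 10 Hz min width."""
    return DeviceProfile(
        brand_label="toy",
        n_electrodes=3,
        default_bands=((100.0, 200.0), (200.0, 400.0), (400.0, 500.0)),
        freq_step_hz=1.0,
        min_band_width_hz=10.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
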