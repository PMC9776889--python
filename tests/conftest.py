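"""Shared fixtures: small phantoms reused across test modules.

The expensive full-scale phantoms used by the acceptance suite live in
``test_acceptance.py``; fixtures here are kept small (few cycles, 2 slices)
so the unit suite stays fast.
"""

import numpy as np
import pytest

from lvtrack import phantom


@pytest.fixture(scope="session")
def small_settings():
    return phantom.RenderSettings(noise_sd=0.0)


@pytest.fixture(scope="session")
def small_subject(small_settings):
    """Noiseless 2-slice, 2-cycle subject (one basal, one apical)."""
    params = [phantom.MotionParams(theta_amp=-0.15),
              phantom.MotionParams(theta_amp=+0.15)]
    return phantom.generate_subject(params, n_cycles=2, seed=3,
                                    settings=small_settings)


@pytest.fixture(scope="session")
def noisy_subject():
    """Default-noise 2-slice, 3-cycle subject."""
    params = [phantom.MotionParams(theta_amp=-0.15),
              phantom.MotionParams(theta_amp=+0.15)]
    return phantom.generate_subject(params, n_cycles=3, seed=7)


@pytest.fixture(scope="session")
def static_series(small_settings):
    """A static (non-contracting, non-rotating) slice: identical frames."""
    from lvtrack.imageio import ImageSeries

    p = phantom.MotionParams(r_ed=25.0, r_es=15.0, theta_amp=0.0)
    renderer = phantom._SliceRenderer(
        p, small_settings, phantom._texture_field(np.random.default_rng(2)))
    frame = renderer.render(22.0, 0.0, None)
    frames = np.repeat(frame[None], 90, axis=0)
    return ImageSeries(frames, np.arange(90) * 20.0,
                       small_settings.pixel_spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
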