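import numpy as np
import pytest

from gaitgaze.io import GazeRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(x, y, *, rate=120.0, pupil=None, valid=None, world="VR",
                   tracking_range=(100.0, 110.0), t=None):
    """Small helper to build a recording from plain gaze arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if t is None:
        t = np.arange(n) / rate
    if pupil is None:
        pupil = np.full(n, 3.0)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    return GazeRecording(
        participant_id="test", world=world, t=t, x=x, y=y,
        pupil=pupil, valid=valid, nominal_rate=rate,
        tracking_range=tracking_range,
    )


@pytest.fixture
def make_rec():
    return make_recording
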