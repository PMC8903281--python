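import numpy as np
import pytest

from batkit import make_beat_grid


@pytest.fixture
def grid_120bpm():
    """Isochronous 120 bpm grid (IBI 0.5 s), 21 beats starting at 0."""
    return make_beat_grid(120.0, 21, 0.0, excerpt_id="g120")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
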