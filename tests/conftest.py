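import numpy as np
import pytest
from hypothesis import settings

from wormscore import (SwimVideoTruth, generate_swim_video, make_profile,
                       simulate_panel)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

#: published score-table rows: variant -> (viability, swimming, migration, total);
#: None marks the migration assay not performed (printed N/A).
EXPECTED_TABLE1 = {
    "N53S": (2, 0, 1, 3),
    "Y59C": (1, 2, 1, 4),
    "R64P": (1, 2, 0, 3),
    "E358K": (1, 0, 0, 1),
    "L535P": (2, 2, 0, 4),
    "E96K": (0, 0, 0, 0),
    "E175K": (0, 0, 0, 0),
    "R204W": (0, 0, 1, 1),
    "K284Q": (0, 0, 0, 0),
    "K331Q": (0, 2, 0, 2),
    "G407D": (0, 0, 0, 0),
    "G528R": (0, 0, None, 0),
}


@pytest.fixture(scope="session")
def panel_datasets():
    """One simulated twelve-variant panel at the published sample sizes."""
    return simulate_panel(seed=1)


@pytest.fixture(scope="session")
def small_video():
    """A short two-worm swim video plus its ground truth (1.0 Hz, 10 s)."""
    truth = SwimVideoTruth(bend_freq_hz=1.0, fps=30, duration_s=10,
                           frame_shape=(256, 256), seed=3)
    frames, worms = generate_swim_video(truth, 2)
    return truth, frames, worms


@pytest.fixture
def wt_profile():
    return make_profile("wild_type")


@pytest.fixture
def severe_profile():
    return make_profile("severe")
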