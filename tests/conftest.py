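import math

import numpy as np
import pytest

from fishtrack import synthfish
from fishtrack.imaging import Frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_tail_truth():
    return synthfish.TailGroundTruth(
        angles=np.zeros(9), start_xy=(20.0, 60.0), segment_length=12.0
    )


def random_smooth_tail(rng, n_segments=9, max_step_deg=6.0, start=(20.0, 60.0),
                       segment_length=12.0, shape=(160, 200)):
    """Random smooth tail: per-segment bend steps bounded so the curve stays
    inside the frame and within the tracker's max-bend clamp."""
    steps = rng.uniform(-math.radians(max_step_deg), math.radians(max_step_deg),
                       n_segments)
    angles = np.cumsum(steps)
    angles -= angles[0]  # first segment along +x so the curve stays in frame
    return synthfish.TailGroundTruth(
        angles=angles, start_xy=start, segment_length=segment_length, shape=shape
    )


@pytest.fixture
def uniform_frame():
    def make(value, shape=(40, 50), t=0.0):
        return Frame(pixels=np.full(shape, float(value)), t=t)

    return make
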