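import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from arakin.event_detection import IntensityTrace


@pytest.fixture
def frame_times():
    return np.arange(121) * 60.0


def make_staircase(times, jump_frames, amplitude=100.0, noise_sd=0.0, rng=None):
    """Noisy monotone staircase trace with unit jumps at given frames."""
    y = np.zeros(times.size)
    for j in jump_frames:
        y[j:] += amplitude
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, times.size)
    return IntensityTrace(cell_id=0, times=times, intensities=y)
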