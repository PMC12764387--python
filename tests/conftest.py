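import numpy as np
import pytest

from stimwave.datatypes import Movie
from stimwave.synthetic import TransientKernel, generate_trace_set, generate_wave_movie

# canonical study conditions: GCaMP movies at 20 frames/s, 2 um pixels,
# 0.5 Hz spontaneous beating, rise 100 ms / tau 400 ms transients
FRAME_RATE = 20.0
PIXEL_SIZE = 2.0
PERIOD_MS = 2000.0


@pytest.fixture(scope="session")
def kernel() -> TransientKernel:
    return TransientKernel(rise_ms=100.0, tau_ms=400.0, amplitude=1.0)


@pytest.fixture(scope="session")
def clean_traces(kernel):
    """Noiseless, jitter-free 3-ROI beat train (all ROIs identical)."""
    traces, truth = generate_trace_set(
        n_rois=3, n_beats=4, period_ms=PERIOD_MS, kernel=kernel,
        jitter_sd_ms=0.0, noise_sd=0.0, frame_rate=FRAME_RATE, seed=11)
    return traces, truth


@pytest.fixture(scope="session")
def small_plane_wave(kernel):
    """64x64 plane wave along +x at 10 um/s, light noise."""
    return generate_wave_movie(
        h=64, w=64, pixel_size=PIXEL_SIZE, frame_rate=FRAME_RATE, n_frames=60,
        pattern="plane_wave", speed=10.0, direction=0.0, period_ms=PERIOD_MS,
        kernel=kernel, noise_sd=0.02, seed=3)


@pytest.fixture
def constant_movie() -> Movie:
    frames = np.full((20, 16, 16), 100.0)
    return Movie(frames=frames, frame_rate=FRAME_RATE, pixel_size=PIXEL_SIZE)
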