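import numpy as np
import pytest

from vsdpipe import synthgen as sg


@pytest.fixture(scope="session")
def small_map():
    """10 neurons per surface, deterministic."""
    return sg.generate_canonical_map(10, seed=1)


@pytest.fixture(scope="session")
def cell_stack(small_map):
    """Noiseless, motionless dual-view rendering of resting cells.

    Small frame so per-test image work stays fast.
    """
    v, _ = sg.simulate_voltages(
        small_map, sg.default_program(small_map, "swim", seed=2),
        "swim", None, duration_s=3.0, rate_Hz=50.0, seed=3)
    params = sg.ImagingParams(frame_shape=(64, 128), shot_noise_ppm=0.0,
                              bleach_amplitude=0.0, global_sd=0.0)
    rec = sg.render_recording(small_map, v * 0.0 - 50.0, params, seed=4)
    return rec


@pytest.fixture(scope="session")
def reference_frame(cell_stack):
    return cell_stack.stacks[0][0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
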