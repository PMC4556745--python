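import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

from fiberdiam import build_calibration_spec, render  # noqa: E402


@pytest.fixture(scope="session")
def ordered25_full():
    """Full-size ordered calibration image: 25 px lines, mixed angles."""
    spec = build_calibration_spec("Ordered-1D", seed=1, diameter=25)
    return render(spec) > 0


@pytest.fixture(scope="session")
def disordered9_small():
    """Small disordered phantom, 9 px lines, for segmentation tests."""
    spec = build_calibration_spec("Disordered-1D", seed=5, diameter=9, canvas=(320, 240))
    return render(spec) > 0


def horizontal_bar(width=25, shape=(60, 400)):
    m = np.zeros(shape, bool)
    y0 = shape[0] // 2 - width // 2
    m[y0 : y0 + width, :] = True
    return m
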