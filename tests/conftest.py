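import numpy as np
import pytest

from iristex.segmentation import Circle
from iristex.synthetic import EyeSpec, generate_cohort, generate_eye, toy_matrices


@pytest.fixture(scope="session")
def toys():
    return toy_matrices()


@pytest.fixture(scope="session")
def default_eye():
    """One clean synthetic eye with known geometry (pupil r=40 at (200, 220))."""
    spec = EyeSpec(
        image_height=440,
        image_width=420,
        pupil=Circle(200.0, 220.0, 40.0),
        iris=Circle(200.0, 220.0, 120.0),
        seed=11,
    )
    return generate_eye(spec)


@pytest.fixture(scope="session")
def recovery_batch():
    """40 randomized eyes (fixed seed) for localization-accuracy checks."""
    return generate_cohort(20, 70.0, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
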