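import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from facesym import FaceSpec, generate_face

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def symmetric_face():
    """A moderately resolved, exactly mirror-symmetric synthetic face."""
    return generate_face(FaceSpec(target_faces=8000))


@pytest.fixture
def axis_aligned_landmarks():
    """Landmarks of an ideally positioned head: FH horizontal, midline at x=0."""
    from facesym import LandmarkSet3D

    return LandmarkSet3D.from_mapping(
        {
            "tragion_r": (-60.0, 0.0, 0.0),
            "tragion_l": (60.0, 0.0, 0.0),
            "exocanthion_r": (-45.0, 70.0, 0.0),
            "exocanthion_l": (45.0, 70.0, 0.0),
            "sellion": (0.0, 80.0, 90.0),
            "subnasale": (0.0, 95.0, 40.0),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251)
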