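import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hepquant as hq

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """The embedded 33-lesion reference cohort."""
    return hq.reference_cohort()


@pytest.fixture(scope="session")
def rr_and_grades(cohort):
    rr = np.array([r.reduction_rate for r in cohort])
    grades = np.array([r.grade for r in cohort], dtype=object)
    return rr, grades


def circle(radius: float, center: float = 25.0, n: int = 72) -> np.ndarray:
    """Closed regular polygon approximating a circle (vertices in mm)."""
    th = np.linspace(0.0, 2.0 * np.pi, n + 1)[:-1]
    return np.column_stack([center + radius * np.cos(th), center + radius * np.sin(th)])


@pytest.fixture
def circle_contour():
    return circle
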