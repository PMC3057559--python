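import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sasangface as sf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def template():
    """The shipped canonical face template (mm units)."""
    return sf.template_landmarks()


@pytest.fixture(scope="session")
def make_landmarks(template):
    """Factory: template landmarks with selected points overridden."""

    def _make(overrides=None, subject_id="test"):
        pts = dict(template.points)
        pts.update(overrides or {})
        return sf.LandmarkSet(subject_id, pts, unit="mm")

    return _make


@pytest.fixture(scope="session")
def m20s_records():
    """One deterministic synthetic male-twenties cohort at printed group sizes."""
    return sf.generate_metric_level(sf.default_config(strata=["M20s"], seed=0))


@pytest.fixture(scope="session")
def m20s_specs():
    return sf.default_config(strata=["M20s"]).stratum_specs("M20s")


def random_simple_polygon(rng, n_min=3, n_max=12):
    """Star-shaped (hence simple) polygon around the origin.

    Angular gaps are kept strictly below a half-turn so the origin lies in
    the polygon's kernel, which guarantees simplicity for any radii.
    """
    n = int(rng.integers(n_min, n_max + 1))
    gaps = rng.uniform(0.6, 1.0, size=n)
    angles = 2 * np.pi * np.cumsum(gaps) / gaps.sum()
    radii = rng.uniform(0.5, 10.0, size=n)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
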