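import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def clean_phantom():
    """Noise-free default phantom with the (0, 0.2, 0.4, 0.6) fat gradient."""
    from dataclasses import replace

    from mfiquart.phantom import PhantomSpec, generate_phantom

    spec = replace(PhantomSpec(), noise_sd=0.0)
    return generate_phantom(spec, subject_id="P0001", level="L3", seed=0)


def random_star_polygon(rng, center, n_vertices, r_min, r_max):
    """Random star-shaped (hence simple) polygon around ``center`` (row, col)."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(r_min, r_max, n_vertices)
    rows = center[0] + radii * np.sin(angles)
    cols = center[1] + radii * np.cos(angles)
    return np.column_stack([rows, cols])
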