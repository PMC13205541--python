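import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fviq.synthetic import SyntheticPatientSpec, generate_patient

settings.register_profile(
    "fviq",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fviq")


@pytest.fixture(scope="session")
def small_patient():
    """One deterministic synthetic patient shared by read-only tests."""
    return generate_patient(
        SyntheticPatientSpec(seed=7, image_size=(128, 128))
    )


def pixel_in_polygon(px: float, py: float, vertices) -> bool:
    """Scalar even-odd ray-cast oracle, reimplemented independently of the
    vectorised rasteriser: casts a ray toward +x from (px, py)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if y1 == y2:
            continue
        if (y1 > py) != (y2 > py):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_at:
                inside = not inside
    return inside


def bruteforce_rasterize(vertices, width: int, height: int) -> np.ndarray:
    out = np.zeros((height, width), dtype=bool)
    for y in range(height):
        for x in range(width):
            out[y, x] = pixel_in_polygon(x + 0.5, y + 0.5, vertices)
    return out
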