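import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_eye():
    """A noise-free synthetic eye with its ground truth."""
    from irismoments.synthetic import EyeSpec, generate_eye_image

    spec = EyeSpec(
        center=(100.0, 100.0),
        pupil_radius=30.0,
        iris_radius=80.0,
        texture_class_id=0,
    )
    image, truth = generate_eye_image(spec)
    return image, truth


@pytest.fixture(scope="session")
def skewed_blob():
    """Band-limited, elongated, skewed test image for invariance checks.

    Generic anisotropy and skew keep all Hu invariants away from
    symmetric cancellation, so relative tolerances are meaningful.
    """
    return make_skewed_blob(n=256, seed=3)


def make_skewed_blob(n=256, seed=3, k=3.0, ncomp=5, elong=1.8, skew=0.8):
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:n, 0:n] / n - 0.5
    tex = np.zeros((n, n))
    for _ in range(ncomp):
        fx, fy = rng.uniform(-k, k, 2)
        ph = rng.uniform(0, 2 * np.pi)
        tex += rng.uniform(0.3, 1.0) * np.cos(2 * np.pi * (fx * x + fy * y) + ph)
    tex = tex - tex.min() + 0.5
    sx, sy = 0.16, 0.16 / elong
    w = np.exp(-0.5 * ((x / sx) ** 2 + (y / sy) ** 2))
    w = w * (1 + skew * np.clip(x / sx, -1.5, 1.5))
    return tex * w * 100.0
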