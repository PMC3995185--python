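"""Synthetic eye-image generator with known ground truth.

Real iris images come from a dedicated close-up acquisition device and a
large enrolled database; neither is assumed here.  Instead this module
renders the structure the recognition method relies on — a bright sclera,
a dark pupil disk and an annular iris carrying a person-specific texture —
with exact ground-truth geometry, so every downstream stage (segmentation,
unwrapping, moment features, matching) is testable end to end.

The iris texture is a band-limited sum of eight sinusoids in normalised
polar coordinates ``(r_norm, theta)``.  The sinusoid frequencies, phases
and amplitudes are a deterministic function of ``texture_class_id`` alone,
so in-plane rotation, scaling and translation of the eye act purely as
geometric transforms of one underlying texture function.  Radial
components (concentric "rings") carry most of the class identity; angular
components add azimuthal detail.  See docs/methods.md for the rationale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "EyeSpec",
    "GroundTruth",
    "EyeSample",
    "TransformRanges",
    "TextureBasis",
    "texture_basis",
    "iris_texture",
    "generate_eye_image",
    "generate_dataset",
    "save_dataset",
]

SCLERA_LEVEL = 230.0
PUPIL_LEVEL = 20.0
IRIS_BASE_LEVEL = 128.0

_N_RADIAL = 4
_N_ANGULAR = 4
_BASIS_SALT = 0xC1A55


@dataclass(frozen=True)
class EyeSpec:
    """Parameters of one rendered eye.

    ``center`` is ``(x, y)`` in pixels (x = column, y = row, origin at the
    top-left pixel); ``image_size`` is ``(height, width)``.  ``rotation``
    is the in-plane rotation of the iris texture in radians.
    ``texture_amplitude`` is a global gain on the texture sinusoids
    (0 renders a flat iris at the base level, useful for degenerate
    tests); 1 is the nominal contrast.
    """

    center: tuple[float, float]
    pupil_radius: float
    iris_radius: float
    texture_class_id: int
    rotation: float = 0.0
    luminosity: float = 1.0
    noise_sigma: float = 0.0
    image_size: tuple[int, int] = (200, 200)
    seed: int = 0
    texture_amplitude: float = 1.0

    def validate(self) -> None:
        h, w = self.image_size
        cx, cy = self.center
        if not 0 < self.pupil_radius < self.iris_radius:
            raise ValueError(
                f"need 0 < pupil_radius < iris_radius, got "
                f"{self.pupil_radius} and {self.iris_radius}"
            )
        if (
            cx - self.iris_radius < 0
            or cy - self.iris_radius < 0
            or cx + self.iris_radius > w - 1
            or cy + self.iris_radius > h - 1
        ):
            raise ValueError(
                f"iris disk (center {self.center}, radius {self.iris_radius}) "
                f"exceeds the {h}x{w} image bounds"
            )
        if not 0.5 <= self.luminosity <= 1.5:
            raise ValueError(f"luminosity must lie in [0.5, 1.5], got {self.luminosity}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Exact geometry of a rendered eye, recorded for evaluation."""

    center: tuple[float, float]
    pupil_radius: float
    iris_radius: float
    rotation: float
    texture_class_id: int


@dataclass(frozen=True)
class EyeSample:
    image: np.ndarray
    class_id: int
    truth: GroundTruth
    spec: EyeSpec


@dataclass(frozen=True)
class TextureBasis:
    """Band-limited texture of one class.

    value(r, th) = ramp·(r − 1/2) + Σ A·cos(2π·a·r + b·th + φ); the ramp
    models class-specific radial shading (e.g. limbal darkening), the
    sinusoids the ring/stripe pattern.
    """

    radial_freq: np.ndarray  # a, cycles across the annulus width
    angular_freq: np.ndarray  # b, integer cycles per revolution
    phase: np.ndarray
    amplitude: np.ndarray
    ramp: float


def texture_basis(texture_class_id: int) -> TextureBasis:
    """Deterministic sinusoid bank for a texture class.

    Depends only on ``texture_class_id`` — never on an image seed — so all
    images of one class share a single underlying texture function.
    """
    rng = np.random.default_rng(_BASIS_SALT + 1000003 * int(texture_class_id))
    # low-frequency, high-contrast radial "rings" carry the class identity
    # (their count varies per class); angular components add azimuthal
    # furrow detail at lower contrast and higher frequency
    n_active = int(rng.integers(2, _N_RADIAL + 1))
    a_rad = rng.uniform(0.2, 2.0, _N_RADIAL)
    phi_rad = rng.uniform(0.0, 2 * np.pi, _N_RADIAL)
    amp_rad = rng.uniform(6.0, 20.0, _N_RADIAL)
    amp_rad[n_active:] = 0.0
    a_ang = rng.uniform(0.0, 1.0, _N_ANGULAR)
    b_ang = rng.integers(8, 25, _N_ANGULAR).astype(float)
    phi_ang = rng.uniform(0.0, 2 * np.pi, _N_ANGULAR)
    amp_ang = rng.uniform(0.5, 1.5, _N_ANGULAR)
    ramp = float(rng.choice([-1.0, 1.0]) * rng.uniform(10.0, 50.0))
    return TextureBasis(
        radial_freq=np.concatenate([a_rad, a_ang]),
        angular_freq=np.concatenate([np.zeros(_N_RADIAL), b_ang]),
        phase=np.concatenate([phi_rad, phi_ang]),
        amplitude=np.concatenate([amp_rad, amp_ang]),
        ramp=ramp,
    )


def iris_texture(
    texture_class_id: int,
    r_norm: np.ndarray,
    theta: np.ndarray,
    amplitude_gain: float = 1.0,
) -> np.ndarray:
    """Evaluate the analytic class texture at normalised polar coordinates.

    ``r_norm`` is 0 at the pupil boundary and 1 at the outer iris boundary;
    ``theta`` in radians.  Returns intensities around ``IRIS_BASE_LEVEL``.
    """
    basis = texture_basis(texture_class_id)
    r = np.asarray(r_norm, dtype=float)[..., None]
    th = np.asarray(theta, dtype=float)[..., None]
    waves = basis.amplitude * np.cos(
        2 * np.pi * basis.radial_freq * r + basis.angular_freq * th + basis.phase
    )
    total = waves.sum(axis=-1) + basis.ramp * (r[..., 0] - 0.5)
    # keep the texture clear of the pupil/sclera levels so boundary edges
    # stay the strongest gradients in the frame
    total = np.clip(total, -55.0, 55.0)
    return IRIS_BASE_LEVEL + amplitude_gain * total


def generate_eye_image(spec: EyeSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render an 8-bit grayscale eye image from a spec.

    Sclera near-white, pupil near-black, iris annulus textured; the whole
    frame is multiplied by ``luminosity``, degraded by additive Gaussian
    noise of ``noise_sigma`` and clipped to [0, 255].  Bit-identical for
    identical specs.
    """
    spec.validate()
    h, w = spec.image_size
    cx, cy = spec.center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx = xx - cx
    dy = yy - cy
    dist = np.hypot(dx, dy)

    img = np.full((h, w), SCLERA_LEVEL)
    img[dist <= spec.pupil_radius] = PUPIL_LEVEL

    iris_mask = (dist > spec.pupil_radius) & (dist <= spec.iris_radius)
    r_norm = (dist[iris_mask] - spec.pupil_radius) / (
        spec.iris_radius - spec.pupil_radius
    )
    theta = np.arctan2(dy[iris_mask], dx[iris_mask]) - spec.rotation
    img[iris_mask] = iris_texture(
        spec.texture_class_id, r_norm, theta, spec.texture_amplitude
    )

    img *= spec.luminosity
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        center=spec.center,
        pupil_radius=spec.pupil_radius,
        iris_radius=spec.iris_radius,
        rotation=spec.rotation,
        texture_class_id=spec.texture_class_id,
    )
    return img, truth


@dataclass(frozen=True)
class TransformRanges:
    """Sampling ranges for the per-image transforms of a dataset.

    The base geometry (pupil/iris radii, image centre) is perturbed per
    image: the centre is translated by ``(dx, dy)`` drawn from
    ``translate``, both radii are multiplied by a factor from ``scale``,
    and rotation / luminosity / noise are drawn from their ranges.
    Zero-width ranges pin a parameter.  Luminosity defaults to exactly 1
    for every image: the method assumes a common acquisition illumination
    and its moment features are deliberately not gain-invariant.
    """

    base_pupil_radius: float = 24.0
    base_iris_radius: float = 64.0
    image_size: tuple[int, int] = (200, 200)
    translate: tuple[float, float] = (-10.0, 10.0)
    scale: tuple[float, float] = (0.8, 1.2)
    rotation: tuple[float, float] = (0.0, 2 * np.pi)
    luminosity: tuple[float, float] = (1.0, 1.0)
    noise_sigma: tuple[float, float] = (0.0, 4.0)

    def validate(self) -> None:
        for name in ("translate", "scale", "rotation", "luminosity", "noise_sigma"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name!r}: ({lo}, {hi})")
        if self.base_pupil_radius <= 0 or self.base_iris_radius <= self.base_pupil_radius:
            raise ValueError("need 0 < base_pupil_radius < base_iris_radius")


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    return float(lo) if hi == lo else float(rng.uniform(lo, hi))


def generate_dataset(
    n_classes: int,
    n_per_class: int,
    transform_ranges: TransformRanges | None = None,
    seed: int = 0,
) -> list[EyeSample]:
    """Generate ``n_classes * n_per_class`` labelled eye images.

    Within a class the texture is fixed while geometry, rotation, noise
    and luminosity vary per image.  One seed stream per dataset is split
    per image by ``(seed, class, index)`` counters, so the output is
    reproducible and independent of generation order.
    """
    if n_classes < 1 or n_per_class < 1:
        raise ValueError("n_classes and n_per_class must both be >= 1")
    ranges = transform_ranges if transform_ranges is not None else TransformRanges()
    ranges.validate()
    h, w = ranges.image_size
    samples: list[EyeSample] = []
    for c in range(n_classes):
        for j in range(n_per_class):
            ss = np.random.SeedSequence([int(seed), c, j])
            rng = np.random.default_rng(ss)
            s = _uniform(rng, ranges.scale)
            tx = _uniform(rng, ranges.translate)
            ty = _uniform(rng, ranges.translate)
            spec = EyeSpec(
                center=((w - 1) / 2 + tx, (h - 1) / 2 + ty),
                pupil_radius=ranges.base_pupil_radius * s,
                iris_radius=ranges.base_iris_radius * s,
                texture_class_id=c,
                rotation=_uniform(rng, ranges.rotation),
                luminosity=_uniform(rng, ranges.luminosity),
                noise_sigma=_uniform(rng, ranges.noise_sigma),
                image_size=ranges.image_size,
                seed=int(ss.generate_state(1)[0] % (2**31)),
            )
            image, truth = generate_eye_image(spec)
            samples.append(EyeSample(image=image, class_id=c, truth=truth, spec=spec))
    return samples


def save_dataset(samples: Sequence[EyeSample], out_dir: str | Path) -> Path:
    """Write samples as ``class_<id>/img_<j>.png`` plus a ground-truth CSV.

    Returns the path of the sidecar table (filename, class_id, cx, cy,
    r_pupil, r_iris, rotation).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = out / "ground_truth.csv"
    counters: dict[int, int] = {}
    with open(table, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["filename", "class_id", "cx", "cy", "r_pupil", "r_iris", "rotation"]
        )
        for s in samples:
            j = counters.get(s.class_id, 0)
            counters[s.class_id] = j + 1
            rel = Path(f"class_{s.class_id}") / f"img_{j}.png"
            (out / rel.parent).mkdir(exist_ok=True)
            iio.imwrite(out / rel, s.image)
            writer.writerow(
                [
                    str(rel),
                    s.class_id,
                    s.truth.center[0],
                    s.truth.center[1],
                    s.truth.pupil_radius,
                    s.truth.iris_radius,
                    s.truth.rotation,
                ]
            )
    return table
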