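"""Iris segmentation: locate the pupil and iris boundary circles.

The iris is modelled as an annulus between two (approximately concentric)
circles.  The pipeline is: iterated median denoising, edge detection
(Canny or Sobel), raster-scan collection of edge points into inner and
outer arrays by radial banding around a pupil hint, exact three-point
circle solving on many sampled triplets, and a trimmed average of the
resulting centres and radii.  A shared centre is enforced by pooling the
inner- and outer-circle centre estimates.

Coordinate convention (used package-wide): pixel centres at integer
coordinates, x = column, y = row, origin top-left, y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import permutations

import numpy as np
from scipy import ndimage
from skimage.feature import canny as _canny

__all__ = [
    "Circle",
    "IrisAnnulus",
    "CenterHint",
    "SegmentationConfig",
    "SegmentationError",
    "CollinearPointsError",
    "denoise_median",
    "detect_edges",
    "estimate_pupil_hint",
    "collect_circle_points",
    "fit_circle_three_points",
    "robust_circle_estimate",
    "segment_iris",
]


class SegmentationError(RuntimeError):
    """A segmentation stage failed; the message names the stage."""


class CollinearPointsError(SegmentationError):
    """Three-point circle fit received a degenerate (collinear) triplet."""


@dataclass(frozen=True)
class Circle:
    """A fitted circle with its x²+y²+2gx+2fy+c=0 coefficients.

    The centre is (−g, −f) and r² = g² + f² − c.
    """

    center: tuple[float, float]
    radius: float
    g: float
    f: float
    c: float


@dataclass(frozen=True)
class IrisAnnulus:
    """Shared centre with inner (pupil) radius r_m and outer radius R_m."""

    center: tuple[float, float]
    inner_radius: float
    outer_radius: float

    def validate(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError(
                f"need 0 < inner_radius < outer_radius, got "
                f"{self.inner_radius} and {self.outer_radius}"
            )


@dataclass(frozen=True)
class CenterHint:
    """Approximate pupil centre plus radial bands selecting the two edges."""

    center: tuple[float, float]
    inner_band: tuple[float, float]
    outer_band: tuple[float, float]


@dataclass(frozen=True)
class SegmentationConfig:
    median_iterations: int = 3
    median_window: int = 3
    edge_method: str = "canny"
    canny_sigma: float = 2.0
    # thresholds in raw-Sobel units of the luminosity-normalized image
    # (an ideal step of height h responds at about 8*h/(sigma*sqrt(2*pi)));
    # they sit between the weakest boundary step (>= ~50 intensity levels)
    # and the strongest band-limited iris texture gradients
    canny_low: float = 50.0
    canny_high: float = 80.0
    sobel_threshold: float = 150.0
    n_triplets: int = 50
    trim_fraction: float = 0.2
    seed: int = 0
    # pupil hint: dark threshold as a fraction of the estimated sclera level
    dark_fraction: float = 0.26
    inner_band_factors: tuple[float, float] = (0.5, 1.6)
    outer_band_halfwidth: float = 0.25


def _as_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    return arr


def denoise_median(image: np.ndarray, iterations: int = 3, window: int = 3) -> np.ndarray:
    """Apply a window×window median filter ``iterations`` times."""
    arr = _as_image(image)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    out = arr.copy()
    for _ in range(iterations):
        out = ndimage.median_filter(out, size=window)
    return out


def detect_edges(
    image: np.ndarray,
    method: str = "canny",
    *,
    sigma: float = 2.0,
    low_threshold: float = 50.0,
    high_threshold: float = 80.0,
    sobel_threshold: float = 150.0,
) -> np.ndarray:
    """Binary edge map by Canny or Sobel.

    Thresholds are in the intensity units of the input (0–255 for 8-bit
    images).  The Sobel path thresholds the gradient magnitude of the raw
    ±1/±2 kernels, whose response to an ideal 0→v step is 4v in the
    columns adjacent to the step.
    """
    arr = _as_image(image).astype(float)
    if method == "canny":
        return _canny(
            arr, sigma=sigma, low_threshold=low_threshold, high_threshold=high_threshold
        )
    if method == "sobel":
        gx = ndimage.sobel(arr, axis=1)
        gy = ndimage.sobel(arr, axis=0)
        return np.hypot(gx, gy) > sobel_threshold
    raise ValueError(f"unknown edge method {method!r}; expected 'canny' or 'sobel'")


def estimate_pupil_hint(
    image: np.ndarray,
    edges: np.ndarray,
    dark_fraction: float = 0.26,
    inner_band_factors: tuple[float, float] = (0.5, 1.6),
    outer_band_halfwidth: float = 0.25,
) -> CenterHint:
    """Pupil centre/radius hint from the darkest blob, bands from edge radii.

    The pupil is found as the largest connected component darker than
    ``dark_fraction`` of the estimated sclera level (the 99th-percentile
    intensity), which makes the threshold track global luminosity.  The
    outer band is centred on the median radius of edge pixels beyond the
    inner band.
    """
    arr = _as_image(image).astype(float)
    sclera = np.percentile(arr, 99)
    mask = arr < dark_fraction * sclera
    labels, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationError("pupil hint: no dark region found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    cy, cx = ndimage.center_of_mass(labels == best)
    r_hint = float(np.sqrt(sizes[best - 1] / np.pi))

    lo_f, hi_f = inner_band_factors
    inner_band = (lo_f * r_hint, hi_f * r_hint)
    ys, xs = np.nonzero(edges)
    if xs.size == 0:
        raise SegmentationError("pupil hint: empty edge map")
    d = np.hypot(xs - cx, ys - cy)
    outer_d = d[d > inner_band[1]]
    if outer_d.size == 0:
        raise SegmentationError("pupil hint: no edge pixels beyond the inner band")
    r_outer = float(np.median(outer_d))
    outer_band = (
        (1 - outer_band_halfwidth) * r_outer,
        (1 + outer_band_halfwidth) * r_outer,
    )
    return CenterHint(center=(float(cx), float(cy)), inner_band=inner_band, outer_band=outer_band)


def collect_circle_points(
    edges: np.ndarray, hint: CenterHint
) -> tuple[np.ndarray, np.ndarray]:
    """Split edge pixels into inner- and outer-circle point arrays.

    The map is raster-scanned top to bottom, left to right; each edge
    pixel is assigned by its distance from the hint centre to the inner
    or the outer radial band, and discarded if it falls in neither.
    Returns two ``(n, 2)`` arrays of ``(x, y)`` points.
    """
    arr = np.asarray(edges)
    if arr.size == 0:
        raise ValueError("empty edge map")
    ys, xs = np.nonzero(arr)  # row-major scan order: top-to-bottom, left-to-right
    cx, cy = hint.center
    d = np.hypot(xs - cx, ys - cy)
    in_inner = (d >= hint.inner_band[0]) & (d <= hint.inner_band[1])
    in_outer = (d >= hint.outer_band[0]) & (d <= hint.outer_band[1]) & ~in_inner
    inner = np.column_stack([xs[in_inner], ys[in_inner]]).astype(float)
    outer = np.column_stack([xs[in_outer], ys[in_outer]]).astype(float)
    if len(inner) < 3:
        raise SegmentationError(
            f"collect: only {len(inner)} edge points in the inner band"
        )
    if len(outer) < 3:
        raise SegmentationError(
            f"collect: only {len(outer)} edge points in the outer band"
        )
    return inner, outer


def fit_circle_three_points(p1, p2, p3) -> Circle:
    """Exact circle through three non-collinear points.

    Solves the simultaneous equations of x²+y²+2gx+2fy+c=0 at the three
    points in closed form; the centre is (−g, −f) and r = √(g²+f²−c).
    """
    pts = [tuple(map(float, p)) for p in (p1, p2, p3)]
    scale = max(1.0, max(abs(v) for p in pts for v in p))
    # closed form divides by (y2 - y1); permute so that pair differs in y
    for q1, q2, q3 in permutations(pts):
        (x1, y1), (x2, y2), (x3, y3) = q1, q2, q3
        denom = 2.0 * ((x3 - x1) * (y2 - y1) + (x1 - x2) * (y3 - y1))
        if abs(denom) <= 1e-12 * scale * scale:
            raise CollinearPointsError(f"degenerate triplet {pts}")
        if y2 != y1:
            g = (
                (x1 * x1 - x3 * x3 + y1 * y1 - y3 * y3) * (y2 - y1)
                - (x1 * x1 - x2 * x2 + y1 * y1 - y2 * y2) * (y3 - y1)
            ) / denom
            f = (x1 * x1 - x2 * x2 + y1 * y1 - y2 * y2 + 2 * g * (x1 - x2)) / (
                2.0 * (y2 - y1)
            )
            c = -x1 * x1 - y1 * y1 - 2 * g * x1 - 2 * f * y1
            r2 = g * g + f * f - c
            if r2 <= 0:
                raise CollinearPointsError(f"degenerate triplet {pts}")
            return Circle(center=(-g, -f), radius=float(np.sqrt(r2)), g=g, f=f, c=c)
    raise CollinearPointsError(f"degenerate triplet {pts}")


def robust_circle_estimate(
    points: np.ndarray,
    n_triplets: int = 50,
    trim_fraction: float = 0.2,
    seed: int = 0,
) -> Circle:
    """Trimmed-mean circle from many exact three-point solutions.

    Samples ``n_triplets`` seeded triplets (without replacement within a
    triplet), solves each exactly, discards degenerate solutions, drops
    the ``trim_fraction`` of centre estimates farthest from the
    coordinate-wise median centre, and averages the surviving centres and
    radii.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need an (n, 2) array with n >= 3")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(n_triplets):
        idx = rng.choice(len(pts), size=3, replace=False)
        try:
            circ = fit_circle_three_points(*pts[idx])
        except CollinearPointsError:
            continue
        centers.append(circ.center)
        radii.append(circ.radius)
    if not centers:
        raise SegmentationError("robust fit: all sampled triplets were degenerate")
    ctr = np.asarray(centers)
    rad = np.asarray(radii)
    med = np.median(ctr, axis=0)
    dist = np.hypot(ctr[:, 0] - med[0], ctr[:, 1] - med[1])
    n_keep = max(1, int(np.ceil((1.0 - trim_fraction) * len(ctr))))
    keep = np.argsort(dist, kind="stable")[:n_keep]
    cx, cy = ctr[keep].mean(axis=0)
    r = float(rad[keep].mean())
    g, f = -cx, -cy
    return Circle(
        center=(float(cx), float(cy)), radius=r, g=float(g), f=float(f),
        c=float(g * g + f * f - r * r),
    )


def segment_iris(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> IrisAnnulus:
    """Full segmentation: denoise → edges → collect → robust fit both circles.

    The two fitted centres are pooled into one shared centre (the mean of
    the inner- and outer-circle centre estimates); radii come from the
    trimmed averages of the three-point solutions.
    """
    cfg = config or SegmentationConfig()
    arr = _as_image(image).astype(float)
    if float(arr.max() - arr.min()) < 10.0:
        raise SegmentationError("segment: image has no usable contrast")
    smooth = denoise_median(arr, cfg.median_iterations, cfg.median_window)
    # normalize global luminosity so edge thresholds track the sclera level
    sclera = float(np.percentile(smooth, 99))
    if sclera <= 0:
        raise SegmentationError("segment: image is black")
    smooth = smooth * (230.0 / sclera)
    edges = detect_edges(
        smooth,
        method=cfg.edge_method,
        sigma=cfg.canny_sigma,
        low_threshold=cfg.canny_low,
        high_threshold=cfg.canny_high,
        sobel_threshold=cfg.sobel_threshold,
    )
    if not edges.any():
        raise SegmentationError("segment: edge detector found no edges")
    hint = estimate_pupil_hint(
        smooth,
        edges,
        dark_fraction=cfg.dark_fraction,
        inner_band_factors=cfg.inner_band_factors,
        outer_band_halfwidth=cfg.outer_band_halfwidth,
    )
    inner_pts, outer_pts = collect_circle_points(edges, hint)
    inner = robust_circle_estimate(
        inner_pts, cfg.n_triplets, cfg.trim_fraction, seed=cfg.seed
    )
    outer = robust_circle_estimate(
        outer_pts, cfg.n_triplets, cfg.trim_fraction, seed=cfg.seed + 1
    )
    center = (
        0.5 * (inner.center[0] + outer.center[0]),
        0.5 * (inner.center[1] + outer.center[1]),
    )
    annulus = IrisAnnulus(
        center=center, inner_radius=inner.radius, outer_radius=outer.radius
    )
    try:
        annulus.validate()
    except ValueError as exc:
        raise SegmentationError(f"segment: inconsistent radii ({exc})") from exc
    return annulus
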