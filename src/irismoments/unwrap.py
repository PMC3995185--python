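"""Radial-to-linear transformation of the iris annulus.

Each radial segment from the inner radius r_m to the outer radius R_m at
angle θ is rasterized with the integer midpoint line algorithm, resampled
to a fixed number of radial cells, and stored as one column of a
rectangular canvas; columns sweep θ from 0° towards 360°.  The midpoint
rasterizer and eight-way circle symmetry are the integer-arithmetic
optimizations of the transform.

Canvas layout: row 0 ↔ r_m, last row ↔ R_m; column j ↔ θ_j = j·2π/n_theta
with θ measured from the +x axis in the package's image coordinates
(x = column, y = row increasing downward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import IrisAnnulus

__all__ = [
    "UnwrappedIris",
    "polar_point",
    "midpoint_line_pixels",
    "eight_way_reflect",
    "unwrap_annulus",
]


@dataclass(frozen=True)
class UnwrappedIris:
    """Rectangular iris canvas: rows = radial steps, columns = angular steps."""

    canvas: np.ndarray
    annulus: IrisAnnulus

    @property
    def n_r(self) -> int:
        return self.canvas.shape[0]

    @property
    def n_theta(self) -> int:
        return self.canvas.shape[1]


def polar_point(
    r: float, theta: float, center: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float]:
    """Continuous Cartesian point at polar (r, θ) about ``center``."""
    if r < 0:
        raise ValueError("radius must be non-negative")
    return (center[0] + r * np.cos(theta), center[1] + r * np.sin(theta))


def midpoint_line_pixels(
    start: tuple[int, int], end: tuple[int, int]
) -> list[tuple[int, int]]:
    """Rasterize a line segment with the integer midpoint algorithm.

    Returns the pixels from ``start`` to ``end`` inclusive, one per step
    of the driving (longer) axis.  In the first octant the decision
    variable starts at d = 2·dy − dx and the North-East pixel is chosen
    when d > 0 (d is then updated by 2(dy − dx)), otherwise the East
    pixel (d updated by 2·dy); a tie d = 0 selects East.  Other octants
    are handled by axis swap and sign reflection.  The inner loop is
    integer-only.
    """
    x0, y0 = int(start[0]), int(start[1])
    x1, y1 = int(end[0]), int(end[1])
    if (x0, y0) == (x1, y1):
        return [(x0, y0)]

    dx = x1 - x0
    dy = y1 - y0
    swapped = abs(dy) > abs(dx)
    if swapped:
        x0, y0, x1, y1 = y0, x0, y1, x1
        dx, dy = dy, dx
    sx = 1 if dx > 0 else -1
    sy = 1 if dy >= 0 else -1
    adx = abs(dx)
    ady = abs(dy)

    pixels: list[tuple[int, int]] = []
    d = 2 * ady - adx
    y = 0
    for x in range(adx + 1):
        px = x0 + sx * x
        py = y0 + sy * y
        pixels.append((py, px) if swapped else (px, py))
        if d > 0:
            y += 1
            d += 2 * (ady - adx)
        else:
            d += 2 * ady
    return pixels


def eight_way_reflect(
    point: tuple[float, float], center: tuple[float, float] = (0.0, 0.0)
) -> list[tuple[float, float]]:
    """The seven dihedral partners of a point on a circle about ``center``.

    For centre-relative (a, b) these are (b, a), (−a, b), (−b, a),
    (a, −b), (b, −a), (−a, −b), (−b, −a), translated back by the centre.
    Duplicates (e.g. for a = b) are kept; callers may deduplicate.
    """
    a = point[0] - center[0]
    b = point[1] - center[1]
    rel = [(b, a), (-a, b), (-b, a), (a, -b), (b, -a), (-a, -b), (-b, -a)]
    return [(center[0] + u, center[1] + v) for u, v in rel]


def unwrap_annulus(
    image: np.ndarray,
    annulus: IrisAnnulus,
    n_theta: int = 96,
    n_r: int = 64,
) -> UnwrappedIris:
    """Unwrap the annulus of ``image`` onto an (n_r, n_theta) canvas.

    For each of ``n_theta`` equally spaced angles the radial segment
    (r_m, θ)→(R_m, θ) is rasterized with the midpoint algorithm and its
    pixel run is resampled to exactly ``n_r`` cells by nearest index;
    no sub-pixel interpolation is performed.

    The default canvas is deliberately near-square (96 angular × 64
    radial cells): the downstream third-order moments weight columns by
    up to (n_theta/2)³, so a canvas much wider than tall amplifies the
    ±half-pixel rasterization noise of the columns by (n_theta/n_r)³
    relative to the radial structure that carries the iris signature.
    """
    annulus.validate()
    if n_theta < 8 or n_r < 2:
        raise ValueError("need n_theta >= 8 and n_r >= 2")
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    h, w = arr.shape
    cx, cy = annulus.center
    R = annulus.outer_radius
    if cx - R < -0.5 or cy - R < -0.5 or cx + R > w - 0.5 or cy + R > h - 0.5:
        raise ValueError("annulus exceeds the image bounds")

    canvas = np.empty((n_r, n_theta), dtype=float)
    # nearest-index resampling positions, precomputed per run length
    sel_cache: dict[int, np.ndarray] = {}
    for j in range(n_theta):
        theta = 2.0 * np.pi * j / n_theta
        x0, y0 = polar_point(annulus.inner_radius, theta, annulus.center)
        x1, y1 = polar_point(R, theta, annulus.center)
        run = midpoint_line_pixels(
            (int(round(x0)), int(round(y0))), (int(round(x1)), int(round(y1)))
        )
        m = len(run)
        sel = sel_cache.get(m)
        if sel is None:
            sel = np.rint(np.linspace(0.0, m - 1, n_r)).astype(int)
            sel_cache[m] = sel
        for i, k in enumerate(sel):
            px, py = run[k]
            canvas[i, j] = arr[py, px]
    return UnwrappedIris(canvas=canvas, annulus=annulus)
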