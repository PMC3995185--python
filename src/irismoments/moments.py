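"""Image-moment feature stack: raw, central, normalized moments, orientation,
covariance eigenvalues, eccentricity and the eight Hu invariants.

Coordinates in the moment sums are 1-based: x runs over columns 1..K and
y over rows 1..L of a K-wide, L-tall image, so M_pq = Σ_x Σ_y x^p y^q I(x,y).
Central moments μ are translation invariant, the scale-normalized moments
η_pq = μ_pq / μ00^((p+q)/2 + 1) add spatial-scale invariance, and the Hu
combinations I1…I7 are additionally rotation invariant (I7 flips sign
under mirror reflection); I8 is an extra second/third-order combination.
None of these are invariant to a global intensity gain — the method
assumes a common acquisition luminosity.

The matching feature vector is [I1, I2, I3, I4, |I5|, I6, eccentricity],
each invariant passed through a signed log, s(v) = −sign(v)·log10(|v| + ε),
to tame the wildly different magnitudes before Euclidean-distance
matching.  Two deliberate omissions: the orientation angle Θ is
rotation-covariant and therefore reported as metadata only; and I7 and I8
are computed and reported but excluded from matching, because on a
canvas spanning a full angular revolution every term of I7 and I8
contains an x-odd third-order moment that vanishes by angular
periodicity — what remains of them is resampling noise of indeterminate
sign, which measurably corrupts Euclidean distances.  I5 shares the
sign instability (its leading stable term is a fourth power of the
radial-profile skewness) but its magnitude is informative, so it enters
the vector as a magnitude-only log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MomentVector",
    "IsotropicImageError",
    "raw_moments",
    "centroid",
    "central_moments",
    "normalized_moments",
    "orientation",
    "eigen_eccentricity",
    "hu_invariants",
    "signed_log",
    "feature_vector",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("I1", "I2", "I3", "I4", "I5_mag", "I6", "eccentricity")

SIGNED_LOG_EPS = 1e-30


class IsotropicImageError(ValueError):
    """Orientation is undefined: μ20′ = μ02′ and μ11′ = 0."""


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D intensity array")
    return arr


def raw_moments(image, max_order: int = 3) -> np.ndarray:
    """Raw moments M_pq = Σ_{x=1..K} Σ_{y=1..L} x^p y^q I(x, y).

    Returns an array ``M`` with ``M[p, q]`` filled for p + q <= max_order
    (NaN elsewhere).  x indexes columns, y indexes rows, both 1-based.
    """
    arr = _as_image(image)
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    L, K = arr.shape
    x = np.arange(1, K + 1, dtype=float)
    y = np.arange(1, L + 1, dtype=float)
    M = np.full((max_order + 1, max_order + 1), np.nan)
    xp = {p: x**p for p in range(max_order + 1)}
    yq = {q: y**q for q in range(max_order + 1)}
    for p in range(max_order + 1):
        for q in range(max_order + 1 - p):
            M[p, q] = yq[q] @ arr @ xp[p]
    return M


def centroid(M: np.ndarray) -> tuple[float, float]:
    """Intensity centroid (x̄, ȳ) = (M10/M00, M01/M00)."""
    if not M[0, 0] > 0:
        raise ValueError("blank image: M00 = 0 has no centroid")
    return float(M[1, 0] / M[0, 0]), float(M[0, 1] / M[0, 0])


def central_moments(image, max_order: int = 3) -> np.ndarray:
    """Central moments μ_pq = Σ Σ (x − x̄)^p (y − ȳ)^q I(x, y) by direct summation."""
    arr = _as_image(image)
    M = raw_moments(arr, max_order=max(1, max_order))
    xbar, ybar = centroid(M)
    L, K = arr.shape
    dx = np.arange(1, K + 1, dtype=float) - xbar
    dy = np.arange(1, L + 1, dtype=float) - ybar
    mu = np.full((max_order + 1, max_order + 1), np.nan)
    for p in range(max_order + 1):
        for q in range(max_order + 1 - p):
            mu[p, q] = (dy**q) @ arr @ (dx**p)
    if max_order >= 1:
        mu[1, 0] = 0.0  # exact identities; kill summation roundoff
        mu[0, 1] = 0.0
    return mu


def normalized_moments(mu: np.ndarray) -> np.ndarray:
    """Scale-normalized moments η_pq = μ_pq / μ00^γ, γ = (p+q)/2 + 1, p+q >= 2."""
    if not mu[0, 0] > 0:
        raise ValueError("μ00 = 0: normalized moments undefined")
    n = mu.shape[0]
    eta = np.full_like(mu, np.nan)
    for p in range(n):
        for q in range(n - p):
            if p + q >= 2:
                gamma = (p + q) / 2.0 + 1.0
                eta[p, q] = mu[p, q] / mu[0, 0] ** gamma
    return eta


def _second_order_primes(mu: np.ndarray) -> tuple[float, float, float]:
    mu00 = mu[0, 0]
    return mu[2, 0] / mu00, mu[0, 2] / mu00, mu[1, 1] / mu00


def orientation(mu: np.ndarray) -> float:
    """Orientation Θ of the principal intensity axis, Θ ∈ (−π/2, π/2].

    Θ = ½·arctan(2μ11′ / (μ20′ − μ02′)) with the quadrant disambiguated by
    the sign of (μ20′ − μ02′) (two-argument arctangent).  Isotropic images
    (μ20′ = μ02′ and μ11′ = 0) have no defined orientation.
    """
    if not mu[0, 0] > 0:
        raise ValueError("μ00 = 0: orientation undefined")
    m20, m02, m11 = _second_order_primes(mu)
    scale = m20 + m02
    if abs(m20 - m02) <= 1e-9 * scale and abs(m11) <= 1e-9 * scale:
        raise IsotropicImageError("isotropic image, orientation undefined")
    return 0.5 * float(np.arctan2(2.0 * m11, m20 - m02))


def eigen_eccentricity(mu: np.ndarray) -> tuple[float, float, float]:
    """Eigenvalues λ1 >= λ2 of the second-moment covariance and eccentricity.

    λ = (μ20′+μ02′)/2 ± √(4μ11′² + (μ20′−μ02′)²)/2;
    eccentricity = √(1 − λ2/λ1).
    """
    if not mu[0, 0] > 0:
        raise ValueError("μ00 = 0: covariance undefined")
    m20, m02, m11 = _second_order_primes(mu)
    mean = 0.5 * (m20 + m02)
    half = 0.5 * np.sqrt(4.0 * m11 * m11 + (m20 - m02) ** 2)
    lam1 = float(mean + half)
    lam2 = float(max(mean - half, 0.0))  # clip roundoff; true λ2 >= 0
    if lam1 <= 0:
        raise ValueError("λ1 = 0 (single-point image): eccentricity undefined")
    ecc = float(np.sqrt(max(0.0, 1.0 - lam2 / lam1)))
    return lam1, lam2, ecc


def hu_invariants(eta: np.ndarray) -> np.ndarray:
    """The eight Hu-style invariants I1…I8 from the η table (orders 2 and 3)."""
    n20, n02, n11 = eta[2, 0], eta[0, 2], eta[1, 1]
    n30, n03 = eta[3, 0], eta[0, 3]
    n21, n12 = eta[2, 1], eta[1, 2]
    if any(np.isnan(v) for v in (n20, n02, n11, n30, n03, n21, n12)):
        raise ValueError("η table incomplete for orders 2..3")
    s1 = n30 + n12
    s2 = n21 + n03
    d1 = n30 - 3 * n12
    d2 = 3 * n21 - n03
    I1 = n20 + n02
    I2 = (n20 - n02) ** 2 + (2 * n11) ** 2
    I3 = d1**2 + d2**2
    I4 = s1**2 + s2**2
    I5 = d1 * s1 * (s1**2 - 3 * s2**2) + d2 * s2 * (3 * s1**2 - s2**2)
    I6 = (n20 - n02) * (s1**2 - s2**2) + 4 * n11 * s1 * s2
    I7 = d2 * s1 * (s1**2 - 3 * s2**2) - d1 * s2 * (3 * s1**2 - s2**2)
    I8 = n11 * (s1**2 - s2**2) - (n20 - n02) * s1 * s2
    return np.array([I1, I2, I3, I4, I5, I6, I7, I8])


def signed_log(values, eps: float = SIGNED_LOG_EPS) -> np.ndarray:
    """Signed log transform s(v) = −sign(v)·log10(|v| + ε), elementwise."""
    v = np.asarray(values, dtype=float)
    return -np.sign(v) * np.log10(np.abs(v) + eps)


@dataclass(frozen=True)
class MomentVector:
    """Full moment stack of one canvas plus the matching feature vector.

    ``features`` follows ``FEATURE_NAMES``: signed-log of I1, I2, I3, I4
    and I6, the magnitude-only log of I5, and the eccentricity;
    per-component standardization happens at model training time with
    training-set statistics.  The full ``hu`` array (I1…I8) is always
    reported.  ``theta`` is ``None`` when the image is isotropic
    (orientation undefined).
    """

    raw: np.ndarray
    centroid: tuple[float, float]
    mu: np.ndarray
    eta: np.ndarray
    theta: float | None
    eigenvalues: tuple[float, float]
    eccentricity: float
    hu: np.ndarray
    features: np.ndarray


def feature_vector(canvas) -> MomentVector:
    """Run the full moment stack on a canvas (or any grayscale image).

    An undefined orientation (isotropic image) is recorded as missing
    metadata and never aborts feature extraction; a blank canvas is an
    error.
    """
    if hasattr(canvas, "canvas"):
        canvas = canvas.canvas
    arr = _as_image(canvas)
    M = raw_moments(arr, max_order=3)
    if not M[0, 0] > 0:
        raise ValueError("blank canvas: no features")
    cen = centroid(M)
    mu = central_moments(arr, max_order=3)
    eta = normalized_moments(mu)
    try:
        theta: float | None = orientation(mu)
    except IsotropicImageError:
        theta = None
    lam1, lam2, ecc = eigen_eccentricity(mu)
    hu = hu_invariants(eta)
    s = signed_log(hu)
    i5_mag = float(np.log10(np.abs(hu[4]) + SIGNED_LOG_EPS))
    feats = np.array([s[0], s[1], s[2], s[3], -i5_mag, s[5], ecc])
    return MomentVector(
        raw=M,
        centroid=cen,
        mu=mu,
        eta=eta,
        theta=theta,
        eigenvalues=(lam1, lam2),
        eccentricity=ecc,
        hu=hu,
        features=feats,
    )
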