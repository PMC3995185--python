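"""Segmentation: median denoising, edge maps, circle fitting, full recovery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from skimage.draw import circle_perimeter

from irismoments.segmentation import (
    CenterHint,
    CollinearPointsError,
    SegmentationConfig,
    SegmentationError,
    collect_circle_points,
    denoise_median,
    detect_edges,
    fit_circle_three_points,
    robust_circle_estimate,
    segment_iris,
)
from irismoments.synthetic import EyeSpec, generate_eye_image


def lstsq_circle(p1, p2, p3):
    """Independent algebraic oracle: solve the linear system of
    x^2+y^2+2gx+2fy+c=0 at the three points with numpy's solver."""
    pts = np.array([p1, p2, p3], dtype=float)
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(3)])
    b = -(pts[:, 0] ** 2 + pts[:, 1] ** 2)
    g, f, c = np.linalg.solve(A, b)
    return (-g, -f), np.sqrt(g * g + f * f - c)


class TestDenoiseMedian:
    def test_constant_image_unchanged(self):
        img = np.full((9, 9), 37.0)
        assert np.array_equal(denoise_median(img, 5, 3), img)

    def test_zero_iterations_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (8, 8)).astype(float)
        assert np.array_equal(denoise_median(img, 0, 3), img)

    def test_salt_pixel_removed(self):
        img = np.zeros((3, 3))
        img[1, 1] = 255.0
        out = denoise_median(img, 1, 3)
        assert out[1, 1] == 0.0  # median of the 9-neighbourhood

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            denoise_median(np.zeros((4, 4)), 1, 4)


class TestDetectEdges:
    def test_constant_image_no_edges(self):
        assert not detect_edges(np.full((32, 32), 99.0), "canny").any()
        assert not detect_edges(np.full((32, 32), 99.0), "sobel").any()

    def test_sobel_vertical_step_two_columns(self):
        # raw +-1/+-2 kernels respond with 4*255 = 1020 in the two columns
        # adjacent to a 0->255 step and 0 elsewhere
        img = np.zeros((10, 10))
        img[:, 5:] = 255.0
        edges = detect_edges(img, "sobel", sobel_threshold=500.0)
        cols = set(np.nonzero(edges[1:-1])[1])
        assert cols == {4, 5}

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown edge method"):
            detect_edges(np.zeros((4, 4)), "prewitt")

    def test_edges_localized_on_synthetic_eye(self, clean_eye):
        img, truth = clean_eye
        smooth = denoise_median(img.astype(float), 3, 3)
        edges = detect_edges(smooth, "canny")
        ys, xs = np.nonzero(edges)
        d = np.hypot(xs - truth.center[0], ys - truth.center[1])
        near = np.minimum(
            np.abs(d - truth.pupil_radius), np.abs(d - truth.iris_radius)
        )
        assert (near <= 1.5).mean() >= 0.90


class TestCollectCirclePoints:
    @staticmethod
    def two_circle_map():
        edges = np.zeros((200, 200), dtype=bool)
        for r in (30, 80):
            rr, cc = circle_perimeter(100, 100, r)
            edges[rr, cc] = True
        return edges

    def test_disjoint_bands_capture_everything(self):
        edges = self.two_circle_map()
        hint = CenterHint((100.0, 100.0), (20.0, 50.0), (60.0, 100.0))
        inner, outer = collect_circle_points(edges, hint)
        assert len(inner) + len(outer) == edges.sum()
        d_in = np.hypot(inner[:, 0] - 100, inner[:, 1] - 100)
        d_out = np.hypot(outer[:, 0] - 100, outer[:, 1] - 100)
        assert np.all(np.abs(d_in - 30) <= 1.0)
        assert np.all(np.abs(d_out - 80) <= 1.0)

    def test_band_missing_circle_is_failure(self):
        edges = self.two_circle_map()
        hint = CenterHint((100.0, 100.0), (20.0, 50.0), (55.0, 70.0))
        with pytest.raises(SegmentationError, match="outer band"):
            collect_circle_points(edges, hint)

    def test_synthetic_eye_points_near_truth(self, clean_eye):
        img, truth = clean_eye
        smooth = denoise_median(img.astype(float), 3, 3)
        edges = detect_edges(smooth, "canny")
        hint = CenterHint(truth.center, (15.0, 45.0), (60.0, 100.0))
        inner, outer = collect_circle_points(edges, hint)
        d_in = np.hypot(inner[:, 0] - truth.center[0], inner[:, 1] - truth.center[1])
        d_out = np.hypot(outer[:, 0] - truth.center[0], outer[:, 1] - truth.center[1])
        assert np.abs(d_in - truth.pupil_radius).max() <= 1.5
        assert np.abs(d_out - truth.iris_radius).max() <= 1.5


class TestFitCircleThreePoints:
    def test_symmetric_triplet(self):
        c = fit_circle_three_points((5, 0), (0, 5), (-5, 0))
        assert c.center == pytest.approx((0.0, 0.0), abs=1e-12)
        assert c.radius == pytest.approx(5.0, abs=1e-12)

    def test_worked_example(self):
        # each point satisfies (x-1)^2 + (y-2)^2 = 25
        c = fit_circle_three_points((1, 7), (6, 2), (1, -3))
        assert c.center == pytest.approx((1.0, 2.0), abs=1e-12)
        assert c.radius == pytest.approx(5.0, abs=1e-12)

    def test_collinear_rejected(self):
        with pytest.raises(CollinearPointsError):
            fit_circle_three_points((0, 0), (1, 1), (2, 2))

    def test_coefficient_identity_holds(self):
        c = fit_circle_three_points((3, 1), (7, 9), (-2, 4))
        assert c.radius**2 == pytest.approx(c.g**2 + c.f**2 - c.c, rel=1e-12)

    @given(st.integers(0, 9), st.integers(0, 9), st.integers(0, 9),
           st.integers(0, 9), st.integers(0, 9), st.integers(0, 9))
    def test_matches_algebraic_oracle(self, x1, y1, x2, y2, x3, y3):
        pts = [(x1, y1), (x2, y2), (x3, y3)]
        area2 = (x3 - x1) * (y2 - y1) + (x1 - x2) * (y3 - y1)
        if area2 == 0:
            with pytest.raises(CollinearPointsError):
                fit_circle_three_points(*pts)
            return
        c = fit_circle_three_points(*pts)
        (ox, oy), orad = lstsq_circle(*pts)
        scale = max(1.0, orad)
        assert abs(c.center[0] - ox) <= 1e-9 * scale
        assert abs(c.center[1] - oy) <= 1e-9 * scale
        assert abs(c.radius - orad) <= 1e-9 * scale


class TestRobustCircleEstimate:
    @staticmethod
    def lattice_circle(cx=50.0, cy=50.0, r=20.0):
        rr, cc = circle_perimeter(int(cy), int(cx), int(r))
        return np.column_stack([cc, rr]).astype(float)

    def test_recovers_lattice_circle(self):
        pts = self.lattice_circle()
        c = robust_circle_estimate(pts, n_triplets=50, trim_fraction=0.1, seed=1)
        assert np.hypot(c.center[0] - 50, c.center[1] - 50) <= 0.5
        assert abs(c.radius - 20) <= 0.5

    def test_single_triplet_reduces_to_exact_fit(self):
        pts = np.array([(5.0, 0.0), (0.0, 5.0), (-5.0, 0.0)])
        c = robust_circle_estimate(pts, n_triplets=1, trim_fraction=0.0, seed=0)
        exact = fit_circle_three_points(*pts)
        assert c.center == pytest.approx(exact.center, abs=1e-12)
        assert c.radius == pytest.approx(exact.radius, abs=1e-12)

    def test_outlier_resistance(self):
        rng = np.random.default_rng(4)
        pts = self.lattice_circle()
        outliers = rng.uniform(0, 100, size=(len(pts) // 10, 2))
        noisy = np.vstack([pts, outliers])
        c = robust_circle_estimate(noisy, n_triplets=200, trim_fraction=0.3, seed=2)
        assert np.hypot(c.center[0] - 50, c.center[1] - 50) <= 1.0

    def test_all_collinear_fails(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(SegmentationError, match="degenerate"):
            robust_circle_estimate(pts, n_triplets=5, seed=0)


class TestSegmentIris:
    def test_clean_eye_recovered(self, clean_eye):
        img, truth = clean_eye
        ann = segment_iris(img)
        assert np.hypot(ann.center[0] - 100, ann.center[1] - 100) <= 2.0
        assert abs(ann.inner_radius - truth.pupil_radius) <= 2.0
        assert abs(ann.outer_radius - truth.iris_radius) <= 2.0

    def test_noisy_eye_recovered(self):
        spec = EyeSpec((100.0, 100.0), 30.0, 80.0, 2, noise_sigma=8.0, seed=5)
        img, truth = generate_eye_image(spec)
        ann = segment_iris(img)
        assert np.hypot(ann.center[0] - 100, ann.center[1] - 100) <= 2.0
        assert abs(ann.inner_radius - 30) <= 2.0
        assert abs(ann.outer_radius - 80) <= 2.0

    def test_blank_image_fails(self):
        with pytest.raises(SegmentationError):
            segment_iris(np.full((100, 100), 128.0))

    def test_radius_ordering(self, clean_eye):
        ann = segment_iris(clean_eye[0])
        assert 0 < ann.inner_radius < ann.outer_radius

    @pytest.mark.parametrize("shift", [(7, 0), (0, -9), (5, 11)])
    def test_translation_equivariance(self, shift):
        dx, dy = shift
        base = EyeSpec((100.0, 100.0), 24.0, 64.0, 1)
        moved = EyeSpec((100.0 + dx, 100.0 + dy), 24.0, 64.0, 1)
        a0 = segment_iris(generate_eye_image(base)[0])
        a1 = segment_iris(generate_eye_image(moved)[0])
        assert abs((a1.center[0] - a0.center[0]) - dx) <= 0.5
        assert abs((a1.center[1] - a0.center[1]) - dy) <= 0.5
        assert abs(a1.inner_radius - a0.inner_radius) <= 0.5
        assert abs(a1.outer_radius - a0.outer_radius) <= 0.5

    def test_sobel_path_also_segments(self, clean_eye):
        img, truth = clean_eye
        ann = segment_iris(img, SegmentationConfig(edge_method="sobel"))
        assert np.hypot(ann.center[0] - 100, ann.center[1] - 100) <= 2.0
        assert abs(ann.outer_radius - truth.iris_radius) <= 2.0
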