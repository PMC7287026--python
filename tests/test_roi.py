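import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from ommaquant import (DegenerateInputError, GeometryError, PixelSet,
                       SegmentationParams, StageError, crop_roi,
                       filter_by_distance, fit_confidence_ellipse, l1_median,
                       make_disc_kernel, render_eye, segment_eye,
                       select_bright_pixels, white_tophat)


def brute_force_disc_count(size):
    r = (size - 1) / 2
    return sum(1 for i in range(size) for j in range(size)
               if (i - r) ** 2 + (j - r) ** 2 <= r * r)


def distance_sum(x, pts):
    return np.hypot(*(pts - x).T).sum()


def grid_minimize(pts, resolution=0.01):
    """Shrinking-window grid search for the geometric median.

    The distance-sum objective is convex, so refining a coarse grid around
    the running minimum converges to the global minimum.
    """
    lo = pts.min(axis=0) - 1.0
    hi = pts.max(axis=0) + 1.0
    center = (lo + hi) / 2
    span = (hi - lo).max() / 2
    while span > resolution / 2:
        rr = np.linspace(center[0] - span, center[0] + span, 21)
        cc = np.linspace(center[1] - span, center[1] + span, 21)
        grid = np.array([(r, c) for r in rr for c in cc])
        vals = [distance_sum(g, pts) for g in grid]
        center = grid[int(np.argmin(vals))]
        span *= 0.2
    return center


class TestDiscKernel:
    @pytest.mark.parametrize("size", [1, 3, 5, 7, 9, 11])
    def test_counts_match_brute_force(self, size):
        assert make_disc_kernel(size).sum() == brute_force_disc_count(size)

    def test_size_nine_has_49_pixels(self):
        assert make_disc_kernel(9).sum() == 49

    def test_size_three_is_plus_shape(self):
        expected = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=np.uint8)
        assert np.array_equal(make_disc_kernel(3), expected)

    @pytest.mark.parametrize("size", [0, 2, 8, -3])
    def test_rejects_even_or_nonpositive(self, size):
        with pytest.raises(ValueError):
            make_disc_kernel(size)


class TestWhiteTophat:
    def test_constant_image_gives_zero(self):
        img = np.full((30, 30), 0.6)
        assert np.allclose(white_tophat(img, make_disc_kernel(9)), 0.0)

    def test_small_bright_object_survives(self):
        img = np.zeros((40, 40))
        img[20, 20] = 1.0
        out = white_tophat(img, make_disc_kernel(9))
        assert out[20, 20] == 1.0

    def test_large_plateau_interior_removed(self):
        img = np.zeros((80, 80))
        img[10:60, 10:60] = 0.8
        kernel = make_disc_kernel(9)
        out = white_tophat(img, kernel)
        # oracle: opening composed from erosion followed by dilation
        eroded = ndimage.grey_erosion(img, footprint=kernel, mode="nearest")
        opened = ndimage.grey_dilation(eroded, footprint=kernel, mode="nearest")
        assert np.allclose(out, img - opened)
        assert np.allclose(out[20:50, 20:50], 0.0)

    def test_rgb_processed_per_channel(self, rng):
        img = rng.random((25, 25, 3))
        out = white_tophat(img, make_disc_kernel(5))
        for c in range(3):
            assert np.allclose(out[..., c],
                               white_tophat(img[..., c], make_disc_kernel(5)))

    def test_kernel_too_large(self):
        with pytest.raises(ValueError):
            white_tophat(np.zeros((5, 5)), make_disc_kernel(9))


class TestBrightPixelSelection:
    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            select_bright_pixels(np.full((20, 20), 0.4))

    def test_single_bright_pixel_selected(self):
        img = np.zeros((100, 100))
        img[7, 13] = 1.0
        ps = select_bright_pixels(img, 0.99)
        assert [7, 13] in ps.coordinates.tolist()

    def test_ramp_keeps_strictly_above_interpolated_quantile(self):
        vals = np.linspace(0, 1, 10_000)
        img = vals.reshape(100, 100)
        ps = select_bright_pixels(img, 0.99)
        thr = np.quantile(vals, 0.99)  # Hyndman-Fan type 7
        expected = np.count_nonzero(vals > thr)
        assert len(ps) == expected
        # the strictly-greater rule keeps almost exactly 1% of pixels
        assert abs(expected - 100) <= 1

    def test_monotone_in_quantile(self, small_eye_spec):
        gray = render_eye(small_eye_spec, 3).image.mean(axis=2)
        counts = [len(select_bright_pixels(gray, q))
                  for q in (0.995, 0.99, 0.95, 0.9, 0.5)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestL1Median:
    def test_single_point(self):
        assert np.allclose(l1_median(np.array([[4.0, 7.0]])), [4, 7])

    def test_collinear_returns_middle(self):
        pts = np.array([[0.0, 5.0], [1.0, 5.0], [10.0, 5.0]])
        assert np.allclose(l1_median(pts), [1.0, 5.0], atol=1e-4)

    def test_square_corners_give_center(self):
        pts = np.array([[0.0, 0.0], [0.0, 2.0], [2.0, 0.0], [2.0, 2.0]])
        assert np.allclose(l1_median(pts), [1.0, 1.0], atol=1e-5)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 100, size=(rng.integers(5, 21), 2))
            ours = l1_median(pts)
            oracle = grid_minimize(pts)
            assert distance_sum(ours, pts) <= distance_sum(oracle, pts) + 0.05
            assert np.linalg.norm(ours - oracle) < 0.5 or np.isclose(
                distance_sum(ours, pts), distance_sum(oracle, pts), atol=0.05)

    def test_inside_convex_hull_bounding_box(self, rng):
        pts = rng.uniform(-50, 50, size=(15, 2))
        med = l1_median(pts)
        assert np.all(med >= pts.min(axis=0) - 1e-9)
        assert np.all(med <= pts.max(axis=0) + 1e-9)

    def test_iterate_landing_on_data_point(self):
        # median of this configuration IS a data point: Weiszfeld must not
        # divide by zero and must return it
        pts = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 0.0],
                        [2.0, 2.0], [-6.0, 2.0], [2.0, -6.0]])
        med = l1_median(pts)
        best = min(distance_sum(p, pts) for p in pts)
        assert distance_sum(med, pts) <= best + 1e-3

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            l1_median(np.empty((0, 2)))


class TestDistanceFilter:
    def _pixelset(self, coords):
        coords = np.asarray(coords)
        return PixelSet(coords, np.full(len(coords), 0.5))

    def test_equidistant_all_kept(self):
        pts = self._pixelset([[0, 1], [1, 0], [0, -1], [-1, 0]])
        kept = filter_by_distance(pts, np.array([0.0, 0.0]), 0.8)
        assert len(kept) == 4

    def test_collinear_interpolated_quantile(self):
        pts = self._pixelset([[0, d] for d in range(1, 11)])
        kept = filter_by_distance(pts, np.array([0.0, 0.0]), 0.8)
        # distance quantile of 1..10 at 0.8 is 8.2; 9 and 10 are discarded
        assert sorted(c[1] for c in kept.coordinates) == list(range(1, 9))

    def test_single_point_kept(self):
        kept = filter_by_distance(self._pixelset([[3, 3]]), np.array([0.0, 0.0]))
        assert len(kept) == 1


class TestConfidenceEllipse:
    def test_coverage_matches_level(self, rng):
        pts = rng.multivariate_normal([50, 60], [[9, 2], [2, 4]], size=10_000)
        ell = fit_confidence_ellipse(pts, 0.90)
        coverage = ell.contains(pts).mean()
        assert abs(coverage - 0.90) < 0.01

    def test_isotropic_semi_axes_closed_form(self, rng):
        pts = rng.standard_normal((40_000, 2))
        ell = fit_confidence_ellipse(pts, 0.90)
        # chi-square(2) 0.90-quantile = 2 ln 10, semi-axis = sqrt of it
        assert np.allclose(ell.scale, 2 * np.log(10), rtol=1e-12)
        assert np.allclose(ell.axes_lengths, np.sqrt(2 * np.log(10)), atol=0.05)

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(GeometryError):
            fit_confidence_ellipse(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError):
            fit_confidence_ellipse(np.array([[0.0, 0.0], [1.0, 2.0]]))


class TestCropROI:
    def _circle(self, center, radius_sq_scale=1.0):
        from ommaquant import EllipseROI
        return EllipseROI(center=np.asarray(center, dtype=float),
                          covariance=np.eye(2) * radius_sq_scale,
                          scale=1.0, confidence_level=0.9)

    def test_ellipse_covering_whole_image(self, rng):
        img = rng.random((20, 20, 3))
        ell = self._circle([10, 10], radius_sq_scale=1e4)
        patch = crop_roi(img, ell)
        assert patch.mask.all()
        assert np.allclose(patch.image, img)

    def test_disc_area_within_two_percent(self):
        img = np.ones((400, 400, 3)) * 0.5
        a = 60.0
        ell = self._circle([200, 200], radius_sq_scale=a * a)
        patch = crop_roi(img, ell)
        assert abs(patch.mask.sum() - np.pi * a * a) / (np.pi * a * a) < 0.02

    def test_overhanging_ellipse_clipped(self):
        img = np.ones((50, 50, 3)) * 0.5
        ell = self._circle([25, 48], radius_sq_scale=100.0)
        patch = crop_roi(img, ell)
        assert patch.mask.sum() > 0
        assert patch.offset[1] + patch.image.shape[1] <= 50

    def test_center_outside_rejected(self):
        with pytest.raises(GeometryError):
            crop_roi(np.ones((10, 10, 3)) * 0.5, self._circle([50, 50]))

    def test_outside_mask_zeroed(self, rng):
        img = rng.random((100, 100, 3))
        patch = crop_roi(img, self._circle([50, 50], radius_sq_scale=225.0))
        assert np.all(patch.image[patch.mask == 0] == 0.0)


class TestSegmentEye:
    def test_center_inside_true_eye(self, small_eye_spec):
        li = render_eye(small_eye_spec, 1)
        patch = segment_eye(li.image)
        c = patch.center_full_resolution
        (tr, tc), (a, b) = (li.truth_geometry["eye_center"],
                            li.truth_geometry["eye_axes"])
        assert ((c[0] - tr) / a) ** 2 + ((c[1] - tc) / b) ** 2 <= 1.0

    def test_translation_equivariance(self, small_eye_spec):
        li0 = render_eye(small_eye_spec, 5)
        c0 = segment_eye(li0.image).center_full_resolution
        shifted = dataclasses.replace(small_eye_spec,
                                      eye_center=(small_eye_spec.eye_center[0] + 40,
                                                  small_eye_spec.eye_center[1] - 32))
        li1 = render_eye(shifted, 5)
        c1 = segment_eye(li1.image).center_full_resolution
        assert np.all(np.abs((c1 - c0) - np.array([40, -32])) <= 5.0)

    def test_all_black_image_fails_at_thresholding(self):
        with pytest.raises(StageError) as exc:
            segment_eye(np.zeros((200, 260, 3)))
        assert exc.value.stage == "select_bright_pixels"

    def test_bright_spot_mode_segments(self, small_eye_spec):
        spec = dataclasses.replace(small_eye_spec, illumination="bright_spot")
        li = render_eye(spec, 2)
        patch = segment_eye(li.image)
        c = patch.center_full_resolution
        (tr, tc), (a, b) = (li.truth_geometry["eye_center"],
                            li.truth_geometry["eye_axes"])
        assert ((c[0] - tr) / a) ** 2 + ((c[1] - tc) / b) ** 2 <= 1.0

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SegmentationParams(kernel_size=8)
        with pytest.raises(ValueError):
            SegmentationParams(intensity_quantile=1.0)
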