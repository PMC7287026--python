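"""Automatic eye-ROI detection.

The detector localizes the compound eye in a bright-field photograph by
exploiting that ommatidial facets are small bright structures on a darker
surround.  Five stages run on the quarter-resolution image:

1. white top-hat transform (input minus its morphological opening) with a
   disc structuring element — enhances bright objects smaller than the disc;
2. grayscale conversion and intensity thresholding at the 0.99 quantile —
   keeps only the brightest (facet) pixels;
3. Weiszfeld L1-median of the kept pixel coordinates — a robust centroid;
4. discard of pixels whose distance to the centroid exceeds the 0.8
   quantile of the distance distribution — removes stray bright outliers;
5. a 0.90 confidence ellipse (Gaussian ellipsoid with chi-square(2 df)
   scaling) fitted on the surviving pixels, masked onto the resized image.

Both quantile filters use strict ``>`` comparisons with linearly
interpolated order statistics (Hyndman–Fan type 7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import chi2

from .errors import DegenerateInputError, GeometryError, StageError
from .images import downscale, rgb_to_gray, validate_image


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the five-stage detector.

    ``kernel_size`` is the disc diameter in pixels (odd); the quantiles are
    strict-inequality thresholds; ``ellipse_level`` is the confidence level
    of the final ellipse.
    """

    resize_factor: int = 4
    kernel_size: int = 9
    intensity_quantile: float = 0.99
    distance_quantile: float = 0.8
    ellipse_level: float = 0.90

    def __post_init__(self):
        if self.resize_factor < 1:
            raise ValueError("resize_factor must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        for name in ("intensity_quantile", "distance_quantile", "ellipse_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly inside (0, 1)")


@dataclass
class PixelSet:
    """Candidate eye pixels: integer (row, col) coordinates with their
    intensities."""

    coordinates: np.ndarray  # (n, 2) int
    intensities: np.ndarray  # (n,) float in [0, 1]

    def __post_init__(self):
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=np.intp))
        self.intensities = np.atleast_1d(np.asarray(self.intensities, dtype=np.float64))
        if self.coordinates.shape != (len(self.intensities), 2):
            raise ValueError("coordinates and intensities must be aligned (n, 2)/(n,)")

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class EllipseROI:
    """Confidence ellipse: a point x is inside iff
    ``(x - center)^T cov^{-1} (x - center) <= scale`` with
    ``scale = chi2.ppf(confidence_level, df=2)``."""

    center: np.ndarray          # (2,) (row, col)
    covariance: np.ndarray      # (2, 2) SPD
    scale: float
    confidence_level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for (n, 2) (row, col) points."""
        d = np.atleast_2d(points) - self.center
        sol = np.linalg.solve(self.covariance, d.T)
        return np.einsum("ij,ji->i", d, sol) <= self.scale

    @property
    def axes_lengths(self) -> np.ndarray:
        """Semi-axis lengths (major, minor) in pixels."""
        ev = np.linalg.eigvalsh(self.covariance)
        return np.sqrt(self.scale * ev)[::-1]

    @property
    def angle_deg(self) -> float:
        """Orientation of the major axis, degrees from the column axis."""
        ev, evec = np.linalg.eigh(self.covariance)
        major = evec[:, np.argmax(ev)]
        return float(np.degrees(np.arctan2(major[0], major[1])) % 180.0)


@dataclass
class ROIPatch:
    """Elliptical region cropped from the resized image.

    ``image`` is the rectangular bounding-box crop with pixels outside the
    ellipse zeroed; ``mask`` marks ellipse membership; ``offset`` is the
    (row, col) of the crop's top-left corner in the resized frame.
    """

    image: np.ndarray
    mask: np.ndarray
    source_ellipse: EllipseROI
    offset: tuple[int, int] = (0, 0)
    resize_factor: int = 1
    source_path: str = ""

    @property
    def center_full_resolution(self) -> np.ndarray:
        """Ellipse center mapped back to the original image frame."""
        return self.source_ellipse.center * self.resize_factor


def make_disc_kernel(size: int) -> np.ndarray:
    """Binary disc structuring element of odd diameter ``size``.

    Cell (i, j) is set iff its squared distance to the center is at most
    ``r^2`` with ``r = (size - 1) / 2``, so size 9 gives the 49-pixel disc.
    """
    if not isinstance(size, (int, np.integer)) or size < 1 or size % 2 == 0:
        raise ValueError(f"disc kernel size must be a positive odd integer, got {size!r}")
    r = (size - 1) / 2
    ii, jj = np.mgrid[0:size, 0:size]
    return ((ii - r) ** 2 + (jj - r) ** 2 <= r * r + 1e-12).astype(np.uint8)


def white_tophat(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """White top-hat: input minus its grayscale opening by ``kernel``.

    The opening (erosion then dilation) removes bright objects smaller than
    the structuring element, so the difference retains exactly those
    objects.  RGB input is transformed per channel; borders are handled by
    edge replication to avoid spurious bright rims.
    """
    img = validate_image(img)
    kernel = np.asarray(kernel, dtype=bool)
    if kernel.shape[0] > img.shape[0] or kernel.shape[1] > img.shape[1]:
        raise ValueError("structuring kernel is larger than the image")

    def _one(channel: np.ndarray) -> np.ndarray:
        opened = ndimage.grey_opening(channel, footprint=kernel, mode="nearest")
        return channel - opened

    if img.ndim == 2:
        out = _one(img)
    else:
        out = np.dstack([_one(img[:, :, c]) for c in range(3)])
    # opening <= input pointwise, so the difference is already >= 0
    return np.clip(out, 0.0, 1.0)


def _quantile(values: np.ndarray, q: float) -> float:
    # Hyndman–Fan type 7 (linear interpolation of order statistics)
    return float(np.quantile(values, q, method="linear"))


def select_bright_pixels(gray: np.ndarray, q: float = 0.99) -> PixelSet:
    """Keep pixels with intensity strictly above the ``q`` quantile."""
    gray = validate_image(gray)
    if gray.ndim != 2:
        raise ValueError("select_bright_pixels expects a grayscale image")
    if not 0.0 < q < 1.0:
        raise ValueError("quantile must lie strictly inside (0, 1)")
    thr = _quantile(gray.ravel(), q)
    rows, cols = np.nonzero(gray > thr)
    if rows.size == 0:
        raise DegenerateInputError(
            "no pixel strictly exceeds the intensity quantile "
            f"(threshold {thr:.4f}); lower intensity_quantile or check the image"
        )
    return PixelSet(np.column_stack([rows, cols]), gray[rows, cols])


def l1_median(points: PixelSet | np.ndarray, *, tol: float = 1e-6,
              max_iter: int = 1000) -> np.ndarray:
    """Geometric (L1) median of a 2-D point set by Weiszfeld iteration.

    Minimizes the sum of Euclidean distances to the points — a more robust
    central estimate than the arithmetic mean.  Iterates

        x_{k+1} = sum_i(p_i / ||x_k - p_i||) / sum_i(1 / ||x_k - p_i||)

    starting from the coordinate-wise median, stopping when successive
    iterates move less than ``tol`` (or after ``max_iter`` rounds).  If an
    iterate coincides with a data point the Vardi–Zhang adjusted step is
    used to avoid division by zero.
    """
    pts = points.coordinates if isinstance(points, PixelSet) else np.asarray(points)
    pts = np.atleast_2d(pts).astype(np.float64)
    if pts.size == 0:
        raise ValueError("l1_median requires at least one point")
    if len(pts) == 1:
        return pts[0].copy()

    x = np.median(pts, axis=0)
    for _ in range(max_iter):
        diff = pts - x
        dist = np.hypot(diff[:, 0], diff[:, 1])
        at_point = dist < 1e-9
        if at_point.any():
            # Vardi–Zhang: treat the coincident point's multiplicity as a
            # pull toward staying, balanced against the gradient of the rest
            far = ~at_point
            if not far.any():
                return x
            w = 1.0 / dist[far]
            t = (pts[far] * w[:, None]).sum(axis=0) / w.sum()
            r_vec = ((pts[far] - x) * w[:, None]).sum(axis=0)
            r = np.hypot(*r_vec)
            eta = float(at_point.sum())
            if r < 1e-12 or eta >= r:
                return x  # x is the median
            step = max(0.0, 1.0 - eta / r) * t + min(1.0, eta / r) * x
            x_new = step
        else:
            w = 1.0 / dist
            x_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.hypot(*(x_new - x)) < tol:
            return x_new
        x = x_new
    return x


def filter_by_distance(points: PixelSet, center: np.ndarray,
                       q: float = 0.8) -> PixelSet:
    """Discard points whose Euclidean distance to ``center`` is strictly
    above the ``q`` quantile of the distance distribution."""
    if len(points) == 0:
        raise ValueError("filter_by_distance requires a non-empty point set")
    if not 0.0 < q < 1.0:
        raise ValueError("quantile must lie strictly inside (0, 1)")
    d = np.hypot(*(points.coordinates - np.asarray(center, dtype=np.float64)).T)
    keep = d <= _quantile(d, q)
    return PixelSet(points.coordinates[keep], points.intensities[keep])


def fit_confidence_ellipse(points: PixelSet | np.ndarray,
                           level: float = 0.90) -> EllipseROI:
    """Gaussian confidence ellipse of a 2-D point cloud.

    Center is the coordinate mean, covariance the sample covariance
    (denominator n-1), and the Mahalanobis radius is the chi-square(2 df)
    quantile at ``level`` (about 4.605 at 0.90, i.e. 2·ln 10), so that for
    Gaussian data the ellipse covers a ``level`` fraction of the points.
    """
    pts = points.coordinates if isinstance(points, PixelSet) else np.asarray(points)
    pts = np.atleast_2d(pts).astype(np.float64)
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie strictly inside (0, 1)")
    if len(pts) < 3:
        raise GeometryError("confidence ellipse requires at least 3 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    ev = np.linalg.eigvalsh(cov)
    if ev[0] <= 1e-12 * max(ev[1], 1.0):
        raise GeometryError("singular covariance (collinear points); cannot fit ellipse")
    return EllipseROI(center=center, covariance=cov,
                      scale=float(chi2.ppf(level, df=2)), confidence_level=level)


def crop_roi(img: np.ndarray, ellipse: EllipseROI, *,
             resize_factor: int = 1, source_path: str = "") -> ROIPatch:
    """Crop the ellipse's bounding box from ``img`` and zero pixels outside
    the ellipse, keeping a rectangular grid for featurization."""
    img = validate_image(img)
    h, w = img.shape[:2]
    cr, cc = ellipse.center
    if not (0 <= cr < h and 0 <= cc < w):
        raise GeometryError("ellipse center lies outside the image bounds")
    # max extent of the ellipse along each coordinate axis: sqrt(scale * cov_ii)
    half = np.sqrt(ellipse.scale * np.diag(ellipse.covariance))
    r0 = max(0, int(np.floor(cr - half[0])))
    r1 = min(h, int(np.ceil(cr + half[0])) + 1)
    c0 = max(0, int(np.floor(cc - half[1])))
    c1 = min(w, int(np.ceil(cc + half[1])) + 1)
    if r0 >= r1 or c0 >= c1:
        raise GeometryError("ellipse does not intersect the image")
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    pts = np.column_stack([rr.ravel(), cc_grid.ravel()]).astype(np.float64)
    mask = ellipse.contains(pts).reshape(rr.shape)
    if not mask.any():
        raise GeometryError("ellipse mask is empty after clipping to the image")
    crop = img[r0:r1, c0:c1].copy()
    crop[~mask] = 0.0
    return ROIPatch(image=crop, mask=mask.astype(np.uint8),
                    source_ellipse=ellipse, offset=(r0, c0),
                    resize_factor=resize_factor, source_path=source_path)


def segment_eye(img: np.ndarray, params: SegmentationParams | None = None,
                *, source_path: str = "") -> ROIPatch:
    """Full eye detector; returns the ROI patch in the resized frame.

    Pipeline: downscale → white top-hat (disc kernel, per channel) →
    grayscale → bright-pixel selection → L1-median centroid → distance
    outlier rejection → confidence ellipse → mask onto the resized image.
    Failures are re-raised as :class:`StageError` with the stage name.
    """
    params = params or SegmentationParams()
    img = validate_image(img)

    def _stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except (DegenerateInputError, GeometryError, ValueError) as exc:
            raise StageError(name, exc) from exc

    small = _stage("downscale", downscale, img, params.resize_factor)
    kernel = make_disc_kernel(params.kernel_size)
    enhanced = _stage("white_tophat", white_tophat, small, kernel)
    gray = _stage("rgb_to_gray", rgb_to_gray, enhanced)
    bright = _stage("select_bright_pixels", select_bright_pixels,
                    gray, params.intensity_quantile)
    center = _stage("l1_median", l1_median, bright)
    kept = _stage("filter_by_distance", filter_by_distance,
                  bright, center, params.distance_quantile)
    ellipse = _stage("fit_confidence_ellipse", fit_confidence_ellipse,
                     kept, params.ellipse_level)
    return _stage("crop_roi", crop_roi, small, ellipse,
                  resize_factor=params.resize_factor, source_path=source_path)
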