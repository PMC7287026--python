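"""Histogram-of-oriented-gradients featurization.

Each grayscale ROI is summarized by a coarse HOG: the image is split into a
5 x 5 grid of contiguous cells, the unsigned gradient orientation (0-180°)
of every pixel is assigned to one of five 36°-wide bins weighted by the
gradient magnitude, and each cell histogram is L2-normalized.  The
concatenated, cell-major result is a 125-dimensional descriptor that is
invariant to global intensity scaling and shifts — the classifiers
therefore respond to ommatidial structure, not illumination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import rgb_to_gray, validate_image


@dataclass(frozen=True)
class HOGParams:
    """Descriptor layout: ``cells_per_side``² cells × ``n_orientations``
    unsigned-orientation bins over 0-180°.  ``interpolate_votes`` enables
    bilinear vote sharing between the two nearest bins (off by default:
    hard binning is the documented contract)."""

    cells_per_side: int = 5
    n_orientations: int = 5
    interpolate_votes: bool = False

    def __post_init__(self):
        if self.cells_per_side < 1 or self.n_orientations < 1:
            raise ValueError("cells_per_side and n_orientations must be >= 1")

    @property
    def n_features(self) -> int:
        return self.cells_per_side ** 2 * self.n_orientations


@dataclass
class GradientField:
    """Per-pixel gradient magnitude and unsigned orientation (degrees in
    [0, 180))."""

    magnitude: np.ndarray
    orientation: np.ndarray


@dataclass
class FeatureMatrix:
    """Stacked descriptors with aligned labels and source provenance."""

    X: np.ndarray                 # (n, d)
    labels: list[str] = field(default_factory=list)
    paths: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64).reshape(len(self.labels), -1) \
            if len(self.labels) else np.asarray(self.X, dtype=np.float64)
        if self.labels and self.X.shape[0] != len(self.labels):
            raise ValueError("feature rows and labels must be aligned")

    def __len__(self) -> int:
        return self.X.shape[0]


def compute_gradient(gray: np.ndarray) -> GradientField:
    """Centered-difference gradient with edge-replicated borders.

    Orientation is ``atan2(gy, gx)`` folded modulo 180°, so a purely
    horizontal gradient (a vertical edge) maps to 0°.
    """
    gray = validate_image(gray)
    if gray.ndim != 2:
        raise ValueError("compute_gradient expects a grayscale image")
    if gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for centered differences")
    p = np.pad(gray, 1, mode="edge")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    mag = np.hypot(gx, gy)
    orient = np.degrees(np.arctan2(gy, gx)) % 180.0
    return GradientField(magnitude=mag, orientation=orient)


def _cell_edges(n: int, k: int) -> np.ndarray:
    # k contiguous bands whose sizes differ by at most 1
    return np.linspace(0, n, k + 1).round().astype(int)


def hog_descriptor(gray: np.ndarray, params: HOGParams | None = None, *,
                   normalize: bool = True, eps: float = 1e-6) -> np.ndarray:
    """Compute the descriptor for one grayscale image.

    Cells are contiguous bands (sizes differing by at most one pixel when
    the dimensions are not divisible).  With hard binning, a pixel's
    magnitude is added to bin ``floor(orientation / bin_width)`` clamped to
    the last bin.  Each cell block is L2-normalized
    (``h / sqrt(||h||² + eps²)``), so a zero-gradient cell stays zero and
    every block has norm at most 1.  Blocks are concatenated cell-major
    (row-major over cells, orientation bins innermost).
    """
    params = params or HOGParams()
    gray = validate_image(gray)
    if gray.ndim != 2:
        raise ValueError("hog_descriptor expects a grayscale image")
    k = params.cells_per_side
    if gray.shape[0] < max(k, 3) or gray.shape[1] < max(k, 3):
        raise ValueError(f"image too small for a {k}x{k} cell grid")

    field_ = compute_gradient(gray)
    nb = params.n_orientations
    bin_width = 180.0 / nb

    if params.interpolate_votes:
        pos = field_.orientation / bin_width - 0.5
        lo = np.floor(pos).astype(int)
        frac = pos - lo
        lo_m = field_.magnitude * (1.0 - frac)
        hi_m = field_.magnitude * frac
        lo_bin = lo % nb
        hi_bin = (lo + 1) % nb
    else:
        hard = np.minimum((field_.orientation // bin_width).astype(int), nb - 1)

    row_edges = _cell_edges(gray.shape[0], k)
    col_edges = _cell_edges(gray.shape[1], k)
    out = np.empty(k * k * nb, dtype=np.float64)
    idx = 0
    for i in range(k):
        for j in range(k):
            sl = (slice(row_edges[i], row_edges[i + 1]),
                  slice(col_edges[j], col_edges[j + 1]))
            if params.interpolate_votes:
                h = (np.bincount(lo_bin[sl].ravel(), lo_m[sl].ravel(), minlength=nb)
                     + np.bincount(hi_bin[sl].ravel(), hi_m[sl].ravel(), minlength=nb))
            else:
                h = np.bincount(hard[sl].ravel(),
                                weights=field_.magnitude[sl].ravel(), minlength=nb)
            if normalize:
                h = h / np.sqrt(h @ h + eps * eps)
            out[idx:idx + nb] = h
            idx += nb
    return out


def featurize_dataset(patches, labels, params: HOGParams | None = None) -> FeatureMatrix:
    """Batch featurization: grayscale conversion then HOG per ROI patch.

    ``patches`` may be :class:`~ommaquant.roi.ROIPatch` objects or plain
    image arrays; rows keep the input order.
    """
    params = params or HOGParams()
    patches = list(patches)
    labels = list(labels)
    if len(patches) != len(labels):
        raise ValueError("patches and labels must be aligned")
    rows, paths = [], []
    for p in patches:
        img = getattr(p, "image", p)
        paths.append(getattr(p, "source_path", ""))
        gray = rgb_to_gray(img) if np.ndim(img) == 3 else validate_image(img)
        rows.append(hog_descriptor(gray, params))
    X = np.vstack(rows) if rows else np.empty((0, params.n_features))
    return FeatureMatrix(X=X, labels=labels, paths=paths)
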