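"""Image I/O and geometry primitives.

All images in this package are ``float64`` arrays with intensities in
``[0, 1]``: RGB images have shape ``(height, width, 3)`` and grayscale
images ``(height, width)``.  Coordinates are ``(row, col)``, 0-based, with
rows increasing downward.  Every other module relies on these conventions.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio
from skimage.transform import resize as _sk_resize

from .errors import ImageFormatError

#: Rec. 709 luminance coefficients for (R, G, B).  The grayscale conversion
#: preserves luminance; the weights are configurable in :func:`rgb_to_gray`.
REC709_WEIGHTS = (0.2126, 0.7152, 0.0722)


def _as_float01(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer image to [0, 1] by its bit-depth maximum."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / info.max
    arr = arr.astype(np.float64)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ImageFormatError("float image intensities must lie in [0, 1]")
    return arr


def validate_image(img: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Check the shared pixel contract: finite values in [0, 1], 2-D gray
    or (h, w, 3) RGB, non-empty."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim not in (2, 3) or (img.ndim == 3 and img.shape[2] != 3):
        raise ImageFormatError(
            f"{name} must be 2-D grayscale or (h, w, 3) RGB, got shape {img.shape}"
        )
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ImageFormatError(f"{name} must have positive dimensions")
    if not np.all(np.isfinite(img)):
        raise ImageFormatError(f"{name} contains non-finite intensities")
    if img.min() < 0 or img.max() > 1:
        raise ImageFormatError(f"{name} intensities must lie in [0, 1]")
    return img


def load_image(path) -> np.ndarray:
    """Load a TIFF/PNG raster as an (h, w, 3) RGB float image in [0, 1].

    Integer pixel values are rescaled by the bit-depth maximum (255 for
    8-bit, 65535 for 16-bit).  Single-channel inputs are replicated to three
    channels; an alpha channel is dropped.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt/unreadable file
        raise ImageFormatError(f"cannot read image file {path!s}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(
            f"unsupported pixel layout {arr.shape} in {path!s} (expected gray, RGB or RGBA)"
        )
    return validate_image(_as_float01(arr), name=str(path))


def save_image(path, img: np.ndarray) -> None:
    """Write an image as 8-bit PNG (or TIFF by extension)."""
    img = validate_image(img)
    iio.imwrite(path, np.round(img * 255).astype(np.uint8))


def downscale(img: np.ndarray, factor: int = 4) -> np.ndarray:
    """Shrink an image by an integer factor with bilinear interpolation.

    Output dimensions are ``round(h / factor) x round(w / factor)``.  An
    antialiasing filter is applied before resampling to avoid moiré on
    ommatidial lattices.
    """
    img = validate_image(img)
    if not (isinstance(factor, (int, np.integer)) and not isinstance(factor, bool)):
        raise ValueError(f"downscale factor must be an integer, got {factor!r}")
    if factor < 1:
        raise ValueError(f"downscale factor must be >= 1, got {factor}")
    if factor > min(img.shape[0], img.shape[1]):
        raise ValueError("downscale factor exceeds the image dimensions")
    if factor == 1:
        return img.copy()
    out_shape = (
        max(1, round(img.shape[0] / factor)),
        max(1, round(img.shape[1] / factor)),
    )
    return resize_to(img, *out_shape, antialias=True)


def rgb_to_gray(img: np.ndarray, weights=REC709_WEIGHTS) -> np.ndarray:
    """Convert RGB to grayscale luminance (weighted channel mean).

    Default weights are Rec. 709; they sum to 1 so constants are preserved
    and the output stays within ``[min(R,G,B), max(R,G,B)]`` pointwise.
    """
    img = validate_image(img)
    if img.ndim == 2:
        return img.copy()
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,) or not np.isclose(w.sum(), 1.0):
        raise ValueError("luminance weights must be 3 values summing to 1")
    return img @ w


def resize_to(img: np.ndarray, out_height: int, out_width: int, *,
              antialias: bool | None = None) -> np.ndarray:
    """Resize to exact dimensions with bilinear interpolation.

    Constant images map to the same constant; resizing to the input's own
    dimensions is the identity.
    """
    img = validate_image(img)
    if out_height < 1 or out_width < 1:
        raise ValueError("target dimensions must be positive")
    if (out_height, out_width) == img.shape[:2]:
        return img.copy()
    if antialias is None:
        antialias = out_height < img.shape[0] or out_width < img.shape[1]
    out_shape = (out_height, out_width) + img.shape[2:]
    out = _sk_resize(img, out_shape, order=1, anti_aliasing=antialias,
                     preserve_range=True, mode="edge")
    return np.clip(out, 0.0, 1.0)
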