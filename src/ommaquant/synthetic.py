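"""Synthetic compound-eye renderer.

Generates labeled bright-field-like images of a fly eye so that every
pipeline stage — segmentation, featurization, classification, IREG — can be
exercised end to end without external data.  The appearance model is
deliberately minimal but captures the features the pipeline keys on:

* a convex elliptical eye (radially shaded dark red body) on a dim
  background;
* a hexagonal lattice of ommatidial facets clipped to the eye, rendered
  as the Voronoi cells of the facet centers: bright domed interiors
  separated by thin dark grooves.  A regular lattice gives hexagonal
  facets whose groove edges fall into three orientation families; Gaussian
  positional jitter deforms the cells and randomizes edge orientations,
  which is exactly the structural signal oriented-gradient features key
  on in real degeneration;
* degeneration features: fusion of neighboring facets (the groove between
  a facet and its two nearest neighbors is erased, merging them into
  larger smooth blobs), depigmented patches with an attenuated red
  channel, and loss of the dark interommatidial bristle dots;
* two illumination modes — ``diffuse`` (facets read as brighter red
  polygons) and ``bright_spot`` (a specular white highlight per facet);
* a Gaussian camera point-spread function and additive pixel noise.

The degeneration endpoints are calibrated so that the five equally spaced
disorder levels move the image statistics in visibly distinct steps: the
jitter endpoint (0.23 of the lattice spacing) spreads the decay of the
hexagonal orientation order over the whole level range instead of
saturating early, while fusion and bristle loss progress linearly and
carry the upper levels.

Rendering is fully deterministic given ``(spec, seed)``, and the ground
truth (eye ellipse, facet centers) is returned alongside each image.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import save_image

#: Disorder level of each phenotype class, mirroring the equally spaced
#: IREG gridlines.
CLASS_LEVELS: dict[str, float] = {
    "WT": 0.0,
    "modifier#1": 0.25,
    "modifier#2": 0.5,
    "modifier#3": 0.75,
    "gmr>SCA1": 1.0,
}

#: Fully degenerated (level 1) endpoint of the degeneration series; the
#: level-0 endpoint is the base spec itself.
SCA1_ENDPOINT = {
    "jitter_sd": 5.5,
    "fusion_prob": 1.0,
    "depig_prob": 0.6,
    "bristle_density": 0.0,
}

#: Fixed orientation of the ommatidial lattice rows (degrees).  Placing the
#: three groove-edge families mid-bin (at 15, 75 and 135 degrees) avoids
#: the 0/180 wrap-around of unsigned orientations.
LATTICE_ROTATION_DEG = 15.0

_EYE_BODY = np.array([0.42, 0.07, 0.07])
_FACET = np.array([0.80, 0.20, 0.12])
_GROOVE = np.array([0.06, 0.02, 0.02])
_BRISTLE = np.array([0.05, 0.04, 0.04])
_SPOT = np.array([0.97, 0.95, 0.90])


@dataclass(frozen=True)
class EyeSpec:
    """Geometry, degeneration and illumination parameters of one render.

    ``eye_axes`` are the (row, col) semi-axes of the eye ellipse in pixels;
    ``lattice_spacing`` is the ommatidial center-to-center distance;
    ``jitter_sd`` the Gaussian positional noise of facet centers;
    ``fusion_prob`` the per-facet probability of merging with its nearest
    neighbor; ``depig_prob`` controls the extent of depigmented patches;
    ``bristle_density`` the fraction of interommatidial bristles present.
    """

    image_size: tuple[int, int] = (960, 1280)
    eye_center: tuple[float, float] = (480.0, 640.0)
    eye_axes: tuple[float, float] = (220.0, 300.0)
    lattice_spacing: float = 24.0
    jitter_sd: float = 0.5
    fusion_prob: float = 0.02
    depig_prob: float = 0.02
    bristle_density: float = 0.9
    illumination: str = "diffuse"
    background_level: float = 0.12
    blur_sigma: float = 4.0
    noise_sd: float = 0.003

    def __post_init__(self):
        h, w = self.image_size
        cr, cc = self.eye_center
        a, b = self.eye_axes
        if not (a <= cr <= h - a and b <= cc <= w - b):
            raise ValueError("eye ellipse does not fit inside the image")
        if self.lattice_spacing < 2:
            raise ValueError("lattice_spacing must be >= 2 px")
        for name in ("fusion_prob", "depig_prob", "bristle_density"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")
        if self.illumination not in ("diffuse", "bright_spot"):
            raise ValueError("illumination must be 'diffuse' or 'bright_spot'")
        if self.jitter_sd < 0 or self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class LabeledImage:
    """A rendered eye with its class label and generator ground truth."""

    image: np.ndarray
    class_label: str | None
    disorder_level: float
    truth_geometry: dict


def _hex_lattice(spec: EyeSpec) -> np.ndarray:
    """Hexagonal facet centers (rotated by LATTICE_ROTATION_DEG) clipped to
    92% of the eye ellipse."""
    cr, cc = spec.eye_center
    a, b = spec.eye_axes
    s = spec.lattice_spacing
    radius = max(a, b)
    dy = s * np.sqrt(3) / 2
    pts = []
    for k in range(int(np.ceil(-radius / dy)), int(np.floor(radius / dy)) + 1):
        r = k * dy
        off = (k % 2) * s / 2
        for m in range(int(np.ceil((-radius - off) / s)),
                       int(np.floor((radius - off) / s)) + 1):
            pts.append((r, off + m * s))
    pts = np.asarray(pts, dtype=np.float64)
    th = np.deg2rad(LATTICE_ROTATION_DEG)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pts = pts @ rot.T + np.array([cr, cc])
    keep = (((pts[:, 0] - cr) / a) ** 2
            + ((pts[:, 1] - cc) / b) ** 2) <= 0.92 ** 2
    return pts[keep]


def _stamp_disc(img: np.ndarray, center, radius: float, color: np.ndarray,
                blend: float = 1.0) -> None:
    """Alpha-blend an antialiased disc into the image in place."""
    h, w = img.shape[:2]
    r0 = max(0, int(np.floor(center[0] - radius - 1)))
    r1 = min(h, int(np.ceil(center[0] + radius + 2)))
    c0 = max(0, int(np.floor(center[1] - radius - 1)))
    c1 = min(w, int(np.ceil(center[1] + radius + 2)))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - center[0], cc - center[1])
    wgt = np.clip(radius + 0.5 - dist, 0.0, 1.0) * blend
    img[r0:r1, c0:c1] = (img[r0:r1, c0:c1] * (1 - wgt[..., None])
                         + color * wgt[..., None])


def render_eye(spec: EyeSpec, seed: int, *, class_label: str | None = None,
               disorder_level: float = 0.0) -> LabeledImage:
    """Render one eye image; deterministic given ``(spec, seed)``."""
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    cr, cc = spec.eye_center
    a, b = spec.eye_axes
    img = np.full((h, w, 3), spec.background_level, dtype=np.float64)

    rr, ccg = np.mgrid[0:h, 0:w]
    rho2 = ((rr - cr) / a) ** 2 + ((ccg - cc) / b) ** 2
    eye = rho2 <= 1.0
    shade = np.where(eye, 1.0 - 0.12 * rho2, 1.0)
    img[eye] = _EYE_BODY * shade[eye, None]

    centers = _hex_lattice(spec)
    if spec.jitter_sd > 0 and len(centers):
        centers = centers + rng.normal(0.0, spec.jitter_sd, centers.shape)
        inside = (((centers[:, 0] - cr) / a) ** 2
                  + ((centers[:, 1] - cc) / b) ** 2) <= 0.97 ** 2
        centers = centers[inside]

    # fused neighbor pairs: the groove between the two cells is erased
    fused_pairs: set[tuple[int, int]] = set()
    if len(centers):
        fused = rng.random(len(centers)) < spec.fusion_prob
        for i in np.flatnonzero(fused):
            d = np.hypot(*(centers - centers[i]).T)
            d[i] = np.inf
            for j in np.argsort(d)[:2]:
                fused_pairs.add((min(i, int(j)), max(i, int(j))))

    # facets as Voronoi cells: bright domed interior, dark groove where the
    # two nearest centers are nearly equidistant
    if len(centers):
        from scipy.spatial import cKDTree
        s = spec.lattice_spacing
        rows_e, cols_e = np.nonzero(eye)
        pts = np.column_stack([rows_e, cols_e]).astype(np.float64)
        dist, idx = cKDTree(centers).query(pts, k=2)
        d1, d2 = dist[:, 0], dist[:, 1]
        n1, n2 = idx[:, 0], idx[:, 1]
        px_shade = shade[rows_e, cols_e]

        in_lattice = d1 <= 1.1 * s
        dome = np.clip(1.0 - 0.05 * (d1 / (0.6 * s)) ** 2, 0.6, 1.0)
        facet_rgb = _FACET * (px_shade * dome)[:, None]

        groove_w = 0.26 * s
        is_groove = (d2 - d1) < groove_w
        if fused_pairs:
            pair_keys = np.minimum(n1, n2) * len(centers) + np.maximum(n1, n2)
            fused_keys = np.array([i * len(centers) + j for i, j in fused_pairs])
            is_groove &= ~np.isin(pair_keys, fused_keys)
        groove_rgb = _GROOVE * px_shade[:, None]

        color = np.where(is_groove[:, None], groove_rgb, facet_rgb)
        if spec.illumination == "bright_spot":
            spot = (d1 < 0.22 * s) & ~is_groove
            color = np.where(spot[:, None], _SPOT, color)
        sel = in_lattice
        img[rows_e[sel], cols_e[sel]] = color[sel]

    # depigmented patches: red channel attenuated inside random discs
    n_patches = int(np.round(spec.depig_prob * 10))
    for _ in range(n_patches):
        theta = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.uniform(0, 0.7))
        pc = (cr + rad * a * np.sin(theta), cc + rad * b * np.cos(theta))
        pr = rng.uniform(0.12, 0.22) * min(a, b)
        rr0 = max(0, int(pc[0] - pr)); rr1 = min(h, int(pc[0] + pr) + 1)
        cc0 = max(0, int(pc[1] - pr)); cc1 = min(w, int(pc[1] + pr) + 1)
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        sub_r, sub_c = np.mgrid[rr0:rr1, cc0:cc1]
        patch = (np.hypot(sub_r - pc[0], sub_c - pc[1]) <= pr) & eye[rr0:rr1, cc0:cc1]
        sub = img[rr0:rr1, cc0:cc1]
        sub[patch, 0] *= 0.45                       # lose red pigment
        sub[patch, 1] = np.clip(sub[patch, 1] * 1.6 + 0.05, 0, 1)  # pale yellow

    # interommatidial bristles: dark dots at interstitial lattice sites
    if spec.bristle_density > 0:
        lat = _hex_lattice(spec)
        if len(lat):
            s_lat = spec.lattice_spacing
            sites = np.vstack([
                lat + np.array([s_lat * np.sqrt(3) / 6, s_lat / 2]),
                lat + np.array([-s_lat * np.sqrt(3) / 6, s_lat / 2]),
            ])
            keep = rng.random(len(sites)) < spec.bristle_density
            in_eye = (((sites[:, 0] - cr) / a) ** 2
                      + ((sites[:, 1] - cc) / b) ** 2) <= 0.9 ** 2
            br = 0.25 * s_lat
            for p in sites[keep & in_eye]:
                _stamp_disc(img, p, br, _BRISTLE, blend=1.0)

    # camera point-spread function: without it, rasterized groove edges are
    # staircases whose centered-difference orientations collapse onto
    # 0/45/90/135 degrees instead of the true lattice orientations
    if spec.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter
        for ch in range(3):
            img[:, :, ch] = gaussian_filter(img[:, :, ch], spec.blur_sigma)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)

    return LabeledImage(
        image=img, class_label=class_label, disorder_level=disorder_level,
        truth_geometry={
            "eye_center": (cr, cc), "eye_axes": (a, b),
            "ommatidium_centers": centers.copy(),
        },
    )


def degeneration_series(level: float, base: EyeSpec) -> EyeSpec:
    """Interpolate degeneration parameters linearly between the base spec
    (level 0, healthy) and the fully degenerated endpoint (level 1)."""
    if not 0.0 <= level <= 1.0:
        raise ValueError("disorder level must lie in [0, 1]")
    return dataclasses.replace(
        base,
        jitter_sd=base.jitter_sd + level * (SCA1_ENDPOINT["jitter_sd"] - base.jitter_sd),
        fusion_prob=base.fusion_prob + level * (SCA1_ENDPOINT["fusion_prob"] - base.fusion_prob),
        depig_prob=base.depig_prob + level * (SCA1_ENDPOINT["depig_prob"] - base.depig_prob),
        bristle_density=base.bristle_density
        + level * (SCA1_ENDPOINT["bristle_density"] - base.bristle_density),
    )


def _random_center(rng: np.random.Generator, spec: EyeSpec) -> tuple[float, float]:
    h, w = spec.image_size
    a, b = spec.eye_axes
    pad = 4.0
    return (float(rng.uniform(a + pad, h - a - pad)),
            float(rng.uniform(b + pad, w - b - pad)))


def iter_labeled_set(n_per_class: int, base: EyeSpec, seed: int,
                     *, random_positions: bool = True):
    """Lazily render ``n_per_class`` images per phenotype class, with the
    eye at a uniformly random in-frame position so translation invariance
    is exercised continuously.  Yields :class:`LabeledImage` one at a time
    (full-resolution frames are large; callers usually reduce each to an
    ROI patch before accumulating)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    for label, level in CLASS_LEVELS.items():
        spec = degeneration_series(level, base)
        for _ in range(n_per_class):
            if random_positions:
                spec_i = dataclasses.replace(spec, eye_center=_random_center(rng, spec))
            else:
                spec_i = spec
            child = int(rng.integers(0, 2 ** 31 - 1))
            yield render_eye(spec_i, child, class_label=label,
                             disorder_level=level)


def make_labeled_set(n_per_class: int, base: EyeSpec, seed: int,
                     *, random_positions: bool = True) -> list[LabeledImage]:
    """Eager version of :func:`iter_labeled_set`; prefer the iterator for
    large batches."""
    return list(iter_labeled_set(n_per_class, base, seed,
                                 random_positions=random_positions))


def generate_dataset(n_per_class: int, base: EyeSpec, seed: int,
                     out_dir) -> pd.DataFrame:
    """Write a labeled PNG dataset plus a manifest CSV.

    The manifest records path, class, disorder level and the ground-truth
    eye geometry of every image; two runs with the same seed produce
    identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, li in enumerate(iter_labeled_set(n_per_class, base, seed)):
        name = f"eye_{li.class_label.replace('>', '_').replace('#', '')}_{k:04d}.png"
        path = out_dir / name
        save_image(path, li.image)
        tg = li.truth_geometry
        rows.append({
            "path": str(path), "class": li.class_label,
            "disorder_level": li.disorder_level,
            "center_row": tg["eye_center"][0], "center_col": tg["eye_center"][1],
            "axis_row": tg["eye_axes"][0], "axis_col": tg["eye_axes"][1],
            "n_ommatidia": len(tg["ommatidium_centers"]),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
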