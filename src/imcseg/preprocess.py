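"""Image preparation: normalization, gradient-direction inputs, mask
rasterization, paired augmentation and dataset splitting.

Conventions (repo-wide): images are 2D float32 grids in [0, 1], row 0 at the
top, 0-based indices; annotation points are (column, row) pairs; masks are
uint8 grids over {0, 1} with 1 = intima-media complex foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import AnnotationError, BoundsError, ConfigurationError, InputError

DEFAULT_PIXEL_DENSITY = 16.66  # pixels per mm

__all__ = [
    "UltrasoundImage",
    "GradientPair",
    "BoundaryAnnotation",
    "AugmentConfig",
    "crop_frame",
    "normalize",
    "gradient_direction",
    "make_pair",
    "rasterize_mask",
    "augment_pair",
    "split_dataset",
]


def _round_half_up(x):
    """Round halves away from zero-free: 0.5 -> 1, 1.5 -> 2 (for x >= 0)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class UltrasoundImage:
    """A grayscale B-mode frame with its pixel-density calibration."""

    pixels: np.ndarray
    pixel_density: float = DEFAULT_PIXEL_DENSITY

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise InputError("image must be a 2D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class GradientPair:
    """The dual model input: Prewitt and Sobel gradient-direction planes."""

    prewitt_dir: np.ndarray
    sobel_dir: np.ndarray

    def __post_init__(self):
        if self.prewitt_dir.shape != self.sobel_dir.shape:
            raise InputError("gradient planes must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.prewitt_dir.shape


@dataclass
class BoundaryAnnotation:
    """Ordered expert points for the lumen-intima (LI) and
    media-adventitia (MA) interfaces, as (column, row) pairs."""

    li_points: list[tuple[float, float]]
    ma_points: list[tuple[float, float]]

    def validate(self) -> None:
        for name, pts in (("LI", self.li_points), ("MA", self.ma_points)):
            if len(pts) < 2:
                raise AnnotationError(f"{name} interface needs >= 2 points, got {len(pts)}")
            cols = [p[0] for p in pts]
            if any(b <= a for a, b in zip(cols, cols[1:])):
                raise AnnotationError(f"{name} columns must be strictly increasing")

    def columns(self, interface: str) -> np.ndarray:
        pts = self.li_points if interface == "LI" else self.ma_points
        return np.asarray([p[0] for p in pts], dtype=float)

    def rows(self, interface: str) -> np.ndarray:
        pts = self.li_points if interface == "LI" else self.ma_points
        return np.asarray([p[1] for p in pts], dtype=float)


@dataclass
class AugmentConfig:
    """Random-transform magnitudes for paired image/mask augmentation."""

    rotation_deg: float = 10.0
    shift_frac: float = 0.2
    zoom_frac: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.rotation_deg < 0 or self.shift_frac < 0 or self.zoom_frac < 0:
            raise ConfigurationError("augmentation magnitudes must be nonnegative")
        if self.shift_frac >= 0.5:
            raise ConfigurationError("shift_frac must be < 0.5")
        if self.zoom_frac >= 1:
            raise ConfigurationError("zoom_frac must be < 1")


def crop_frame(image: UltrasoundImage, rect: tuple[int, int, int, int]) -> UltrasoundImage:
    """Cut out ``rect = (top, left, height, width)``, e.g. to drop the
    scanner's text frame. Pixel density is preserved."""
    top, left, height, width = rect
    h, w = image.shape
    if height <= 0 or width <= 0:
        raise BoundsError("crop rectangle must have positive area")
    if top < 0 or left < 0 or top + height > h or left + width > w:
        raise BoundsError(f"crop rect {rect} outside image bounds {(h, w)}")
    return UltrasoundImage(image.pixels[top : top + height, left : left + width].copy(),
                           image.pixel_density)


def normalize(grid: np.ndarray, levels: int = 256,
              pixel_density: float = DEFAULT_PIXEL_DENSITY) -> UltrasoundImage:
    """Linear min-max rescale of a raw intensity grid (any integer or float
    range, typically ``levels`` grey levels) to [0, 1].

    A constant grid maps to all zeros by convention.
    """
    arr = np.asarray(grid, dtype=np.float64)
    if arr.size == 0:
        raise InputError("cannot normalize an empty grid")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        out = np.zeros_like(arr)
    else:
        out = (arr - lo) / (hi - lo)
    return UltrasoundImage(out.astype(np.float32), pixel_density)


_OPERATORS = {
    "sobel": ndimage.sobel,
    "prewitt": ndimage.prewitt,
}


def gradient_direction(image: UltrasoundImage | np.ndarray, operator: str) -> np.ndarray:
    """Per-pixel gradient direction from a 3x3 derivative operator, mapped
    affinely from (-pi, pi] to [0, 1].

    Borders are replicate-padded. Pixels with zero gradient magnitude map
    to 0.5 (the image of angle 0).
    """
    if operator not in _OPERATORS:
        raise ConfigurationError(f"unknown operator {operator!r}; use 'sobel' or 'prewitt'")
    arr = image.pixels if isinstance(image, UltrasoundImage) else np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 3:
        raise InputError(f"image must be at least 3x3 for a 3x3 kernel, got {arr.shape}")
    op = _OPERATORS[operator]
    arr = arr.astype(np.float64)
    g_y = op(arr, axis=0, mode="nearest")  # derivative down the rows
    g_x = op(arr, axis=1, mode="nearest")  # derivative along the columns
    theta = np.arctan2(g_y, g_x)  # in [-pi, pi]
    out = (theta + np.pi) / (2.0 * np.pi)
    out[out == 0.0] = 1.0  # fold -pi onto pi: same direction, keeps (0, 1]
    out[(g_x == 0.0) & (g_y == 0.0)] = 0.5
    return out.astype(np.float32)


def make_pair(image: UltrasoundImage) -> GradientPair:
    """Build the model's dual input from one image."""
    return GradientPair(
        prewitt_dir=gradient_direction(image, "prewitt"),
        sobel_dir=gradient_direction(image, "sobel"),
    )


def rasterize_mask(ann: BoundaryAnnotation, shape: tuple[int, int]) -> np.ndarray:
    """Convert sparse LI/MA boundary points into a filled binary band.

    Rows are linearly interpolated per column over each interface's column
    span (no thresholding), rounded half-up, and the band is inclusive of
    both boundary rows. Only columns covered by both interfaces are filled.
    """
    ann.validate()
    h, w = shape
    for name in ("LI", "MA"):
        cols, rows = ann.columns(name), ann.rows(name)
        if cols.min() < 0 or cols.max() > w - 1 or rows.min() < 0 or rows.max() > h - 1:
            raise BoundsError(f"{name} points fall outside shape {shape}")
    c_lo = int(np.ceil(max(ann.columns("LI").min(), ann.columns("MA").min())))
    c_hi = int(np.floor(min(ann.columns("LI").max(), ann.columns("MA").max())))
    mask = np.zeros(shape, dtype=np.uint8)
    if c_hi < c_lo:
        return mask
    cols = np.arange(c_lo, c_hi + 1)
    li = np.interp(cols, ann.columns("LI"), ann.rows("LI"))
    ma = np.interp(cols, ann.columns("MA"), ann.rows("MA"))
    if np.any(li > ma):
        bad = int(cols[np.argmax(li > ma)])
        raise AnnotationError(f"LI lies below MA at column {bad}")
    li_r = _round_half_up(li).astype(int)
    ma_r = _round_half_up(ma).astype(int)
    rows = np.arange(h)[:, None]
    mask[:, c_lo : c_hi + 1] = ((rows >= li_r[None, :]) & (rows <= ma_r[None, :])).astype(np.uint8)
    return mask


def _affine_params(cfg: AugmentConfig, shape: tuple[int, int], draw: int):
    rng = np.random.default_rng([cfg.seed, draw])
    rot = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    sy = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * shape[0]
    sx = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * shape[1]
    zoom = rng.uniform(1.0 - cfg.zoom_frac, 1.0 + cfg.zoom_frac)
    return rot, sy, sx, zoom


def _affine_matrix(rot_deg: float, sy: float, sx: float, zoom: float,
                   shape: tuple[int, int]):
    """Inverse (output -> input) map for scipy.ndimage.affine_transform,
    rotating/zooming about the image centre then translating."""
    theta = np.deg2rad(rot_deg)
    c, s = np.cos(theta), np.sin(theta)
    # forward: out = zoom * R @ (in - centre) + centre + t  (row, col coords)
    fwd = zoom * np.array([[c, -s], [s, c]])
    inv = np.linalg.inv(fwd)
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    t = np.array([sy, sx])
    offset = centre - inv @ (centre + t)
    return inv, offset


def augment_pair(inputs: GradientPair, mask: np.ndarray, cfg: AugmentConfig,
                 draw: int) -> tuple[GradientPair, np.ndarray]:
    """One random rotation + shift + zoom, identical for both gradient
    planes and the mask; deterministic given (cfg.seed, draw).

    Gradient planes are interpolated bilinearly with reflect fill; the mask
    uses nearest-neighbour sampling with background fill and is re-binarized.
    """
    cfg.validate()
    if inputs.shape != mask.shape:
        raise InputError("gradient pair and mask shapes differ")
    rot, sy, sx, zoom = _affine_params(cfg, mask.shape, draw)
    if rot == 0.0 and sy == 0.0 and sx == 0.0 and zoom == 1.0:
        return GradientPair(inputs.prewitt_dir.copy(), inputs.sobel_dir.copy()), mask.copy()
    matrix, offset = _affine_matrix(rot, sy, sx, zoom, mask.shape)

    def warp_image(plane):
        return ndimage.affine_transform(plane.astype(np.float32), matrix, offset=offset,
                                        order=1, mode="reflect").astype(np.float32)

    warped_mask = ndimage.affine_transform(mask.astype(np.float32), matrix, offset=offset,
                                           order=0, mode="constant", cval=0.0)
    return (
        GradientPair(warp_image(inputs.prewitt_dir), warp_image(inputs.sobel_dir)),
        (warped_mask > 0.5).astype(np.uint8),
    )


def split_dataset(items: Sequence, train_frac: float = 0.8, seed: int = 0):
    """Seeded shuffle then split at round(n * train_frac): disjoint and
    exhaustive (train, test) lists."""
    if len(items) == 0:
        raise InputError("cannot split an empty dataset")
    if not 0.0 < train_frac < 1.0:
        raise ConfigurationError(f"train_frac must be in (0, 1), got {train_frac}")
    n = len(items)
    order = np.random.default_rng(seed).permutation(n)
    cut = int(np.floor(n * train_frac + 0.5))
    train = [items[i] for i in order[:cut]]
    test = [items[i] for i in order[cut:]]
    return train, test
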