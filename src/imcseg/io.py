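"""Reading and writing the package's on-disk formats (PNG, CSV, NPZ)."""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InputError
from .preprocess import BoundaryAnnotation, GradientPair


def write_image_png(path: str | Path, pixels: np.ndarray) -> None:
    """Save a [0,1] float grid as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0).round().astype(np.uint8))


def read_image_png(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale PNG/TIFF as a [0,1] float32 grid."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    return (arr.astype(np.float32) / 255.0).astype(np.float32)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Save a {0,1} mask as 0/255 PNG."""
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise InputError("mask values must be 0/1")
    iio.imwrite(Path(path), (m.astype(np.uint8) * 255))


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def write_annotation_csv(path: str | Path, ann: BoundaryAnnotation) -> None:
    """CSV with header ``interface,column,row``; interface in {LI, MA}."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["interface", "column", "row"])
        for c, r in ann.li_points:
            w.writerow(["LI", c, r])
        for c, r in ann.ma_points:
            w.writerow(["MA", c, r])


def read_annotation_csv(path: str | Path) -> BoundaryAnnotation:
    li, ma = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ["interface", "column", "row"]:
            raise InputError(f"bad annotation header in {path}: {reader.fieldnames}")
        for row in reader:
            point = (float(row["column"]), float(row["row"]))
            if row["interface"] == "LI":
                li.append(point)
            elif row["interface"] == "MA":
                ma.append(point)
            else:
                raise InputError(f"unknown interface {row['interface']!r} in {path}")
    return BoundaryAnnotation(li_points=li, ma_points=ma)


def write_pair_npz(path: str | Path, pair: GradientPair) -> None:
    """Cache a gradient pair as an NPZ archive with two named planes."""
    np.savez(Path(path), prewitt_dir=pair.prewitt_dir, sobel_dir=pair.sobel_dir)


def read_pair_npz(path: str | Path) -> GradientPair:
    with np.load(Path(path)) as data:
        return GradientPair(prewitt_dir=data["prewitt_dir"], sobel_dir=data["sobel_dir"])
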