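"""Synthetic carotid-like B-mode phantoms with known band geometry.

Each phantom renders a dark lumen above a bright, slowly curving
double-line band (the LI/MA interfaces enclosing the intima-media
complex) on a tissue-level background, multiplied by gamma-distributed
speckle with unit mean. The true band thickness, the pixel mask and a
sparse expert-style boundary annotation are all exported, so every
downstream stage has ground truth without an external dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .preprocess import (
    DEFAULT_PIXEL_DENSITY,
    BoundaryAnnotation,
    UltrasoundImage,
    _round_half_up,
)

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "make_dataset"]

_BAND_LEVEL = 0.8      # pre-speckle intensity of the IMC band
_EDGE_GAIN = 1.2       # LI/MA interface rows rendered brighter than the band
_LUMEN_FRAC = 0.2      # lumen level as a fraction of the tissue background

# Fields of PhantomSpec that make_dataset may sample from intervals.
_RANGE_FIELDS = (
    "lumen_depth_frac",
    "thickness_mm",
    "curve_amplitude",
    "curve_period",
    "speckle_looks",
    "contrast",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise parameters of one phantom."""

    height: int = 64
    width: int = 128
    pixel_density: float = DEFAULT_PIXEL_DENSITY
    lumen_depth_frac: float = 0.45
    thickness_mm: float = 0.6
    curve_amplitude: float = 2.0
    curve_period: float = 97.0
    speckle_looks: float = 16.0
    contrast: float = 4.0
    seed: int = 0

    @property
    def thickness_px(self) -> float:
        return self.thickness_mm * self.pixel_density

    def validate(self) -> None:
        if self.height < 32:
            raise ConfigurationError(f"height must be >= 32, got {self.height}")
        if self.width < 64:
            raise ConfigurationError(f"width must be >= 64, got {self.width}")
        if not 0.2 < self.lumen_depth_frac < 0.8:
            raise ConfigurationError(
                f"lumen_depth_frac must be in (0.2, 0.8), got {self.lumen_depth_frac}")
        if self.thickness_px < 2:
            raise ConfigurationError(
                f"thickness_mm*pixel_density must be >= 2 px, got {self.thickness_px:.3f}")
        if self.curve_amplitude < 0:
            raise ConfigurationError("curve_amplitude must be nonnegative")
        if self.curve_amplitude + self.thickness_px / 2 >= 0.2 * self.height:
            raise ConfigurationError(
                "curve_amplitude + thickness_px/2 must stay below 0.2*height "
                f"({self.curve_amplitude} + {self.thickness_px / 2:.2f} vs {0.2 * self.height:.2f})")
        if self.curve_period <= 0:
            raise ConfigurationError("curve_period must be positive")
        if self.speckle_looks <= 0:
            raise ConfigurationError("speckle_looks must be positive")
        if not 1.0 < self.contrast <= 10.0:
            raise ConfigurationError(f"contrast must be in (1, 10], got {self.contrast}")
        if self.pixel_density <= 0:
            raise ConfigurationError("pixel_density must be positive")


@dataclass
class PhantomSample:
    """One generated phantom: image, mask, annotation and ground truth."""

    image: UltrasoundImage
    mask: np.ndarray
    annotation: BoundaryAnnotation
    true_thickness_px: float
    spec: PhantomSpec


def _band_rows(spec: PhantomSpec, phase: float):
    """Integer LI (top) and MA (bottom) rows per column, plus the smooth
    sub-pixel LI curve they were rounded from."""
    cols = np.arange(spec.width)
    centre = (spec.lumen_depth_frac * spec.height
              + spec.curve_amplitude * np.sin(2 * np.pi * cols / spec.curve_period + phase))
    run = int(_round_half_up(spec.thickness_px))
    li_f = centre - spec.thickness_px / 2.0
    li = _round_half_up(li_f).astype(int)
    ma = li + run - 1
    return li, ma, li_f, run


def noiseless_structure(spec: PhantomSpec, phase: float = 0.0) -> np.ndarray:
    """The speckle-free intensity field: tissue background, dark lumen above
    the band, bright band with 1-px brighter LI/MA edge rows."""
    li, ma, _, _ = _band_rows(spec, phase)
    tissue = _BAND_LEVEL / spec.contrast
    clean = np.full((spec.height, spec.width), tissue, dtype=np.float64)
    rows = np.arange(spec.height)[:, None]
    clean[rows < li[None, :]] = tissue * _LUMEN_FRAC
    band = (rows >= li[None, :]) & (rows <= ma[None, :])
    clean[band] = _BAND_LEVEL
    edges = (rows == li[None, :]) | (rows == ma[None, :])
    clean[edges] = min(1.0, _BAND_LEVEL * _EDGE_GAIN)
    return clean


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom; bit-identical for a fixed spec (incl. seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    li, ma, li_f, run = _band_rows(spec, phase)
    clean = noiseless_structure(spec, phase)
    speckle = rng.gamma(shape=spec.speckle_looks, scale=1.0 / spec.speckle_looks,
                        size=clean.shape)
    image = np.clip(clean * speckle, 0.0, 1.0).astype(np.float32)

    rows = np.arange(spec.height)[:, None]
    mask = ((rows >= li[None, :]) & (rows <= ma[None, :])).astype(np.uint8)

    # Sparse expert-style points with sub-pixel rows from the smooth
    # boundary curve: they round to the mask's LI/MA rows at the sampled
    # columns and interpolate the sinusoid accurately between them.
    n_pts = max(10, spec.width // 8)
    ann_cols = np.unique(np.linspace(0, spec.width - 1, n_pts).round().astype(int))
    annotation = BoundaryAnnotation(
        li_points=[(int(c), float(li_f[c])) for c in ann_cols],
        ma_points=[(int(c), float(li_f[c] + run - 1)) for c in ann_cols],
    )
    return PhantomSample(
        image=UltrasoundImage(image, spec.pixel_density),
        mask=mask,
        annotation=annotation,
        true_thickness_px=spec.thickness_px,
        spec=spec,
    )


def make_dataset(n: int, spec_ranges: dict[str, tuple[float, float]] | None = None,
                 seed: int = 0, base: PhantomSpec | None = None) -> list[PhantomSample]:
    """Generate ``n`` phantoms with per-sample parameters drawn uniformly
    from ``spec_ranges`` (field name -> (lo, hi) interval) on top of the
    ``base`` spec. Per-sample seeds derive deterministically from ``seed``.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    base = base if base is not None else PhantomSpec()
    spec_ranges = dict(spec_ranges or {})
    for name, (lo, hi) in spec_ranges.items():
        if name not in _RANGE_FIELDS:
            raise ConfigurationError(f"unknown or non-rangeable spec field {name!r}")
        if hi < lo:
            raise ConfigurationError(f"empty interval for {name!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in spec_ranges.items()}
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base, seed=child_seed, **draws)
        samples.append(generate_phantom(spec))
    return samples


def write_dataset(samples: list[PhantomSample], out_dir: str | Path) -> Path:
    """Write images/masks as PNG, annotations as CSV and a JSON manifest."""
    from . import io as iomod

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, s in enumerate(samples):
        stem = f"phantom_{i:04d}"
        iomod.write_image_png(out / "images" / f"{stem}.png", s.image.pixels)
        iomod.write_mask_png(out / "masks" / f"{stem}.png", s.mask)
        iomod.write_annotation_csv(out / "annotations" / f"{stem}.csv", s.annotation)
        manifest.append({
            "id": stem,
            "image": f"images/{stem}.png",
            "mask": f"masks/{stem}.png",
            "annotation": f"annotations/{stem}.csv",
            "seed": s.spec.seed,
            "true_thickness_px": s.true_thickness_px,
            "true_thickness_mm": s.spec.thickness_mm,
            "pixel_density": s.spec.pixel_density,
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
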