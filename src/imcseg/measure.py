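"""Intima-media thickness from binary band masks.

Thickness is the per-column foreground run length: the literal vertical
distance from the band's upper to its lower boundary. Per image the
maximum (default) or mean over nonempty columns is taken; the cohort
thickness is the arithmetic mean over images, converted to mm via the
pixel-density calibration (16.66 px/mm by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InputError, MeasurementError
from .preprocess import DEFAULT_PIXEL_DENSITY

__all__ = [
    "ExpertReference",
    "ThicknessReport",
    "column_runs",
    "image_thickness",
    "cohort_mean",
    "px_to_mm",
    "expert_error",
    "thickness_report",
]


@dataclass(frozen=True)
class ExpertReference:
    """A reference mean IMT reading (e.g. one expert at one time point)."""

    label: str
    mean_mm: float

    def validate(self) -> None:
        if self.mean_mm <= 0:
            raise ConfigurationError("reference mean IMT must be positive")


@dataclass
class ThicknessReport:
    per_image_px: list[float]
    mean_px: float
    mean_mm: float
    pixel_density: float
    mode: str = "max"
    expert_errors: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def to_csv(self, path: str | Path) -> None:
        lines = ["image,thickness_px,thickness_mm"]
        for i, px in enumerate(self.per_image_px):
            lines.append(f"{i},{px},{px / self.pixel_density}")
        lines.append(f"cohort_mean,{self.mean_px},{self.mean_mm}")
        Path(path).write_text("\n".join(lines) + "\n")


def column_runs(mask: np.ndarray) -> np.ndarray:
    """Longest contiguous vertical foreground run per column (0 if empty)."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise InputError("mask must be 2D")
    if not np.isin(m, (0, 1)).all():
        raise InputError("mask values must be 0/1")
    h, w = m.shape
    padded = np.zeros((h + 2, w), dtype=np.int8)
    padded[1:-1] = m
    runs = np.zeros(w, dtype=np.int64)
    diff = np.diff(padded, axis=0)
    for c in range(w):
        starts = np.flatnonzero(diff[:, c] == 1)
        if starts.size == 0:
            continue
        ends = np.flatnonzero(diff[:, c] == -1)
        runs[c] = int((ends - starts).max())
    return runs


def image_thickness(mask: np.ndarray, mode: str = "max") -> float:
    """Per-image thickness in pixels: max (default) or mean of the
    per-column run lengths over nonempty columns."""
    if mode not in ("max", "mean"):
        raise ConfigurationError(f"mode must be 'max' or 'mean', got {mode!r}")
    runs = column_runs(mask)
    nonempty = runs[runs > 0]
    if nonempty.size == 0:
        raise MeasurementError("no IMC detected: mask has no foreground")
    return float(nonempty.max()) if mode == "max" else float(nonempty.mean())


def cohort_mean(per_image_px) -> float:
    """Arithmetic mean thickness over images, in pixels."""
    values = list(per_image_px)
    if not values:
        raise InputError("cohort is empty")
    return float(np.mean(values))


def px_to_mm(px: float, density: float = DEFAULT_PIXEL_DENSITY) -> float:
    """Convert a pixel distance to mm with the scanner calibration."""
    if density <= 0:
        raise ConfigurationError(f"pixel density must be positive, got {density}")
    return px / density


def expert_error(measured_mm: float, ref: ExpertReference | float) -> float:
    """Absolute difference (mm) against a reference reading, rounded to
    2 decimals as conventionally reported."""
    ref_mm = ref.mean_mm if isinstance(ref, ExpertReference) else float(ref)
    if isinstance(ref, ExpertReference):
        ref.validate()
    return round(abs(measured_mm - ref_mm), 2)


def thickness_report(masks, density: float = DEFAULT_PIXEL_DENSITY, mode: str = "max",
                     experts: list[ExpertReference] | None = None) -> ThicknessReport:
    """Per-image thickness plus cohort mean (px and mm) and, optionally,
    the absolute error against each expert reference."""
    per_image = [image_thickness(m, mode=mode) for m in masks]
    mean_px = cohort_mean(per_image)
    mean_mm = px_to_mm(mean_px, density)
    errors = {}
    for ref in experts or []:
        errors[ref.label] = expert_error(mean_mm, ref)
    return ThicknessReport(per_image_px=per_image, mean_px=mean_px, mean_mm=mean_mm,
                           pixel_density=density, mode=mode, expert_errors=errors)
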