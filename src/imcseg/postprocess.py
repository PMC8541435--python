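"""Morphological refinement of predicted band masks.

The default chain is close (2, 30) -> open (2, 30) -> close (3, 30) with
flat rectangular structuring elements, sized (rows, columns): wide and
flat to match the horizontal band. Border convention: dilation pads with
background and erosion pads with foreground, so results equal those on an
infinitely padded canvas (dilation-neutral; closing stays extensive and
opening anti-extensive at image borders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError

__all__ = ["MorphStep", "DEFAULT_CHAIN", "morph_apply", "refine"]


@dataclass(frozen=True)
class MorphStep:
    op: str                      # "close" or "open"
    se_shape: tuple[int, int]    # (rows, columns) of the rectangular SE

    def validate(self) -> None:
        if self.op not in ("close", "open"):
            raise ConfigurationError(f"unknown morphological op {self.op!r}")
        h, w = self.se_shape
        if h < 1 or w < 1:
            raise ConfigurationError(f"structuring element must be >= 1x1, got {self.se_shape}")


DEFAULT_CHAIN: tuple[MorphStep, ...] = (
    MorphStep("close", (2, 30)),
    MorphStep("open", (2, 30)),
    MorphStep("close", (3, 30)),
)


def _check_mask(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise InputError("mask must be 2D")
    if not np.isin(m, (0, 1)).all():
        raise InputError("mask values must be 0/1")
    return m.astype(bool)


def _dilate(m: np.ndarray, se: np.ndarray) -> np.ndarray:
    return ndimage.binary_dilation(m, structure=se, border_value=0)


def _erode(m: np.ndarray, se: np.ndarray) -> np.ndarray:
    return ndimage.binary_erosion(m, structure=se, border_value=1)


def morph_apply(mask: np.ndarray, step: MorphStep) -> np.ndarray:
    """Binary closing (dilate-erode) or opening (erode-dilate) with a flat
    rectangular structuring element."""
    step.validate()
    m = _check_mask(mask)
    se_h, se_w = step.se_shape
    if se_h > m.shape[0] or se_w > m.shape[1]:
        raise ConfigurationError(
            f"structuring element {step.se_shape} larger than image {m.shape}")
    se = np.ones(step.se_shape, dtype=bool)
    if step.op == "close":
        out = _erode(_dilate(m, se), se)
    else:
        out = _dilate(_erode(m, se), se)
    return out.astype(np.uint8)


def refine(mask: np.ndarray, chain: tuple[MorphStep, ...] = DEFAULT_CHAIN,
           keep_largest: bool = False) -> np.ndarray:
    """Apply the morphological post-processing chain in order.

    ``keep_largest`` optionally retains only the largest connected
    component afterwards (off by default; not part of the standard chain).
    """
    out = np.asarray(mask)
    for step in chain:
        out = morph_apply(out, step)
    if keep_largest and out.any():
        labels, n = ndimage.label(out)
        if n > 1:
            sizes = ndimage.sum_labels(out, labels, index=range(1, n + 1))
            out = (labels == (int(np.argmax(sizes)) + 1)).astype(np.uint8)
    return out
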