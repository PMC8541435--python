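"""Shared fixtures. The expensive desk-scale training run is session-scoped
and shared by the network sanity tests and the end-to-end acceptance test."""

from __future__ import annotations

import numpy as np
import pytest

from imcseg import network, phantom, postprocess, preprocess
from imcseg.network import ModelConfig, binarize, build_model, predict, train
from imcseg.phantom import PhantomSpec
from imcseg.preprocess import AugmentConfig, make_pair, split_dataset


@pytest.fixture(scope="session")
def desk_run():
    """Train the desk-scale model on 30 phantoms (64x128, thickness
    0.4-1.0 mm) once per session and predict on the held-out split.

    Returns a dict with the untrained and trained predictions, refined
    masks, ground truth, true thicknesses and the loss history.
    """
    base = PhantomSpec(height=64, width=128, speckle_looks=16.0, curve_amplitude=2.0)
    samples = phantom.make_dataset(30, {"thickness_mm": (0.4, 1.0)}, seed=11, base=base)
    items = [(make_pair(s.image), s.mask, s.true_thickness_px) for s in samples]
    train_items, test_items = split_dataset(items, 0.8, seed=5)

    cfg = ModelConfig.desk_scale(seed=3)
    model = build_model(cfg)
    untrained = [binarize(predict(model, pair)) for pair, _, _ in test_items]
    history = train(model, [(p, m) for p, m, _ in train_items], cfg, AugmentConfig(seed=7))
    raw = [binarize(predict(model, pair)) for pair, _, _ in test_items]
    refined = [postprocess.refine(m) for m in raw]
    return {
        "cfg": cfg,
        "model": model,
        "history": history,
        "untrained": untrained,
        "raw": raw,
        "refined": refined,
        "gt": [m for _, m, _ in test_items],
        "true_px": [t for _, _, t in test_items],
        "n_train": len(train_items),
        "n_test": len(test_items),
    }


@pytest.fixture
def tiny_model_cfg():
    """A seconds-scale model config for contract tests."""
    return ModelConfig(input_shape=(32, 64), encoder_blocks=3, base_filters=4,
                       epochs=2, steps_per_epoch=2, batch_size=2,
                       learning_rate=1e-3, seed=0)


def band_mask(shape, top, bottom, col_lo=None, col_hi=None):
    """Horizontal band with foreground rows top..bottom inclusive."""
    m = np.zeros(shape, dtype=np.uint8)
    col_lo = 0 if col_lo is None else col_lo
    col_hi = shape[1] - 1 if col_hi is None else col_hi
    m[top : bottom + 1, col_lo : col_hi + 1] = 1
    return m
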