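"""The dual-encoder convolutional encoder-decoder segmenter.

Two weight-independent encoders (one per gradient-direction plane), each
a truncated VGG-style stack of conv+BN+PReLU blocks with 2x2 max pooling;
their bottleneck feature maps are concatenated channel-wise, reduced by a
1x1 convolution, and decoded by a mirrored stack of 2x upsampling and
conv+BN+PReLU blocks to per-pixel class probabilities via softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigurationError, InputError
from .preprocess import AugmentConfig, GradientPair, augment_pair

__all__ = [
    "ModelConfig",
    "DualEncoderModel",
    "build_model",
    "softmax_loss",
    "train",
    "predict",
    "binarize",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    Defaults follow the reference protocol: batch 8, 50 epochs, 10 steps
    per epoch, learning rate 1e-5, batch normalization on. The
    ``desk_scale`` preset shrinks the model and shortens training so the
    whole pipeline runs in minutes on one CPU.
    """

    input_shape: tuple[int, int] = (64, 128)
    num_classes: int = 2
    encoder_blocks: int = 4
    base_filters: int = 64
    fusion: str = "concat"
    batch_norm: bool = True
    activation: str = "prelu"
    learning_rate: float = 1e-5
    batch_size: int = 8
    epochs: int = 50
    steps_per_epoch: int = 10
    seed: int = 0

    @classmethod
    def desk_scale(cls, **overrides) -> "ModelConfig":
        base = dict(input_shape=(64, 128), encoder_blocks=3, base_filters=16,
                    epochs=15, learning_rate=1e-3)
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        h, w = self.input_shape
        div = 2 ** self.encoder_blocks
        if h % div or w % div:
            raise ConfigurationError(
                f"input shape {self.input_shape} not divisible by 2^{self.encoder_blocks}")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if not 3 <= self.encoder_blocks <= 5:
            raise ConfigurationError("encoder_blocks must be in 3..5")
        if self.base_filters < 1 or self.batch_size < 1 or self.steps_per_epoch < 1:
            raise ConfigurationError("counts must be positive")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be nonnegative")
        if self.fusion != "concat":
            raise ConfigurationError(f"unsupported fusion {self.fusion!r}")
        if self.activation != "prelu":
            raise ConfigurationError(f"unsupported activation {self.activation!r}")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")

    def block_filters(self, b: int) -> int:
        """Channel count of encoder block b (1-based), VGG-style doubling
        capped at 8x base."""
        return self.base_filters * 2 ** min(b - 1, 3)

    def block_convs(self, b: int) -> int:
        """VGG-19 style: 2 convs in blocks 1-2, 4 in deeper blocks."""
        return 2 if b <= 2 else 4


def _conv_bn_act(in_ch: int, out_ch: int, ksize: int, cfg: ModelConfig,
                 rng: np.random.Generator) -> list[nn.Layer]:
    layers: list[nn.Layer] = [nn.Conv2d(in_ch, out_ch, ksize, rng)]
    if cfg.batch_norm:
        layers.append(nn.BatchNorm2d(out_ch))
    layers.append(nn.PReLU(out_ch))
    return layers


class DualEncoderModel:
    """Two-input encoder / fused decoder network over numpy layers."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        b_last = cfg.encoder_blocks
        self.encoders = [self._build_encoder(cfg, rng) for _ in range(2)]
        c_last = cfg.block_filters(b_last)
        fuse: list[nn.Layer] = _conv_bn_act(2 * c_last, c_last, 1, cfg, rng)
        self.fuse = nn.Sequential(fuse)
        dec: list[nn.Layer] = []
        prev = c_last
        for b in range(b_last, 0, -1):
            dec.append(nn.Upsample2())
            ch = cfg.block_filters(b)
            for _ in range(cfg.block_convs(b)):
                dec.extend(_conv_bn_act(prev, ch, 3, cfg, rng))
                prev = ch
        dec.append(nn.Conv2d(prev, cfg.num_classes, 1, rng))
        self.decoder = nn.Sequential(dec)

    @staticmethod
    def _build_encoder(cfg: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
        layers: list[nn.Layer] = []
        prev = 1
        for b in range(1, cfg.encoder_blocks + 1):
            ch = cfg.block_filters(b)
            for _ in range(cfg.block_convs(b)):
                layers.extend(_conv_bn_act(prev, ch, 3, cfg, rng))
                prev = ch
            layers.append(nn.MaxPool2())
        return nn.Sequential(layers)

    # -- forward / backward ------------------------------------------------
    def forward(self, x1: np.ndarray, x2: np.ndarray, training: bool = False) -> np.ndarray:
        """x1, x2: (N, H, W, 1) gradient planes -> logits (N, H, W, k)."""
        h, w = self.cfg.input_shape
        if x1.shape[1:3] != (h, w) or x2.shape[1:3] != (h, w):
            raise InputError(f"inputs must be {self.cfg.input_shape}, got "
                             f"{x1.shape[1:3]} / {x2.shape[1:3]}")
        f1 = self.encoders[0].forward(x1, training)
        f2 = self.encoders[1].forward(x2, training)
        self._split = f1.shape[-1]
        fused = self.fuse.forward(np.concatenate([f1, f2], axis=-1), training)
        return self.decoder.forward(fused, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.decoder.backward(dlogits)
        dcat = self.fuse.backward(dfused)
        self.encoders[0].backward(np.ascontiguousarray(dcat[..., : self._split]))
        self.encoders[1].backward(np.ascontiguousarray(dcat[..., self._split :]))

    def _layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for enc in self.encoders:
            out.extend(enc.all_layers())
        out.extend(self.fuse.all_layers())
        out.extend(self.decoder.all_layers())
        return out

    def param_pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(p, g) for layer in self._layers()
                for p, g in zip(layer.params, layer.grads)]

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, layer in enumerate(self._layers()):
            for j, p in enumerate(layer.params):
                arrays[f"param_{i}_{j}"] = p
            if isinstance(layer, nn.BatchNorm2d):
                arrays[f"running_mean_{i}"] = layer.running_mean
                arrays[f"running_var_{i}"] = layer.running_var
        return arrays

    def load_state_arrays(self, arrays) -> None:
        for i, layer in enumerate(self._layers()):
            for j in range(len(layer.params)):
                layer.params[j][...] = arrays[f"param_{i}_{j}"]
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean[...] = arrays[f"running_mean_{i}"]
                layer.running_var[...] = arrays[f"running_var_{i}"]


def build_model(cfg: ModelConfig) -> DualEncoderModel:
    """Construct the network with deterministically seeded weights."""
    return DualEncoderModel(cfg)


def softmax_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Mean pixel-wise cross-entropy between one-hot labels ``y`` (N, k)
    and pre-softmax scores ``p`` (N, k).

    This is the standard negative log-likelihood, so the value is
    nonnegative and zero only in the perfect-prediction limit.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape or y.ndim != 2:
        raise InputError(f"y and p must both be (N, k), got {y.shape} vs {p.shape}")
    if not np.all(np.isfinite(p)):
        raise InputError("scores must be finite")
    if not np.allclose(y.sum(axis=1), 1.0):
        raise InputError("label rows must sum to 1 (one-hot)")
    z = p - p.max(axis=1, keepdims=True)
    log_softmax = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-(y * log_softmax).sum(axis=1).mean())


def _batch_arrays(samples, aug: AugmentConfig | None, draw_base: int):
    """Stack (GradientPair, mask) samples into model tensors, optionally
    applying one fresh augmentation draw per sample."""
    xs1, xs2, labs = [], [], []
    for i, (pair, mask) in enumerate(samples):
        if aug is not None:
            pair, mask = augment_pair(pair, mask, aug, draw_base + i)
        xs1.append(pair.prewitt_dir[..., None])
        xs2.append(pair.sobel_dir[..., None])
        labs.append(mask.astype(np.int64))
    return (np.stack(xs1).astype(np.float32), np.stack(xs2).astype(np.float32),
            np.stack(labs))


def train(model: DualEncoderModel, train_set, cfg: ModelConfig,
          aug: AugmentConfig | None = None) -> list[float]:
    """Seeded Adam training over freshly augmented batches.

    Each epoch consumes ``steps_per_epoch`` batches of ``batch_size``
    samples drawn (with replacement) from ``train_set``; every sample gets
    a fresh augmentation draw. Returns the per-epoch mean loss history.
    """
    cfg.validate()
    if len(train_set) == 0:
        raise InputError("train_set is empty")
    for pair, mask in train_set:
        if pair.shape != tuple(cfg.input_shape) or mask.shape != tuple(cfg.input_shape):
            raise InputError("sample shape does not match cfg.input_shape")
    rng = np.random.default_rng([cfg.seed, 1])
    opt = nn.Adam(model.param_pairs(), lr=cfg.learning_rate)
    history: list[float] = []
    draw = 0
    n = len(train_set)
    for _ in range(cfg.epochs):
        losses = []
        for _ in range(cfg.steps_per_epoch):
            idx = rng.integers(0, n, size=cfg.batch_size)
            x1, x2, labels = _batch_arrays([train_set[i] for i in idx], aug, draw)
            draw += cfg.batch_size
            logits = model.forward(x1, x2, training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def predict(model: DualEncoderModel, inputs: GradientPair) -> np.ndarray:
    """Forward pass -> per-pixel class probabilities, shape (H, W, k)."""
    if inputs.shape != tuple(model.cfg.input_shape):
        raise InputError(f"input shape {inputs.shape} != model shape {model.cfg.input_shape}")
    x1 = inputs.prewitt_dir[None, ..., None].astype(np.float32)
    x2 = inputs.sobel_dir[None, ..., None].astype(np.float32)
    logits = model.forward(x1, x2, training=False)[0]  # (H, W, k)
    z = logits.astype(np.float64) - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def binarize(pm: np.ndarray) -> np.ndarray:
    """Per-pixel argmax of a 2-class probability map; ties -> background."""
    pm = np.asarray(pm)
    if pm.ndim != 3 or pm.shape[-1] != 2:
        raise ConfigurationError(f"binarize needs a (H, W, 2) map, got {pm.shape}")
    return (pm[..., 1] > pm[..., 0]).astype(np.uint8)


def save_model(model: DualEncoderModel, path: str | Path) -> None:
    """Checkpoint weights + config as a single NPZ archive."""
    cfg_json = json.dumps(asdict(model.cfg))
    np.savez(Path(path), __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **model.state_arrays())


def load_model(path: str | Path) -> DualEncoderModel:
    with np.load(Path(path)) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
        model = DualEncoderModel(ModelConfig(**cfg_dict))
        model.load_state_arrays(data)
    return model
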