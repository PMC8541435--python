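"""Structured run configuration with YAML round-tripping and validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .network import ModelConfig
from .phantom import PhantomSpec, _RANGE_FIELDS
from .postprocess import DEFAULT_CHAIN, MorphStep
from .preprocess import DEFAULT_PIXEL_DENSITY, AugmentConfig

__all__ = ["RunConfig", "validate_config", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; defaults are the reference
    protocol scaled to a single desk CPU."""

    out_dir: str = "runs/latest"
    data_dir: str | None = None        # optional real-data manifest dir; None -> phantoms
    n_phantoms: int = 30
    phantom_ranges: dict = field(default_factory=lambda: {"thickness_mm": (0.4, 1.0)})
    phantom_base: dict = field(default_factory=dict)   # overrides for PhantomSpec fields
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig.desk_scale)
    morph_chain: tuple[MorphStep, ...] = DEFAULT_CHAIN
    pixel_density: float = DEFAULT_PIXEL_DENSITY
    train_frac: float = 0.8
    averaging: str = "macro"
    thickness_mode: str = "max"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"]["input_shape"] = list(self.model.input_shape)
        d["morph_chain"] = [{"op": s.op, "se_shape": list(s.se_shape)} for s in self.morph_chain]
        d["phantom_ranges"] = {k: list(v) for k, v in self.phantom_ranges.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d:
            m = dict(d["model"])
            if "input_shape" in m:
                m["input_shape"] = tuple(m["input_shape"])
            d["model"] = ModelConfig(**m)
        if "augment" in d:
            d["augment"] = AugmentConfig(**d["augment"])
        if "morph_chain" in d:
            d["morph_chain"] = tuple(
                MorphStep(op=s["op"], se_shape=tuple(s["se_shape"])) for s in d["morph_chain"])
        if "phantom_ranges" in d:
            d["phantom_ranges"] = {k: tuple(v) for k, v in d["phantom_ranges"].items()}
        return cls(**d)


def validate_config(cfg: RunConfig) -> list[str]:
    """Return every violated invariant as 'field.path: message'; the empty
    list means the config is runnable."""
    violations: list[str] = []
    if cfg.n_phantoms < 1 and cfg.data_dir is None:
        violations.append(f"n_phantoms: must be >= 1, got {cfg.n_phantoms}")
    if not 0.0 < cfg.train_frac < 1.0:
        violations.append(f"train_frac: must be in (0, 1), got {cfg.train_frac}")
    if cfg.pixel_density <= 0:
        violations.append(f"pixel_density: must be positive, got {cfg.pixel_density}")
    if cfg.averaging not in ("macro", "micro"):
        violations.append(f"averaging: must be macro or micro, got {cfg.averaging!r}")
    if cfg.thickness_mode not in ("max", "mean"):
        violations.append(f"thickness_mode: must be max or mean, got {cfg.thickness_mode!r}")
    if not isinstance(cfg.seed, int):
        violations.append("seed: must be an integer")
    if cfg.data_dir is not None and not Path(cfg.data_dir).exists():
        violations.append(f"data_dir: path does not exist: {cfg.data_dir}")
    try:
        cfg.model.validate()
    except ConfigurationError as exc:
        violations.append(f"model: {exc}")
    try:
        cfg.augment.validate()
    except ConfigurationError as exc:
        violations.append(f"augment: {exc}")
    for step in cfg.morph_chain:
        try:
            step.validate()
        except ConfigurationError as exc:
            violations.append(f"morph_chain: {exc}")
    for name, bounds in cfg.phantom_ranges.items():
        if name not in _RANGE_FIELDS:
            violations.append(f"phantom_ranges.{name}: not a rangeable PhantomSpec field")
        elif len(bounds) != 2 or bounds[1] < bounds[0]:
            violations.append(f"phantom_ranges.{name}: empty or malformed interval {bounds}")
    if cfg.data_dir is None:
        h, w = cfg.model.input_shape
        base = dict(height=h, width=w, pixel_density=cfg.pixel_density)
        base.update(cfg.phantom_base)
        try:
            # midpoint spec must satisfy the phantom invariants
            mids = {k: (v[0] + v[1]) / 2.0 for k, v in cfg.phantom_ranges.items()
                    if k in _RANGE_FIELDS}
            PhantomSpec(**base, **mids).validate()
        except (ConfigurationError, TypeError) as exc:
            violations.append(f"phantom_base: {exc}")
    return violations


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
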