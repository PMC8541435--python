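"""End-to-end orchestration: phantoms/ingest -> gradients -> split ->
train -> predict -> refine -> measure -> evaluate, with per-stage logging
and a fully reproducible run directory."""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import io as iomod
from . import measure as measuremod
from . import metrics as metricsmod
from . import network, phantom, postprocess, preprocess
from .config import RunConfig, save_config, validate_config
from .errors import ConfigurationError, MeasurementError

log = logging.getLogger("imcseg")

__all__ = ["run_pipeline"]


def _stage(name: str):
    """Log entry/exit and timing of one pipeline stage."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False
    return _Ctx()


def _child_seeds(master: int, n: int = 8) -> list[int]:
    """Derive independent per-stage seeds from the master seed."""
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n)]


def _load_real_dataset(data_dir: Path, density: float):
    """Read a phantom-format manifest of images + annotations."""
    manifest = json.loads((data_dir / "manifest.json").read_text())
    items = []
    for entry in manifest:
        pixels = iomod.read_image_png(data_dir / entry["image"])
        image = preprocess.UltrasoundImage(pixels, entry.get("pixel_density", density))
        ann = iomod.read_annotation_csv(data_dir / entry["annotation"])
        mask = preprocess.rasterize_mask(ann, image.shape)
        items.append({"id": entry["id"], "image": image, "mask": mask,
                      "true_thickness_px": entry.get("true_thickness_px")})
    return items


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline described by ``cfg``; returns the run
    directory containing config, manifest, logs and all reports."""
    violations = validate_config(cfg)
    if violations:
        raise ConfigurationError("invalid config: " + "; ".join(violations))

    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, run_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, run_dir: Path) -> Path:
    save_config(cfg, run_dir / "config.yaml")
    seed_phantom, seed_split, seed_model, seed_aug = _child_seeds(cfg.seed, 4)
    h, w = cfg.model.input_shape

    with _stage("data"):
        if cfg.data_dir is not None:
            items = _load_real_dataset(Path(cfg.data_dir), cfg.pixel_density)
        else:
            base = phantom.PhantomSpec(height=h, width=w, pixel_density=cfg.pixel_density,
                                       **cfg.phantom_base)
            samples = phantom.make_dataset(cfg.n_phantoms, cfg.phantom_ranges,
                                           seed=seed_phantom, base=base)
            items = [{"id": f"phantom_{i:04d}", "image": s.image, "mask": s.mask,
                      "true_thickness_px": s.true_thickness_px, "seed": s.spec.seed}
                     for i, s in enumerate(samples)]
        log.info("dataset: %d items", len(items))

    with _stage("preprocess"):
        for item in items:
            item["pair"] = preprocess.make_pair(item["image"])

    with _stage("split"):
        train_items, test_items = preprocess.split_dataset(items, cfg.train_frac, seed_split)
        log.info("split: %d train / %d test", len(train_items), len(test_items))

    with _stage("train"):
        model_cfg = replace(cfg.model, seed=seed_model)
        model = network.build_model(model_cfg)
        aug = replace(cfg.augment, seed=seed_aug)
        train_set = [(it["pair"], it["mask"]) for it in train_items]
        history = network.train(model, train_set, model_cfg, aug)
        network.save_model(model, run_dir / "model.npz")
        with open(run_dir / "history.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "loss"])
            for e, loss in enumerate(history, 1):
                writer.writerow([e, f"{loss:.6f}"])

    masks_dir = run_dir / "masks"
    masks_dir.mkdir(exist_ok=True)
    with _stage("predict+refine"):
        refined, gts = [], []
        for item in test_items:
            probs = network.predict(model, item["pair"])
            raw = network.binarize(probs)
            clean = postprocess.refine(raw, cfg.morph_chain)
            refined.append(clean)
            gts.append(item["mask"])
            iomod.write_mask_png(masks_dir / f"{item['id']}_pred.png", clean)
            iomod.write_mask_png(masks_dir / f"{item['id']}_gt.png", item["mask"])

    with _stage("measure"):
        per_image, skipped = [], []
        for item, mask in zip(test_items, refined):
            try:
                per_image.append((item["id"], measuremod.image_thickness(mask, cfg.thickness_mode)))
            except MeasurementError:
                skipped.append(item["id"])
                log.warning("measure: empty prediction for %s, excluded from cohort", item["id"])
        thickness = {
            "mode": cfg.thickness_mode,
            "pixel_density": cfg.pixel_density,
            "per_image_px": {k: v for k, v in per_image},
            "skipped_empty": skipped,
        }
        if per_image:
            mean_px = measuremod.cohort_mean([v for _, v in per_image])
            thickness["mean_px"] = mean_px
            thickness["mean_mm"] = measuremod.px_to_mm(mean_px, cfg.pixel_density)
        true_px = [it["true_thickness_px"] for it in test_items
                   if it.get("true_thickness_px") is not None]
        if true_px:
            thickness["true_mean_px"] = float(np.mean(true_px))
            thickness["true_mean_mm"] = measuremod.px_to_mm(float(np.mean(true_px)),
                                                            cfg.pixel_density)
        (run_dir / "thickness.json").write_text(json.dumps(thickness, indent=2))

    with _stage("evaluate"):
        reports = {avg: metricsmod.evaluate_set(refined, gts, averaging=avg)
                   for avg in ("macro", "micro")}
        payload = {avg: {k: getattr(rep, k)
                         for k in ("precision", "recall", "f1", "dice", "jaccard")}
                   for avg, rep in reports.items()}
        payload["headline"] = cfg.averaging
        payload["per_image"] = reports[cfg.averaging].per_image
        (run_dir / "metrics.json").write_text(json.dumps(payload, indent=2))

    manifest = {
        "seed": cfg.seed,
        "stage_seeds": {"phantom": seed_phantom, "split": seed_split,
                        "model": seed_model, "augment": seed_aug},
        "n_items": len(items),
        "train_ids": [it["id"] for it in train_items],
        "test_ids": [it["id"] for it in test_items],
        "items": [{k: it[k] for k in ("id", "true_thickness_px", "seed") if k in it}
                  for it in items],
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir
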