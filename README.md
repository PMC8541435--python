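# imcseg

Carotid intima-media complex (IMC) segmentation and intima-media
thickness (cIMT) measurement from B-mode ultrasound, with a synthetic
phantom generator so the whole pipeline is trainable and testable without
any external dataset.

The pipeline:

1. **phantom** — synthetic carotid-like images: a dark lumen above a
   bright, slowly curving double-line band of known thickness
   (0.4–1.0 mm by default at 16.66 px/mm), multiplied by gamma speckle;
   exports images, masks, sparse expert-style boundary points and a
   manifest.
2. **preprocess** — frame cropping, min–max normalization, Sobel and
   Prewitt gradient-direction planes (the model's dual input), mask
   rasterization from LI/MA boundary points, paired
   rotation/shift/zoom augmentation, seeded 80/20 splitting.
3. **network** — a dual-encoder convolutional encoder-decoder: two
   weight-independent VGG-style encoders (conv+BN+PReLU, 2×2 max-pool),
   channel-concatenation fusion with a 1×1 reduction, a mirrored
   upsampling decoder, softmax output. Implemented on a small numpy
   layer stack with manual backprop (no DL framework required) and
   trained with Adam; fully seeded and deterministic.
4. **postprocess** — morphological refinement of predicted masks:
   close (2,30) → open (2,30) → close (3,30) with rectangular
   structuring elements.
5. **measure** — per-column run-length thickness, per-image max/mean,
   cohort mean, px→mm conversion, absolute error against expert
   reference readings.
6. **metrics** — confusion counts, precision/recall/F1, Dice, Jaccard,
   with macro (per-image mean) and micro (pooled counts) averaging.

## CLI

```bash
imcseg init-config --out config.yaml       # default desk-scale config
imcseg run --config config.yaml --out runs/demo --seed 1
```

`imcseg run` executes the full pipeline (phantoms → gradients → split →
train → predict → refine → measure → evaluate) and writes `config.yaml`,
`manifest.json`, `history.csv`, `metrics.json`, `thickness.json`,
predicted/ground-truth mask PNGs and a per-stage log into the run
directory. A rerun with the same config reproduces the artifacts.

Individual stages are also exposed:

```bash
imcseg phantom --n 30 --out data/ --seed 7
imcseg preprocess --images-dir data/images --annotations-dir data/annotations --out prep/
imcseg train --config config.yaml --data prep/ --out model/
imcseg predict --weights model/model.npz --in prep/pairs --out-masks pred/
imcseg refine --in pred/ --out refined/
imcseg measure --masks-dir refined/ --density 16.66 --mode max
imcseg evaluate --pred-dir refined/ --gt-dir prep/masks --averaging macro
```

## Conventions

Images are 2D float32 grids in [0,1], row 0 at the top, 0-based indices;
annotation points are `(column, row)` pairs with strictly increasing
columns per interface; masks are `{0,1}` with 1 = IMC foreground;
structuring elements are sized `(rows, columns)`; pixel density defaults
to 16.66 px/mm.
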