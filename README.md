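# tileseg

Tile-based multi-label semantic segmentation of wide, panoramic-style
grayscale images, built to study one question: does training a segmentation
CNN on equally spaced rectangular crops (tiles) of a large image — instead
of the downscaled full image — improve pixelwise performance, especially for
small, infrequent structures?

Because the radiograph dataset motivating this design is private, the
package ships a seeded synthetic generator that reproduces the *structure*
that matters: a wide (~2:1) scene of two dental arches with four restoration
classes of very different sizes and frequencies (fillings, crowns,
root-canal fillings, implants), annotated with exact, possibly overlapping
4-channel binary masks.

Everything — including the U-Net-style encoder–decoder, Adam, instance
normalization and the soft-dice backward pass — is implemented in NumPy, so
the package has no deep-learning-framework dependency and runs anywhere
NumPy/SciPy do.

## Components

| module | what it does |
| --- | --- |
| `tileseg.synthetic` | seeded scene generator, PNG dataset writer/loader, class-frequency reports |
| `tileseg.tiling` | tile-count → rows×cols grid, exact partition into half-open pixel rectangles, extract/stitch (bit-exact round trip) |
| `tileseg.nn` / `tileseg.model` | NumPy layers with hand-written backprop; compact U-Net with skip connections and a per-channel sigmoid head (multi-label, not softmax) |
| `tileseg.training` | soft-dice loss, paired image/mask augmentation, plateau LR reduction + two-stage early stopping |
| `tileseg.metrics` | pixelwise TP/FP/FN per channel, micro-pooled F1 / sensitivity / IoU, tile-predict-stitch evaluation on full images |
| `tileseg.experiment` | five-times-repeated three-fold cross-validation plan, tile-count sweep, Student-t 95% CIs, convergence table, CSV outputs |

## CLI

```bash
# generate 90 synthetic scenes
tileseg synth --n 90 --seed 0 --out data/

# per-channel object size / frequency statistics
tileseg stats --data data/

# train one model on a single split, 8 tiles per image
tileseg train --data data/ --tiles 8 --seed 0 --out model.npz

# full 5x3 cross-validation for one tile count
tileseg cv --data data/ --tiles 8 --seed 0 --out runs/cv8/

# tile-count sweep (results.csv, convergence.csv, summary.csv)
tileseg experiment --data data/ --tiles 1,4,8 --seed 0 \
    --repetitions 1 --folds 3 --test-groups 5 --out runs/sweep/

# summarize an existing results CSV
tileseg report --results runs/sweep/results.csv \
    --convergence runs/sweep/convergence.csv
```

An optional YAML config (`--config`) can override any parameter group:

```yaml
generator:            # GenConfig fields, or just height/width to rescale
  height: 128
  width: 256
model:                # ModelConfig
  input_size: 64
  depth: 3
  base_width: 4
training:             # TrainConfig
  initial_lr: 1.0e-3
  reduced_lr: 1.0e-4
  batch_size: 8
  patience: 5
  max_epochs: 25
```

## Results schema

`results.csv`: one row per (tile_count, repetition, fold, channel∪overall)
with `f1, sensitivity, iou, tp, fp, fn`. `convergence.csv`: epochs-to-stop
per trained model. `summary.csv`: mean and 95% CI per (tile_count, channel,
metric) plus mean epochs-to-stop.

Conventions worth knowing: channels are ordered
`filling, crown, root_canal, implant` (part of the file-format contract);
masks are non-exclusive; metrics pool pixel counts across images (micro) and
"overall" additionally pools the four channels; 0/0 metrics are 1.0 by
convention; the binarization threshold is 0.5.

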