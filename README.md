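# artscore

Automatic real-time scoring of protein-crystallization well images.

High-throughput crystallization platforms image hundreds of thousands
of experiment drops, and someone has to look at every image to spot
crystals.  This package implements an automatic scorer for such well
images: a U-Net locates the protein droplet inside the well, a
convolutional classifier scores chop-sized windows slid across the
droplet, and the per-chop outcomes are aggregated by class priority
into one well score — the **ARTscore** — rendered as colored evidence
frames on the image.  It is written for structural-biology groups
running crystallization screens and for anyone studying patch-based
whole-image classification.

## The method in brief

Wells are scored into 13 classes with score numbers
23/22/21 (crystal), 13/12/11 (precipitate), 34/33/32/31 (other),
1/2 (clear), plus a preprocessing-only class *rim* for droplet-edge
chops (score 1, same as clear), optionally merged to five classes.
Given per-chop class probabilities *p*, the well score is

> the highest-priority class among chops with *p* ≥ *c*,

with priority order 23 > 22 > 21 > 13 > 12 > 11 > 34 > 33 > 32 > 31 >
1 > 2, rim reported as clear, and *unscored* if no chop reaches the
confidence threshold *c* (default 0.85; the sliding step is
*s* = 50 px).  Four classifier architectures are provided, built from
scratch on a small numpy autodiff engine: AlexNet (8 weight layers),
VGG-16 (16), ResNet-50 (50) and SqueezeNet (18, fire modules;
1 248 424 parameters in the canonical 1000-class configuration).

Around the scorer the package provides: minimal-overlap and sliding
chop layouts; training-set construction with contour filtering, UV-mate
vetting of crystal chops (salt does not fluoresce) and rim-chop
extraction; a synthetic well generator with exact ground truth;
success-rate evaluation against human scores (frequency-weighted group
means); and a local batch pipeline (zip work units → CSV → score table
with a manual-scores-are-never-overwritten import policy).

## Worked example

```python
from artscore import (full_scheme, merged_scheme, build_architecture, ArchSpec,
                      count_weight_layers, count_parameters, smallest_overlap_grid)
from artscore.synthgen import scene_for_class, generate_well
from artscore.scoring import OracleChopClassifier, score_well

for arch in ("alexnet", "vgg16", "resnet50", "squeezenet"):
    m = build_architecture(ArchSpec(arch, num_classes=13))
    print(f"{arch:10s} weight layers {count_weight_layers(m):2d}   "
          f"parameters {count_parameters(m):>11,}")

grid = smallest_overlap_grid(2056, 2452, 256, 256)
print(f"full-frame grid: {len(grid)} chops "
      f"({len(grid.y_starts)} x {len(grid.x_starts)})")

scheme = merged_scheme()
spec = scene_for_class(scheme.by_name("crystal"), 384, 384, seed=11)
well = generate_well(spec, scheme=scheme)
ws = score_well(
    well.visible, well.uv,
    lambda image: well.droplet_mask.astype(float),   # oracle segmenter
    OracleChopClassifier(spec, scheme),              # ground-truth classifier
    scheme, s=32, c=0.85, chop_size=96, well_id="demo",
)
print(f"well {ws.well_id}: score {ws.score_no} ({ws.class_def.name}), "
      f"supporting probability {ws.probability:.2f}, "
      f"{len(ws.top_chops)} evidence chops")
```

prints

```
alexnet    weight layers  8   parameters  57,057,101
vgg16      weight layers 16   parameters 134,313,805
resnet50   weight layers 50   parameters  23,561,229
squeezenet weight layers 18   parameters     742,093
full-frame grid: 90 chops (9 x 10)
well demo: score 23 (crystal), supporting probability 0.99, 5 evidence chops
```

The layer counts are the architectures' serial depths (parallel
branches count once); parameters here are for 13-class heads, so
AlexNet/VGG differ slightly from their 1000-class ImageNet figures.  A
nominal 2056 × 2452 well image needs 90 chops of 256² for a minimal
covering with near-equal overlaps.  The demo well is scored with
ground-truth mocks in place of trained models, which is how the
aggregation and rendering stages are tested; `DropletSegmenter.fit`
and `ChopClassifier.fit` (sklearn-style estimators) train the real
models, and `ws.annotated_image` holds the rendered evidence frames.

Trained-model workflow from the shell:

```sh
artscore dropseg train --n-wells 20 --epochs 25 --out unet.h5
artscore nets train --arch squeezenet --width 0.25 --out clf.h5
artscore run --image well.png --seg-model unet.h5 --model clf.h5 \
             --step 50 --threshold 0.85 --out-csv scores.csv
artscore pipeline import --csv scores.csv --db scores.sqlite
```

## Layout

```
src/artscore/classes.py    class scheme, groups, priority order
src/artscore/tiling.py     smallest-overlap and sliding chop grids
src/artscore/synthgen.py   synthetic wells + exact ground truth
src/artscore/dropseg.py    U-Net droplet segmentation (DropletSegmenter)
src/artscore/chopset.py    contour/UV filters, rim class, record packing
src/artscore/nets.py       the four CNNs, audits, training (ChopClassifier)
src/artscore/nn/           numpy reverse-mode autodiff engine
src/artscore/scoring.py    sliding sweep, priority aggregation, rendering
src/artscore/evalkit.py    success tables, weighted means, throughput
src/artscore/pipeline.py   zip work units, CSV finalizer, score import
src/artscore/cli.py        `artscore` command-line interface
docs/methods.md            models, parameters, design choices, limits
```
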