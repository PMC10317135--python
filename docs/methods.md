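# Methods

This package re-creates, at desk scale, an automatic real-time scoring
process for protein-crystallization well images: locate the droplet,
cut the droplet image into classifier-sized chops, classify each chop,
and aggregate the per-chop outcomes into one well score with rendered
evidence.  This note documents the models, the parameters that matter,
the synthetic data the pipeline is validated on, and the numerical and
design choices a maintainer would want to know.

## The scoring model

**Class scheme.** Wells are scored into 13 classes: three crystal
classes (harvestable 23, bad form 22, overnucleated 21), three
precipitate classes (13, 12, 11), four "other" classes (null
experiment 34, other 33, spherolites 32, phase separation 31) and two
clear classes (clear 1, clear-with-other-features 2), plus the
preprocessing-only class *rim* (droplet-edge chops from clear drops,
sharing score number 1 with clear).  Classes are totally ordered by
priority — crystals highest, then precipitate, then other, then clear —
and collapse into those four groups for evaluation.  A merged 5-class
scheme (crystal / precipitate / other / clear / rim) is also supported.
Two ordering details are deliberate design choices: all precipitate
classes rank above all "other" classes, and plain clear (1) ranks above
clear-with-other-features (2), both following the scheme's table order
rather than numeric score order.

**Aggregation.** Each chop classification carries a probability.  Among
chops whose probability reaches the confidence threshold *c* (default
0.85), the highest-priority class wins the well.  A rim win is reported
as clear — rim exists only to stop droplet-edge arcs being read as
crystals, never to label a well.  If no chop reaches *c* the well is
*unscored* rather than guessed; a forced "clear" would create silent
false negatives for the screening use case.  Aggregation is monotone in
*c*: raising the threshold can only move a well to a lower-priority
class or to unscored.

**Sliding sweep.** The scoring program crops the well image to the
droplet bounding box and slides a 256-px chop in steps of *s* = 50 px
(both defaults exposed); the top-*n* (default 5, a package choice)
chops are rendered as 3-px colored frames — red crystal, blue
precipitate, magenta other, gray clear, white rim — plus an image
border tinted with the winning group's color.

## Chop layouts

Two layouts cover a H×W image with fixed c×c chops:

* **Smallest-overlap grid** (training-set preparation): per axis,
  k = ⌈L/c⌉ chops with start positions round(i·(L−c)/(k−1)), so the
  first chop starts at 0, the last ends at L, and consecutive overlaps
  differ by at most one pixel.  k is provably minimal (k−1 chops cover
  at most (k−1)·c < L pixels).  When c divides L the grid has zero
  overlap.  The acceptance suite verifies coverage, minimality and
  ±1-px overlap spread exhaustively for every 1 ≤ c ≤ L ≤ 600.
* **Sliding grid** (scoring): positions 0, s, 2s, …, with a final
  clamped position at L−c so the far border is always covered.

Coordinates are 0-based, half-open, origin top-left, (row, col) =
(y, x).

## Droplet segmentation

A U-Net — an encoder of paired 3×3 convolutions + ReLU with 2×2 max
pooling, filters doubling per level, mirrored by a decoder of 2×2
transposed convolutions with skip concatenations — produces a per-pixel
droplet probability (sigmoid head).  Default architecture: depth 4,
base 16 filters (the original process does not document its
configuration; tests use depth 2–3 with 4–8 filters).  Training is Adam
on pixelwise binary cross-entropy; the loss choice is a package choice,
as is the 0.5 probability threshold.  At inference the largest
connected component of the thresholded map is kept, and its tight
bounding box is padded to at least one chop per side.  "No pixel above
threshold" is reported as *droplet not found* (the well is then
unscored), not as an error.  Models round-trip through HDF5 with
bitwise-identical predictions.

Where the original process used 214 hand-annotated masks, this package
trains on the synthetic generator's exact masks — the learning task is
unchanged, the annotation effort is removed.

## Training-set construction

Chops inherit their well's human score, filtered to keep labels honest:

* **Crystal chops (21–23)** must show contour structure in both the
  visible chop and its UV mate.  Protein crystals fluoresce under UV;
  salt crystals do not, so salt wells are filtered out here.  A missing
  UV mate on a crystal chop is an error by default
  (`FilterConfig.require_uv=False` relaxes this, mirroring archives
  where only part of the data has UV pairs).
* **Precipitate (11–13) and other (31–34) chops** must exceed a contour
  threshold, so featureless regions of such wells are not mislabeled.
* **Clear chops** are always accepted; border chops of clear wells with
  contour structure become the *rim* class.

The contour measure is the total marching-squares iso-contour polyline
length after Gaussian smoothing (σ = 1).  By default the measure probes
levels mean ± 0.1 and takes the larger total: the 0.1 offset keeps the
level out of the sensor-noise band, and probing both sides treats
bright and dark structure symmetrically (crystals and precipitate are
usually darker than the drop).  Thresholds default to 40 px at the
256-px reference chop and scale linearly with chop size; all are
exposed in `FilterConfig`.  For every threshold the accepted set is
non-increasing in the threshold.  An optional
`border_threshold_boost` reproduces the earlier, abandoned idea of
stricter thresholds for border chops (off by default — the rim class
superseded it).

Accepted chops are packed into a small custom record file (magic,
version, count, then length-prefixed 8-bit PNG bytes + score + rim flag
+ well id) with a CSV manifest; records round-trip exactly.

## Classifier architectures

Four canonical CNNs are built from scratch: AlexNet (8 weight layers),
VGG-16 (16), ResNet-50 (50, bottleneck blocks with identity/projection
shortcuts) and SqueezeNet (18, fire modules: a 1×1 squeeze feeding
parallel 1×1 and 3×3 expands).  A *weight layer* is a convolutional or
fully connected layer; parallel branches at one depth (fire expands,
residual shortcuts) count once, i.e. a block's depth is the maximum
over its branches.  The audit is invariant to class count and width.

Grayscale chops are replicated to three channels so the canonical stems
apply unchanged; inputs of 256² are accepted by adaptive average
pooling before the dense heads (AlexNet to 6×6, VGG to 7×7), which also
keeps the published parameter counts exact: SqueezeNet at 1000 classes
counts 1 248 424 trainable parameters (1.2 M at two significant
figures) and single-stream AlexNet 61 100 840 (≈ 6.1 × 10⁷).  One
deviation from the strictest canon: ResNet-50 convolutions keep their
biases although batch normalization follows (25 583 592 vs 25 557 032
parameters); layer count and behavior are unaffected.

A `width_multiplier` in (0, 1] scales every channel count (and the
dense hidden widths) so the networks train on a CPU; audits hold at
every width.  Inputs are standardized with fixed constants
((x − 0.5)/0.25) — without this the optimizer stalls at chance on raw
[0, 1] images.

**Training** is SGD with momentum 0.9 under a stepwise schedule: start
at 10⁻², divide by 10 whenever the validation loss stagnates for 3
epochs, floor at 10⁻⁵ (the published schedule prints start/end rates
only; these defaults are package choices).  The report carries
per-epoch train/validation accuracy, top-5 accuracy, loss, learning
rate and wall time.  Training is deterministic per seed on one machine.

**Compute backend.** No deep-learning framework is assumed: the
package carries a small reverse-mode autodiff engine (`artscore.nn`)
with im2col convolution, transposed convolution, max/adaptive-average
pooling, batch normalization, dropout and the usual losses.  Gradients
are property-tested against central-difference numerical
differentiation at float64 (tolerance 10⁻⁵); training runs in float32
(still deterministic per seed).  Checkpoints are HDF5 (architecture
config + named parameters) and round-trip bitwise.

## Synthetic wells

The generator emulates the imaging output the pipeline consumes:
a grayscale well (nominally 2452 × 2056 px, freely scalable) containing
a circular droplet (radius 40 % of the short side by default) with a
dark rim ring (width 2 % of the short side), plus planted objects, and
a paired UV image in which protein crystals fluoresce (+0.55 over a
0.05–0.10 background) while salt crystals do not.  Gaussian pixel noise
(σ = 0.02) is seeded per scene; every rendering is deterministic from
the scene description.

Object recipes per class: harvestable crystal = one convex polygon
(3–8 vertices, jittered evenly spaced angles, so never degenerate) with
straight high-contrast edges; bad form = concave irregular polygon;
overnucleated = 8–12 small polygons; precipitate = blurred Bernoulli
speckle at densities 0.45/0.22/0.10 for scores 13/12/11; null
experiment = dried drop (no ring, mottled interior); other = irregular
dark blob; spherolites = radial-gradient disc; phase separation =
smooth low-contrast disc; clear-with-other-features = a thin fiber or
scratch.

Ground truth is analytic: each object has a deterministic support mask,
and a chop's label is the highest-priority object with at least
`min_overlap_px` support pixels inside the window (default 200 px at a
256-px chop, scaled with chop area — a package choice that prevents
labeling by one-pixel grazes), falling back to rim if the window meets
the rim annulus, else clear.  The balanced chop-set generator cuts each
labeled chop from its own small well and verifies the label against
this rule.

**What passing tests do and do not show.**  The synthetic classes are
geometrically idealized and nearly separable; no focus stacks, plate
mosaics, lighting gradients, condensation, skins, or inter-rater label
noise are modeled.  Tests on these data validate the machinery — the
layouts, filters, training loop, aggregation and policies — not
real-image accuracy.  The published accuracies of the original process
depend on a proprietary multi-year image archive and are out of reach
here by design; the evaluation kit reproduces the *semantics* of that
comparison (4-group success rates, frequency-weighted mean), not its
numbers.

## Evaluation and throughput

`success_table` collapses automatic and human scores to the four groups
and reports per-group success rates (matches / human-scored wells;
empty groups are omitted) and their frequency-weighted mean.  Unscored
automatic wells count as mismatches — the conservative reading.
`parallelization_required(t, interval)` is the plain ratio t/interval
against the imaging cadence (16.25 s per well standard, 5.19 s at
maximum plate load); callers round up to schedule workers.

## Batch pipeline

The production data flow is mirrored locally and synchronously: images
are packed into zip work units (lossless round-trip), results are
finalized into CSV (one row per well, UNSCORED rows kept, append-safe),
and the CSV is imported into an embedded sqlite score table.  Import
policy: an automatic record is inserted only where no manual record
exists for the same (well, inspection); manual records are never
modified regardless of date — both ratings are kept side by side, and
automatic records carry the inspection time as their score time, so
any later manual rating is unambiguously newer.  Imports are
idempotent; malformed rows are rejected, logged and skipped.

## Problem sizes used in the test suite

Chosen so the whole suite runs comfortably on one CPU core: synthetic
wells of 96–384 px, 64-px chops, width-0.25 SqueezeNet for the learning
check (2000 chops, 15 epochs, three seeds plus a label-shuffled
control), a depth-2 base-8 U-Net for segmentation recovery (20 training
and 10 held-out 96-px wells, 25 epochs), 100 wells for the end-to-end
mock, and exhaustive geometry sweeps up to length 600.

## Known limitations

* Drop realism is intentionally minimal (see above); thresholds tuned
  on synthetic contrast will need re-tuning on real archives.
* The smallest-overlap start positions are a reconstruction (rounded
  linear interpolation); an implementation using a different rounding
  convention could differ by ±1 px while satisfying the same coverage
  and minimality properties.
* Multi-droplet wells are reduced to the largest connected component.
* The embedded score store is single-user sqlite; no scheduler,
  validator or distributed workers are provided — archives are
  processed in order by a local runner.
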