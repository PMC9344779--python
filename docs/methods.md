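# Methods

## Problem and scope

Early oral-cancer screening by Papanicolaou-stained liquid-based cytology
depends on finding the nuclei of blue-stained (basal-lineage) cells: as
cellular atypia increases, so does the nucleus-to-cytoplasm (N/C) ratio, and
basal cells are the ones whose dysplastic change matters diagnostically.
`cytodetect` implements and compares two automatic nucleus-detection
strategies on synthetic cytology fields with exact ground truth:

1. **Sliding-window method (SWM).** The field is tiled into 96 × 96 px
   windows; a convolutional classifier decides per window whether it holds a
   blue-stained nucleus.
2. **Instance-level detection.** A detector proposes candidate regions in
   the whole field and returns one scored mask per nucleus.

Both are scored by a four-criterion matched-region protocol (below).

## The synthetic-data generator

No public corpus of annotated oral cytopreparations exists, so the package
generates its own fields with known per-instance truth.

A field (default 1024 × 1280 px, the nominal camera format; examples and
tests use smaller multiples of 96 px) is a pale background on which cells are
placed by rejection sampling. Each cell is a rotated elliptical nucleus
inside a concentric cytoplasm ellipse whose area is `nucleus_area /
nc_ratio`, with `nc_ratio ~ U(0.2, 0.6)`. By default cell footprints are
pairwise disjoint (`overlap_fraction = 0`), reflecting the sparseness of
liquid-based preparations; overlap is available as a stress knob.

Colors are synthesised in HSV and converted to RGB:

| element          | hue            | saturation  | value       |
|------------------|----------------|-------------|-------------|
| background       | 0.12           | 0.04        | 0.94        |
| blue nucleus     | U(0.58, 0.68)  | U(0.60, 0.80) | U(0.25, 0.42) |
| blue cytoplasm   | same as nucleus| U(0.15, 0.30) | U(0.65, 0.80) |
| red nucleus      | U(0.01, 0.08)  | U(0.60, 0.80) | U(0.30, 0.45) |
| red cytoplasm    | same as nucleus| U(0.15, 0.30) | U(0.70, 0.85) |
| debris           | U(0.20, 0.45)  | U(0.10, 0.35) | U(0.50, 0.75) |

The blue band `[0.55, 0.72]` and the red/orange band `[0, 0.12] ∪ [0.9, 1]`
make "blue-stained" a testable hue predicate. Stain hue and cell density are
not quantified anywhere for real material; these are the package's own
calibration, chosen once to look like Papanicolaou-stained fields and to
keep the two lineages separable by hue. Default density (4 blue + 3 red
cells per small field, ~3–4 blue nuclei per evaluation image) matches the
order of magnitude of the evaluation material the comparison protocol was
designed for. Nucleus semi-axes default to 12–24 px (40× objective scale);
debris is Poisson-placed at 5 blobs per megapixel (clean corpus) or 30
(noisy corpus); additive Gaussian pixel noise has σ = 0.01 of full scale
(clean) or 0.05 (noisy).

Generation is a pure function of `(config, seed)`: the same inputs give
bit-identical images and masks.

**What the generator does not model:** chromatin and nucleolus texture,
anti-aliased or blurred cell borders, staining gradients within a cell,
overlapping cell clusters (unless asked for), scanner artifacts, and
out-of-focus fields. Tests passing on this material show that the
*machinery* — labelling rules, training loops, matching and metric
arithmetic — is correct and that the methods behave in the documented
directions under controlled difficulty; they do not certify accuracy on
clinical images.

## Sliding-window dataset rules

* Tiling: windows of 96 px at stride 96 (non-overlapping grid); partial edge
  windows are dropped rather than padded, because the classifier has a fixed
  input size and padding would inject synthetic borders. Overlapping strides
  are supported as an option.
* Positive label: a window is a "nucleus" window iff some **blue-lineage**
  instance has **strictly more than half of its total mask area** inside the
  window. Exactly 50 % does not qualify. Red-lineage nuclei never produce a
  positive. The fraction is of the nucleus, not of the window: that is the
  natural reading of "containing more than half of the cell nucleus", and it
  makes the rule independent of nucleus size.
* Balance: datasets are assembled with equal per-class counts by
  construction (the reference total of 788 with a 591/197 split is consistent
  with balance but the per-class composition is not stated; imbalance is
  configurable through `n_per_class`).
* Split: stratified by label. The total training count is
  `floor(train_fraction · n)` and is apportioned across labels by largest
  remainder, so 788 balanced windows at 3 : 1 split exactly 591/197 while
  per-label fractions deviate from the target by less than one sample.
  (A plain per-label floor would give 590/198 for balanced classes.)

## The patch classifier

A from-scratch NumPy CNN (`cytodetect._nn`): im2col 3 × 3 stride-1 "same"
convolutions, 2 × 2 max-pooling, ReLU or sigmoid activations, inverted
dropout, affine layers and a softmax output, trained by minimising
categorical cross-entropy with the Adam update rule (lr 1e-3, β₁ 0.9,
β₂ 0.999 — standard defaults, no schedule). Training is bit-deterministic
under `learning_seed`.

**Layer counting.** Architecture depth is reported by counting every
convolution, pooling, activation, dropout and affine layer plus the output
softmax; reshapes are free. The two stock depths:

* **18 layers**: 4 × (conv → act → pool) = 12, then dropout → affine(1152→64)
  → act → dropout → affine(64→2) → softmax = 6. Spatial path
  96→48→24→12→6; channels 3→8→16→32→32.
* **24 layers**: as above plus 3 × (conv → act) at 6 × 6 resolution before
  the head.

Filter counts (8/16/32), kernel size (3 × 3), pooling type (max) and dropout
placement (before each affine layer) are the package's own choices — the
task is colour-dominated, so small filter banks suffice and keep CPU
training in seconds per epoch. Batch size defaults to 32.

**Configuration grid.** The default grid is the nine documented
configurations (ReLU/sigmoid × 5/20/50 epochs × 18/24 layers × dropout
0.25/0.5). A run is flagged *overlearned* when train accuracy exceeds test
accuracy by more than `overfit_gap = 0.05` — a gap that reproduces the
reference verdicts (a 99.8 %/89.1 % run is overlearned; 95.6 %/93.1 % is
not). Non-overlearned runs are ranked by test accuracy. Accuracy is plain
per-window accuracy.

**Overlay.** Scored windows tint the image red when p > 0.9 and yellow when
p > 0.5 (both strict: p = 0.9 is yellow, p = 0.5 is untinted), alpha 0.35.

## The instance backend

No deep detection framework is part of this package's dependency set; the
trainable instance backend is a deliberately compact **propose-and-score
segmenter** that follows the same contract as two-stage instance
segmentation (feature extraction → candidate regions → per-region score and
mask):

1. per-pixel features: RGB, HSV and a 5 × 5 local RGB mean (9 channels);
2. a per-pixel two-class softmax classifier trained with Adam (lr 0.05,
   batch 1024) on class-balanced pixel samples (≤ 4000 per class per image)
   from image + mask teacher pairs; images without masks act as pure
   negatives; the last 20 % of pairs are held out for a validation loss;
3. "nucleusness" probability map → threshold 0.5 → 4-connected components
   ≥ 20 px become candidate instances;
4. each candidate is scored by its mean probability, filtered at
   `score_threshold` (default 0.5), and pruned by greedy box-IoU
   non-maximum suppression (default 0.5).

This backend is linear per pixel, so it is exactly trainable on a CPU in
under a second and fully deterministic; it is *not* a Mask-RCNN and makes no
claim to its capacity. On the synthetic corpus — where lineage is encoded in
colour — it is an appropriate instance detector, and its per-epoch
train/validation loss history satisfies the same falling-loss contract.

The closed-form **oracle detector** thresholds hue into the blue band with a
saturation gate ≥ 0.45 (the deeply stained nucleus is saturated; its paler
halo of the same hue is not) and takes 4-connected components ≥ 20 px, each
with score 1.0. It depends only on hue and saturation, hence is invariant to
image-wide brightness shifts. On the default corpus it recovers every blue
nucleus and nothing else, which makes it both a brute-force reference and a
fixed point of the metric protocol (background fraction 0, undetected 0,
exactly one region per nucleus).

The two-class provenance of teacher material (cytology Class II vs III) is
carried as a metadata tag; detection itself uses a single "blue nucleus"
foreground class. Distinguishing Class II from Class III is out of scope.

## The four-criterion comparison protocol

For a detection set D matched against N blue ground-truth nuclei:

1. **Number of detections** D.
2. **Background fraction** B/D, where a detection is background iff it
   matches no blue nucleus (convention: 0 when D = 0).
3. **Average undetected regions per nucleus** U/N.
4. **Average regions per nucleus** M/N with **M = D − B**.

Matching criterion (default "permissive"): a detection matches a nucleus
when at least 25 % of the detection's area lies on the nucleus mask **or**
the nucleus centroid falls inside the detection mask. The original
assessment was visual; this rule approximates a human's "that detection is
on that nucleus" while staying fully testable. Strict IoU ≥ 0.5 is
available (`overlap_criterion="iou"`). A detection matching two nuclei
appears in both per-nucleus region lists but counts once in M, which keeps
the identity M = D − B that the protocol's reference counts obey (223 = 320 − 97,
36 = 37 − 1).

Expected regions per nucleus differ by mode. Instance mode: one. SWM mode:
the nucleus's positively-labelled windows in the evaluation tiling, so U
counts expected windows missing from the detection set; with stride = window
a nucleus split evenly across a window border has no expected region and
cannot be "undetected". The SWM detection unit is any window with nucleus
probability > 0.5 — the lowest highlighted overlay band.

Metric values are rounded half-up to 4 decimals (3 where a reference value
uses 3), reproducing the stated precision of the reference ratios
(97/320 → 0.3031, 1/37 → 0.027, 67/36 → 1.8611, 223/36 → 6.1944).

The reference counts put 36 nuclei in the per-nucleus denominators
alongside 37 detections with one background error; the package accordingly
treats N = 36 ground-truth nuclei (37 detections = 36 matched + 1
background), the only reading under which all four ratios are consistent.

## Pipeline, seeding and problem sizes

`RunConfig` serialises losslessly to YAML. Every stage derives its seed
deterministically from the single global seed
(`seed · 1000003 + crc32(stage) mod 2³¹`), so all non-training stages — and,
because the NumPy training loops are themselves deterministic, the training
stages too — reproduce bit-identically. Evaluation scenes are generated from
a disjoint seed stream and a leakage guard asserts train/eval id
disjointness.

Desk-scale problem sizes used by the examples, tests and the acceptance
script, chosen as the package's own defaults for CPU execution: fields of
288 × 384 px (3 × 4 windows), corpora of 12–90 scenes, balanced datasets of
80–394 windows per class, 3–20 training epochs for the patch CNN and 4–8 for
the instance backend, 10 evaluation images per comparison. The full
1024 × 1280 format remains the generator default and tiles into 130 windows.

## Numerical and degenerate-input choices

* Max-pool gradient ties route to the first maximal element, keeping
  backprop deterministic.
* Softmax is computed with max-subtraction; sigmoid clips its argument at
  ±60; cross-entropy adds 1e-12 inside the log.
* B/D at D = 0 is defined as 0; per-nucleus averages with N = 0 raise.
* `tile_image` rejects windows larger than the image; `label_window`
  rejects windows not fully inside it; capacity failures during cell
  placement raise `SceneCapacityError` after 200 attempts per cell.
* Coordinates are 0-based (row, col); boxes and windows are half-open.

## Known limitations

* The synthetic material is colour-separable by construction; both backends
  exploit colour far more easily than they could on real chromatin texture.
  Reported accuracies and clean fixed points are properties of the
  machinery under these conditions, not clinical performance claims.
* The instance backend has no learned shape prior; touching nuclei would
  merge into one component (the default corpus keeps cells disjoint).
* The grid runner re-trains from scratch per configuration; no warm starts.
* Papanicolaou class grading (I–V) is out of scope throughout.
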