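# Methods

This note records what `greenfruit` computes, the choices made where the
design was genuinely open, and what the synthetic experiments do and do not
demonstrate.

## Problem setting

Green-fruit detection is ordinary object detection under two aggravating
conditions: the targets are nearly isochromatic with the background
(foliage and unripe fruit share hue; shape, shading and specular highlights
carry most of the signal), and the labeled datasets are small — hundreds of
images, not tens of thousands. The package attacks both: an attention
block that reweights feature maps channel-wise and pixel-wise, and an
aggressive augmentation schedule that multiplies the effective dataset.

## Detector

The detector is a conventional single-stage, anchor-based architecture:
backbone → FPN (top-down semantic fusion) → PAN (bottom-up localization
fusion) → three detection heads at strides 8/16/32 emitting
`3 × (5 + n_classes)` values per grid cell. Decoding uses the
v5-convention transforms `center = (2σ(t) − 0.5 + grid) · stride` and
`size = (2σ(t))² · anchor`, so a zero logit sits at the cell center with
the anchor's size, and predicted sizes are bounded by 4× the anchor —
which is also the target-assignment rule (a ground truth matches an anchor
iff `max(w/wa, wa/w, h/ha, ha/h) < 4`, and is replicated into its cell
plus the two nearest neighbor cells).

### The Conv-AT block

The block composes four concatenation stages (see the README for the
formulas). Several details are under-determined by the formulas alone;
the choices here are:

* **Channel plan.** CBR1/CBR4 project to `c_out/2` (and carry the stride);
  CBR2/CBR3 project their concatenated inputs back to `c_out/2`; CBR5
  restores `c_out`. CA and SA preserve the input's `c_in` channels; their
  outputs are average-pooled with the block's stride so all concatenations
  align spatially. All internal CBRs use 3×3 kernels.
* **Spatial attention reduction.** The channel-pooled average and max maps
  form a 2-channel image that must become a single per-pixel gate before
  it can multiply a C-channel input; the minimal operator with the right
  shape is a learned 1×1 mix of the two pooled channels, applied before
  the sigmoid. That is what `SpatialAttention` implements.
* **Attention MLP.** The channel-attention MLP is the standard shared
  two-layer bottleneck (C → C/r → C, ReLU between, no biases) with
  r = 16 and a floor of min(8, C) on the hidden width, so narrow miniature
  models keep a non-degenerate bottleneck.
* **Double normalization.** CBR5 contains a batch norm and the block closes
  with *another* batch norm. Both are kept deliberately: the closing BN
  guards the concatenation-heavy topology against scale drift.
* **Placement.** Conv-AT replaces the stride-2 downsampling convolutions
  between backbone stages; a boolean mask in the architecture config turns
  each position on or off (useful for ablations).

A useful analytic property, used heavily in the tests: with all learned
attention parameters zero, both CA and SA reduce exactly to `0.5 · X`,
since σ(0) = 1/2.

### Loss

The composite loss is the family standard, restated here because the
package implements it from scratch: `box = mean(1 − CIoU)` over matched
predictions (CIoU = IoU − center-distance²/enclosing-diagonal² − αv with
the aspect term's α treated as a constant in the gradient); `obj` = BCE
over all cells with CIoU-valued soft targets (clamped at 0) at matched
locations, balanced 4.0/1.0/0.4 across the small/medium/large scales;
`cls` = BCE at matched locations, skipped for single-category training.
Term weights default to 0.05/1.0/0.5 and the total is scaled by batch
size. Head objectness biases initialize to −4.5 (≈1% prior) so early
training is not dominated by background gradients.

### Anchors

`autoanchor` clusters training-box sizes with k-means under the
`1 − IoU(w,h)` distance (median centroid updates; an update that would
increase the objective is rejected, making the objective trace
non-increasing by construction), then applies random multiplicative
mutations kept only when best-possible recall (fraction of boxes whose
best anchor passes the ratio-4 test), then mean IoU, improves. With fewer
boxes than clusters it falls back to the standard 640-scale nine with a
warning.

## Augmentation

* **Copy-Paste (mask-guided).** Instances are cut along their masks,
  flipped/rotated/scaled with nearest-neighbor resampling — chosen so
  every pasted pixel is an exact copy of a source pixel and the transform
  is exactly reproducible from its record — and composited. Defaults paste
  4 fruit + 15 leaf instances per image at probability 1.0. Placement is
  uniform with IoU ≤ 0.3 against existing fruit boxes (20 retries, then
  skip with a warning); a pre-existing box is dropped only if pastes cover
  > 90% of its area. Pasted fruits append the tight box of their
  transformed mask; leaves only occlude.
* **Mosaic** (p = 0.8). The four source images are resized to the preset
  square (per the workflow description, not aspect-preserving), tiled
  around a center drawn from `[0.5s, 1.5s]²` on a 2s canvas, and the
  canvas is center-cropped to a random fraction (0.6–1.0) and resized back
  to s. Boxes are clipped; clipped boxes below 10% of their original area
  or thinner than 2 px are dropped. Each quadrant's full source→output
  affine is recorded for auditing.
* **Mixup** (p = 0.3). Pixels blend convexly; **labels concatenate
  unweighted** — no λ weighting and no deduplication of overlapping boxes.
  This is deliberate and differs from classification mixup. α defaults to
  8.0 (draws concentrated near 0.5, SD ≈ 0.12), configurable.
* **Basic transforms.** Horizontal flip (p = 0.5) on the final sample and
  mild HSV jitter on sources. Whole-image rotation is *not* applied in the
  pipeline: rotating axis-aligned boxes inflates them, which would break
  the exact transform-record bookkeeping; rotation lives in the per-instance
  copy-paste transforms instead, where masks make it exact.
* Letterboxing (aspect-preserving resize, symmetric 114-gray padding) runs
  last, always.

The three methods fire independently per sample with their configured
probabilities; the Bernoulli draws are factored into `draw_schedule` so
the frequencies are directly testable.

## Evaluation

A detection is a true positive iff its IoU with an unmatched same-category
ground truth is **strictly greater than 0.5** (ties at exactly 0.5 are
false positives); matching is greedy in descending confidence. AP uses
all-point interpolation over the monotone precision envelope; mAP averages
per-category APs. Reported P and R are taken at the confidence that
maximizes F1 along the curve (the operating point is otherwise arbitrary;
this is the family convention). A brute-force threshold-sweep oracle in the
test suite pins the interpolation choice to 1e-9.

## Synthetic scenes

The generator emulates the difficulties of field imagery, not its
appearance: fruits are shaded ellipses with a specular highlight whose hue
sits within ±`hue_delta` (default 12°, well inside the similar-color
regime) of the foliage hue; leaves are elongated ellipse lobes composited
above fruits (occlusion probability 0.3); exposure jitter (×0.75–1.25)
stands in for weather variation; Gaussian pixel noise for sensor noise.
Boxes are **amodal** — a fruit's box covers its full rendered extent even
under leaf occlusion — matching common field-annotation practice, and the
stored masks are likewise the pre-occlusion instance masks (so copy-paste
may carry a patch of occluding leaf inside a fruit's mask, as a real
segmentation provider would when fruits overlap). Defaults: 640×640,
1–8 fruits of radius 12–60 px, 5–20 leaves, spanning the three head
strides; `SceneConfig.desk_scale()` is the 160×160 miniature (1–4 fruits,
radius 10–28 px) used for CPU-budget experiments. The 7:3 train/test split
uses `floor(0.7·N)` training items.

What passing tests on these scenes shows: the full pipeline — rendering,
masks, augmentation bookkeeping, forward/backward, assignment, decoding,
NMS, metrics — is internally consistent and can fit a detection task whose
color statistics match the hard regime. What it does not show: robustness
to real foliage texture, lighting geometry, camera optics, motion blur, or
annotation noise; no photorealism is attempted.

## Numerical and engineering choices

* The network stack runs on `greenfruit.nn`, a small NumPy reverse-mode
  autodiff engine (im2col convolution, fused batch norm, pooled-window
  max/avg primitives, stable `expit`-based sigmoid/BCE). All primitives
  are verified against central-difference gradients at 1e-6.
* Default training: SGD, momentum 0.937, weight decay 5e-4, linear warmup
  (2 epochs) then cosine decay from lr 0.02 to 0.002, batch 8. These are
  sized for the 160-px miniature; `configs/standard.yaml` carries
  full-scale settings (640 px, wider backbone), which are provided but not
  exercised by the CI-scale tests.
* Desk-scale problem sizes: the learning check and the acceptance script
  train on 64 synthetic 160×160 scenes for 60 epochs (480 SGD steps) and
  evaluate on 16 held-out scenes — chosen as the smallest configuration
  at which the detector reliably clears mAP@0.5 ≥ 0.5, the package's own
  smoke threshold for "the pipeline learns". With only 16 evaluation
  scenes (~40 boxes) the held-out mAP carries sampling noise of roughly
  ±10 points across data seeds.
* Determinism: one master seed fans out to per-stage seeds (crc-derived)
  for scene generation, initialization, augmentation and training; every
  artifact (scenes, label files, checkpoints, evaluation reports) is
  bit-reproducible for a fixed seed on a fixed NumPy build.
* Degenerate inputs are errors, not silent fixes: zero-extent boxes,
  empty masks, empty datasets, non-finite losses (training aborts with
  diagnostics), categories without ground truths (excluded from mAP with a
  warning).

## Known limitations

* The autodiff engine is single-threaded NumPy; full-scale (640 px, wide)
  training is out of reach on CPU — the architecture accepts it, the
  compute budget does not.
* Mosaic's record-keeping assumes axis-aligned affine transforms, which is
  why whole-image rotation is excluded from the pipeline.
* The synthetic provider returns ground-truth masks; an adapter to a real
  segmentation model satisfies the same `get_instances` contract but none
  ships in the package.
* mAP is evaluated at IoU 0.5 only (the protocol implemented here);
  COCO-style mAP@[.5:.95] is not provided.
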