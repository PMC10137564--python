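# Methods

## Problem and pipeline

The cardiothoracic ratio (CTR) on a posterior-anterior chest radiograph is
the maximal transverse width of the cardiac silhouette divided by the
maximal transverse internal width of the thoracic cavity; CTR > 50% is the
conventional operational definition of cardiomegaly.  In hemodialysis
units the CTR is measured routinely to guide dry-weight and
ultrafiltration decisions, and manual measurement is both slow and
operator dependent.  `ctrseg` automates the measurement in two stages:
pixel-wise semantic segmentation of heart and lung fields, followed by a
purely geometric span measurement on the predicted label mask.  Keeping
the geometry stage separate from the network means the final number is
auditable: the measured spans and the columns that produced them are
reported, and an overlay rendering shows the contours the measurement came
from.

## Segmentation network

The network is an encoder-decoder with the AlbuNet-34 shape:

* **Encoder** — ResNet-34 layout: a 7×7 stride-2 stem, a 2×2 max-pool, and
  four residual stages with block counts 3/4/6/3 and channel widths
  1/2/4/8 × `base_width` (two 3×3 convolutions per basic block,
  1×1-projection shortcuts on stage transitions).  The stage-4 output is
  max-pooled once more (`extra_pool`), for six downsamplings in total; the
  bottleneck feature map is 1/64 of the input resolution (8×8 at the
  512×512 default).
* **Decoder** — six nearest-neighbour ×2 upsamplings, each followed by
  concatenation with the matching encoder feature map (U-Net skips; the
  full-resolution block has no skip) and a 3×3 conv + BN + ReLU.  Decoder
  widths mirror the encoder widths.  Nearest-neighbour + convolution is
  the default because it is free of checkerboard artifacts; the skip mode
  is concatenation (addition is not implemented).
* **Head** — a 3×3 convolution with one filter per class and a per-pixel
  softmax.  Background, lung, and heart are mutually exclusive classes,
  matching non-overlapping reference annotations.

Grayscale input is replicated to three channels so that externally
pretrained encoder weights remain loadable; by default weights are
He-normal from a seeded generator (no pretraining is performed or
required).  `base_width` scales all channel counts: the full-scale setting
is 64, and the desk-scale experiments use 8 (≈ 449 k parameters at 64×64),
which keeps a forward pass well under a second on one CPU core.

The implementation is pure NumPy (im2col convolutions with hand-derived
backward passes), validated end to end against central-difference
gradients in float64 (max relative error ~2e-5, limited by batch-norm
conditioning).  Convolutions followed by batch normalisation carry no bias
term — the BN shift makes such a bias exactly non-identifiable.

### Batch-norm evaluation statistics

Evaluation-mode batch-norm uses a bias-corrected exponential moving
average of the batch statistics (accumulators start at zero; the estimate
is divided by 1 − (1 − m)^n with m = 0.1 after n batches).  Plain EMA from
a zero-mean/unit-variance initialisation is badly shrunk toward the
initial values during short trainings, which made early-epoch validation
losses untrustworthy; the corrected estimator tracks the training
distribution from the first batches and coincides with standard EMA once
n is large.

## Loss

The training loss is the soft Jaccard loss summed over all three classes
(background included — leaking foreground into background is then
penalised symmetrically):

loss(p, g) = Σ_c [ 1 − (Σ p_c·g_c + ε) / (Σ p_c + Σ g_c − Σ p_c·g_c + ε) ]

with per-pixel predicted probabilities p, one-hot targets g, and
ε = 1e-6 smoothing both denominators.  It is zero iff the prediction
one-hot-equals the target (up to ε) and is bounded by the number of
classes.  Within a batch, intersections and unions are accumulated **per
image** and the per-image class-summed losses are **summed** over the
batch for the gradient (the reported loss is the per-image mean).  Pooling
intersections/unions across the whole batch instead makes the gradient
scale shrink with batch size, and under the fixed optimiser settings below
it converges markedly slower; per-image reduction is the standard choice
in segmentation practice.

## Optimisation and augmentation

Plain SGD with classical momentum, learning rate 1e-4 and momentum 0.99
(their standard values for this architecture/loss pairing), no learning
rate schedule, no early stopping; the checkpoint returned is the one with
the best validation foreground mIoU.  Images and masks are resized to the
network input size — bilinear for images, nearest neighbour for masks, so
no interpolated class labels ever appear.  Batch size and epoch count are
configuration-exposed (desk-scale defaults 8 and 15).

Seven augmentations are available: random resized crop,
shift/scale/rotate, random brightness/contrast, image inversion, elastic
transform, grid distortion, and optical (radial) distortion.  Geometric
transforms apply the identical inverse coordinate map to image (bilinear)
and mask (nearest); photometric transforms touch the image only.  Each
sample's augmentation parameters come from a dedicated seeded stream keyed
by (run seed, epoch, sample index), independent of batch composition, so a
fixed seed reproduces training bit for bit.  Training is single-threaded
and deterministic; that is the only mode.

## CTR geometry

Spans are global column extents: the cardiac span over all heart-class
pixels, the thoracic span over all lung-class pixels (outer left lung edge
to outer right lung edge).  Widths are inclusive pixel counts
(right − left + 1); the +1 convention is arbitrary at sub-pixel level and
cancels to O(1/width) in the ratio.  Before measurement, the mask is
cleaned by keeping the two largest 4-connected lung components and the
single largest heart component (stray mis-segmented blobs otherwise
inflate the spans); cleanup is idempotent and on by default.  A mask with
no heart or no lung pixels raises a "missing structure" error rather than
producing a number — downstream this routes the image to human review, and
the CLI records it in the CTR CSV with an `error_note` while excluding it
from agreement statistics.  The cardiomegaly call is strictly CTR > 0.50;
ties are negative.

Because the CTR is a ratio of two horizontal spans, any resize — even
anisotropic — multiplies both spans by the same factor, so the CTR is
resize-invariant up to discretisation (≤ 2/width).  Predicted label maps
are nonetheless upscaled back to the original image resolution (nearest
neighbour) before measurement, so the reported pixel spans refer to the
original image and can be audited on the overlay.

## Evaluation suite

Per class c, one-vs-rest pixel confusion counts give
IoU_c = TP/(TP+FP+FN) and Dice_c = 2·PPV·TPR/(PPV+TPR)
(= 2TP/(2TP+FP+FN), a form defined even when PPV or TPR has an empty
denominator); the identity Dice = 2·IoU/(1+IoU) links the two and is
enforced to 1e-12 in tests.  mIoU and ADC are unweighted means over the
foreground classes {lung, heart} by default — the usual reporting
convention — with a flag to include background; the classes actually
averaged are stamped into every report.  Dataset-level metrics sum pixel
counts over images before computing metrics (micro-average), with
per-image macro-averaging as an option; the choice is recorded in the
report.

CTR agreement between a test method and the reference: OLS R² (test
regressed on reference, via `scipy.stats.linregress`), mean ± SD (n−1) of
the absolute difference in CTR percentage points, the count of images with
absolute bias ≥ 2 percentage points (inclusive), Bland–Altman bias ±
1.96·SD limits with the (mean, difference) plot payload, and a paired
two-sided t-test (`scipy.stats.ttest_rel`, df = n−1; degenerate
zero-variance input raises rather than returning a number).

Cardiomegaly detection against reference truth (reference CTR strictly
> 0.50): accuracy, sensitivity, specificity from the 2×2 table, and a
threshold-sweep ROC with trapezoidal AUC.  Tied scores are grouped before
the sweep, which makes the trapezoidal AUC exactly equal the pairwise rule
P(score+ > score−) + ½·P(equal); tests verify this equivalence exactly
against a pairwise-counting oracle.

## Phantom generator

The generator renders what the downstream stages actually consume — two
vertically elongated elliptical lung fields with configurable outer-edge
columns, a cardiac ellipse in the medial/inferior zone (heart wins class
precedence where it overlaps lung, as the cardiac border occludes lung in
a PA silhouette), a smooth background gradient, darker lung fields,
brighter cardiac silhouette, Gaussian noise (sd 0.03 of full scale) and a
1-px Gaussian blur.  Geometry jitter perturbs the defining *fractions*
before rasterization and the analytic truth is recomputed after jitter, so
the recorded spans and the raster always agree to within 1 px per edge.

Defaults emulate a dialysis cohort: thoracic fractions 0.10/0.90 and heart
half-width fraction 0.2136 give a mean analytic CTR of 0.534, and jitter
sd 0.02 per fraction propagates (delta method) to a CTR sd of ≈ 0.053, so
about 74% of phantoms are cardiomegalic — the prevalence regime in which
the evaluation statistics are exercised.

Confounders seen in dialysis patients are painted into the **image only**
(the mask always encodes anatomic truth): a bright sinusoidal catheter
curve from the neck toward the heart, a pacemaker disc with a lead, and
effusion shading over the lower lateral lung zones.  An optional hard mode
(`effusion_hard_mode`, default off) additionally truncates the lung labels
at the blunted costophrenic angles, deliberately breaking the
truth/raster agreement to emulate genuinely ambiguous cases; it is off in
every test.

What the phantoms do **not** emulate: ribs, spine, clavicles and soft
tissue texture, projection-dependent magnification, exposure variation
across machines, pathology that deforms the silhouette (large effusions,
cardiac devices inside the silhouette), and the inter-observer variability
of human annotation.  Passing the phantom experiments therefore
demonstrates that the architecture, loss, training loop, geometry, and
statistics are implemented correctly and that the end-to-end system can
recover known geometry through image noise and confounders — not clinical
performance on real radiographs, which requires real annotated data.

## Desk-scale experiment sizes

The end-to-end experiment used by the test suite and by
`scripts/acceptance.py` runs at 64×64 resolution with base width 8:
200 training and 50 held-out phantoms (jitter on, all confounders on),
15 epochs, batch 8, SGD lr 1e-4 / momentum 0.99, no augmentation (the
phantom family provides its own geometric diversity via jitter; the
augmentation battery is exercised by its own property tests and remains
the default for CLI training).  These sizes were chosen so the whole
experiment completes in about a minute on one CPU core while leaving
clear margins on the recovery criteria (foreground Dice ≥ 0.85, CTR MAE
≤ 0.02, R² ≥ 0.90, cardiomegaly accuracy ≥ 0.90).

## Numerical choices and degenerate inputs

* float32 tensors throughout the network; float64 in geometry and
  statistics.
* ε = 1e-6 in both Jaccard denominators; the loss of a perfect prediction
  is below 1e-5 rather than exactly zero.
* Nearest-neighbour label resize uses the pixel-centre mapping
  ⌊(i + 0.5)·scale⌋, which makes integer-factor upscale/downscale an exact
  round trip.
* Max-pool backward routes the gradient to the first maximal element of
  each window (deterministic tie-break).
* Component cleanup keeps the top-k components by area; equal-area ties
  are broken by label order (deterministic).
* Empty classes: span extraction and cleanup raise "missing structure";
  R² with a constant reference, ROC with single-class labels, and t-tests
  with zero-variance differences all raise degenerate-input errors instead
  of returning NaN.  Dataset evaluation catches these and reports what is
  computable.

## Known limitations

* The thoracic width is the union extent of all lung-class pixels; no
  midline estimation or per-hemithorax decomposition is attempted, so
  rotated or scoliotic anatomy (not present in phantoms) would bias real
  measurements.
* DICOM ingestion is out of scope; inputs are 8/16-bit PNG or JPEG.
* Training is CPU-bound NumPy: correct and deterministic, but not suited
  to full-scale (512×512, base width 64) training within reasonable time;
  the architecture scales there, the compute budget does not.
* The checkpoint format stores raw arrays in class-definition order; it is
  versioned only by the config embedded in the file.
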