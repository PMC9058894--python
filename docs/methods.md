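# Methods

This note records the models, conventions and numerical choices behind
`msiprescreen`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic fixtures do and do
not demonstrate.

## Tile preprocessing

**Tessellation.** A slide raster with physical scale `mpp` (µm/px) is cut
into a row-major grid of non-overlapping square tiles of fixed physical
edge (default 256 µm). The source footprint is `round(256/mpp)` px;
each footprint is resampled bilinearly to the output edge (default
512 px, so a 0.5 µm/px scan needs no resampling). Coordinates are
0-based with x = column and half-open footprints `[x, x+e) × [y, y+e)`.
Partial tiles at the right/bottom margins are dropped rather than padded:
padding would fabricate texture statistics in exactly the regions a tile
classifier summarizes. Tile count is therefore exactly
`floor(H/e)·floor(W/e)`.

**Quality control.** Tiles are scored by the mean of a binary {0, 255}
Canny edge map of their BT.601 grayscale; tiles scoring below 4 are
removed (strictly below — a tile at exactly 4 is kept). Glass background
is nearly constant and scores 0; defocused tissue loses its
high-frequency edges and falls below the threshold, while even lightly
textured tissue scores well above it. The detector parameters are this
package's own choices, fixed and configurable: Gaussian σ = 1.4,
hysteresis thresholds (40, 100) on the 0–255 scale. The tests therefore
avoid cases that flip with the detector parameters; the frozen golden
case is an 8 px checkerboard (score 63.01), which stays far above
threshold under any reasonable parameterization, whereas a 1 px
checkerboard is erased by any smoothing at all.

**Stain normalization (Macenko).** Under Beer–Lambert, a pixel is
`I = I0·10^(−M c)` with `M` the 3×2 matrix of hematoxylin/eosin
optical-density vectors and `c ≥ 0` the concentrations. OD is computed
as `−log10((I+1)/256)`; the +1 offset keeps the transform finite and
invertible on 8-bit data. Pixels with all OD components below 0.15
(background) are discarded; the remaining cloud is projected onto its
top-2 principal directions, and the 1st/99th percentile of the projected
angle defines the two stain vectors (sign-corrected to nonnegative OD,
unit norm). Columns are ordered hematoxylin first, identified as the
vector with the larger red-channel OD — hematoxylin appears blue because
it absorbs red. Concentrations come from least squares clipped at zero;
the per-stain 99th percentile is the robust maximum used for
normalization, which rescales source concentrations by
`target_max/source_max` and recomposes with the target matrix. This
makes normalization invariant to a global concentration (staining
intensity) scale by construction. Degeneracy (blank or single-dye
images) is detected by the ratio of the second to the leading OD
eigenvalue with a 1e-3 cut: measured single-dye clouds sit below ~1e-4
(the 8-bit quantization noise floor), genuine two-dye images above
4e-3.

QC runs before normalization: the blur/background decision is about
physical image content and should not depend on color standardization
(the order is configurable by calling the stages directly).

## Tile scoring

The scorer contract is minimal (`input_px` attribute plus
`score_array(batch) → probabilities`), so backbones are interchangeable.

- **Full recipe** (optional, requires torch): ImageNet-pretrained
  ResNet18, first half of the parameterized layers frozen, fine-tuned
  with Adam and cross-entropy for 5 epochs at batch 1024, lr 1e-4,
  weight decay 1e-5, on tiles resized to 224 px. These are the defaults
  of `ScorerConfig`. "First half of the layers" is interpreted as the
  first `floor(frozen_fraction · n_layers)` parameterized layers in
  definition order, exposed as `frozen_fraction`.
- **Small backbone** (`SmallConvNet`, the tested path): two 3×3
  convolution blocks (8 and 16 channels, ReLU, 2×2 max-pool), global
  average pooling, and a 2-way softmax head, implemented in NumPy with
  full backpropagation (gradients verified against finite differences in
  the test suite) and the same Adam/cross-entropy training loop.
  `ScorerConfig.desk_scale()` uses batch 32, 64 px inputs and lr 1e-2 —
  a from-scratch network of this size wants a larger step than a
  pretrained backbone being fine-tuned. With the default
  `frozen_fraction = 0.5` the first convolution stays at its random
  initialization and acts as a fixed feature bank.
- **Mock scorers**: `MockRedScorer` (mean red intensity / 255) exercises
  the plumbing with a pure, data-independent function;
  `TextureStatScorer` separates the synthetic texture classes with a
  morphology statistic (stained area over hole-filled stained area),
  needing no training at all.

Training-set assembly follows the pre-screening design: patients
contribute at most 500 tiles (uniform random subset, per-patient seeded
stream so results do not depend on processing order); the larger class
is undersampled to exact balance just before training; test tiles are
never balanced or capped below their QC-surviving count.

## Patient aggregation and thresholds

A patient's score is the fraction of their tiles with tile probability
strictly greater than 0.5, pooled across all slides — a count fraction,
so `score · n_tiles` is an integer. The boundary rule (strictly greater)
is a convention; it is configurable and only matters for scorers that
emit exactly 0.5.

Decision policies predict MSI when `score ≥ threshold` (so a threshold
equal to a positive's score counts that patient as detected):

- **Cohort-specific**: the largest threshold with calibration-set
  sensitivity ≥ the target (default 95%). With `n` positives this is the
  `ceil(0.95·n)`-th largest positive score; maximality and the
  sensitivity floor are verified in the tests by exhaustive scan over
  all distinct scores.
- **Fixed**: global candidates 0.25 / 0.50 / 0.75 applied to every
  cohort unchanged.
- **Learned**: each training cohort's optimum is the fixed-sensitivity
  threshold on pooled out-of-fold scores from a label-stratified
  3-fold patient-level CV inside that cohort; the learned value is the
  unweighted mean of the optima ("averaging" is taken as unweighted; the
  per-cohort optima are kept in the policy's provenance so a weighted
  variant can be audited). The "optimal threshold" inside this procedure
  is deliberately the same 95%-sensitivity definition as the
  cohort-specific policy. When the scorer is data-independent the
  out-of-fold scores equal the stored scores and the cohort optimum
  reduces to the plain fixed-sensitivity threshold; a `rescore` callback
  (or the full pipeline's per-fold training) activates the CV machinery
  proper. In the leave-one-cohort-out driver, each cohort's CV optimum
  is computed once and reused across folds — it does not depend on which
  cohort is held out — and the held-out cohort is always excluded from
  its own learned threshold.

## Evaluation

AUROC is the Mann–Whitney rank statistic (ties half-credited), identical
to trapezoidal ROC area; the suite checks it against brute-force pair
counting. Confidence intervals are percentile bootstrap — quantiles of
the resampling distribution, not BCa — with patient-level unstratified
resampling (a stratified variant is available by flag), 1000 resamples
and 95% level by default. Single-class resamples are redrawn, keeping
the effective number of draws at `n_boot`; if the metric fails on more
than half of the attempts the CI is declared unobtainable. Percentile
intervals may in pathological cases exclude the point estimate; this is
logged, not fatal.

Confusion statistics at a policy report the full triage panel:
sensitivity, specificity, PPV, NPV, F1 (MSI as the positive class), the
rule-out fraction TN/N and the FN fraction FN/N, which satisfy
`fn_fraction = (1 − sensitivity) · prevalence` identically. Internal
values are proportions; formatted outputs print percentages.

## Study designs

Leave-one-cohort-out trains one model per held-out cohort on all other
cohorts' patients; every patient is scored exactly once, by a model that
never saw them, and train/test patient-id disjointness is asserted on
every fold. Within-cohort CV uses label-stratified patient-level folds
(stratification guarantees positives in every fold; an unstratified
variant exists); multi-slide patients travel as a unit. Patients dropped
at ingestion (missing label, missing image) are counted in a
consort-style exclusion report; patients whose tiles are all removed by
QC are flagged unevaluable and excluded from metrics with a warning.

## Synthetic fixtures

**Texture slides** render two H&E-like classes through the Beer–Lambert
model with the classic stain vectors: the MSI-associated class is a
dense field of small filled discs (a lymphocyte-rich pattern, radius
3–6 px at 1 µm/px), the MSS-associated class larger ring/gland-like
annuli (radius 8–14 px, wall 4 px) enclosing unstained lumina; both
share an eosin-stained smooth-noise stroma so the class signal lives in
the hematoxylin texture alone. The primitives are deliberately
simplistic: they provide a *learnable, linearly separable* class signal
for end-to-end tests, not histological realism. Passing the end-to-end
study therefore shows that the pipeline wiring, leakage discipline,
calibration and metrics are correct — it says nothing about classifier
performance on real tissue, where the class signal is far subtler and
confounded by site effects.

**Score cohorts** draw labels Bernoulli(prevalence), default 12% as in
sporadic colorectal MSI, and scores from class-conditional Beta models
(default Beta(8,2) for MSI vs Beta(2,8) for MSS), quantized to the
patient's tile count (120–500) because real aggregated scores are tile
fractions. Beta models were chosen because patient scores live in
[0, 1]; the defaults give a strongly separable cohort (true AUROC 0.998
by numeric integration of `∫ f₁ F₀`). The artifact injector degrades
slides deterministically: Gaussian blur (σ = 4·severity), a darkened
duplicated band (tissue fold), or OD scaling (overstain); severity 0 is
the identity.

**Study sizes in the test suite.** The end-to-end study uses 4 cohorts
of 8 patients, one 768 px slide each (9 tiles/slide), the small backbone
at 64 px inputs and 10 epochs, and 200 bootstrap resamples — sizes at
which the whole study runs in a couple of minutes on one CPU while still
exercising every stage. The bootstrap coverage simulation uses 200
cohorts of 120 patients at prevalence 0.3 generated from Beta(4,3) vs
Beta(3,4) (true AUROC 0.717): a mid-range regime chosen because
percentile bootstrap CIs for AUROC are only approximately valid away
from the boundary — near AUROC = 1 they undercover badly, which is a
known property of the method, not an implementation artifact. Prevalence
0.3 (rather than the clinical 12%) keeps enough positives per simulated
cohort for stable resampling at this size.

## Known limitations

- The Canny parameters and grayscale weights behind the QC score are
  package choices; only the threshold (4) and the detector family are
  externally fixed. Tiles near the threshold can flip under different
  detector settings.
- Macenko estimation assumes two dominant dyes; it will reject (by
  design) single-dye or blank inputs and can be biased when one stain is
  nearly absent from a slide.
- The small backbone is meant for desk-scale validation; its capacity is
  far below the full recipe's and its scores should not be interpreted
  beyond the synthetic textures.
- Ingestion is plain rasters (PNG/TIFF) with µm/px metadata; pyramidal
  proprietary WSI containers and tumor-region annotations are out of
  scope (the pipeline is designed for full, non-annotated slides).
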