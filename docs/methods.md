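# Methods

This note documents the models implemented in `chemimage`, the assumptions
behind them, the synthetic world they are tested in, and the numerical and
design choices a maintainer should know about.

## The prediction problem

Each patient contributes 1–2 FTIR chemical images of tissue-microarray cores
(dense cubes, rows × cols × wavenumber channels, absorbance units) and one
binary outcome label (disease recurrence). Prediction quality is always
reported as patient-level ROC AUC: a patient's score is the mean model output
over that patient's images, and all data splitting is by patient, never by
image, so a patient's material can never appear on both sides of a fit.

## Preprocessing

**Truncation.** The axis is restricted to the fingerprint region
(1000–1800 cm⁻¹). The internal convention is an ascending axis; descending
files are flipped on read.

**EMSC.** Scatter and baseline are removed by a single-pass extended
multiplicative signal correction. Every pixel spectrum `s` is modelled by
ordinary least squares on a fixed design: the reference spectrum `m`, a
polynomial in the axis rescaled to [−1, 1] (default order 2), and a smooth
scatter basis (default: the first 3 half-period cosines). The corrected
spectrum is `(s − baseline − scatter)/c` with `c` the reference coefficient.
Choices and caveats:

* The design matrix is identical for all pixels, so a whole image is
  corrected by one pseudo-inverse product. Computation is float64.
* One pass, no iteration: the correction contract used downstream is removal
  of a smooth confound plus reference normalisation, not a physical
  resonant-Mie model (the full iterative algorithm is a separately published
  method and out of scope).
* Pixels whose fitted `c` is below `c_min` (default 0.1) are flagged and
  passed through uncorrected: they carry no reference-like signal (substrate,
  holes, all-zero pixels), and dividing by a near-zero noisy `c` only
  amplifies noise. All-zero pixels therefore stay zero.
* What the correction guarantees — and what the tests assert — is
  *confound invariance*: correcting a cube with a baseline from the modelled
  family equals correcting the same cube without it (≤1e-6). It does **not**
  return the raw tissue spectrum verbatim: OLS also projects part of the
  tissue spectrum itself onto the polynomial/cosine columns, and the 1/c
  normalisation rescales each pixel. This is inherent to EMSC, not an
  implementation artifact.
* The default reference is a synthetic stand-in (a sum of broad protein-like
  bands); a measured reference can be supplied as a two-column CSV and is
  interpolated onto the image axis.

**Substrate masking.** k-means with k = 2 over all pixel spectra of the
corrected image; the cluster with lower mean absorbance in the amide I window
(1600–1700 cm⁻¹) is substrate. Substrate pixels are zero-padded. Masking
runs after correction by default (order is switchable). Degenerate
clusterings (an empty cluster or coincident centroids) are retried with new
seeds and then raised as errors.

## Segmentation

Tissue spectra pooled over the cohort are clustered at two levels
("double" k-means): level 1 on a random subsample (default 20 000 spectra),
then level 2 inside each level-1 cluster. At both levels k ∈ [2, 5] is chosen
by maximising the PBM index

    PBM(K) = ((1/K) · (E₁/E_K) · D_K)²

with E₁ the summed distance of points to the global centroid, E_K the summed
distance to own centroids, D_K the maximum centroid separation; Euclidean
distance on corrected absorbance throughout, no extra normalisation. K = 1
scores 0; zero within-cluster scatter scores +inf. Ties in PBM break toward
smaller k; nearest-centroid ties break toward the lower cluster id. A level-1
cluster with fewer than 10·k_min members keeps a single sub-cluster with a
warning. k-means itself is scikit-learn's (k-means++ init, 10 restarts,
tol 1e-6, max 300 iterations, seeded); the assignment returned to callers is
verified nearest-centroid-consistent.

## PLS-DA

PLS1 by NIPALS on mean-centred X and y ∈ {0,1}: unit-norm weight vectors,
orthogonal scores, X-deflation per component. Coefficients for every
truncation 1..lv_max derive from one fit (NIPALS components are nested), so
validation-F1 model selection over 1–50 latent variables costs one fit.
Ties in F1 go to the smallest LV. Class threshold 0.5; positive class =
recurrence. Component extraction stops early if the residual X carries no
covariance with y (degenerate fixtures). The per-cluster pipeline pools a
cluster's member spectra (capped per image, default 200), labels them by
patient outcome, selects LV on the validation patients, and reports
spectrum-level F1 plus patient-level AUC (patient score = mean of spectrum
scores; median/max switchable), mean ± sd over repeated stratified splits.
The 3-LV embedding maps each tissue pixel to its score triple
`t = Rᵀ(x − x̄)`, `R = W(PᵀW)⁻¹`; substrate pixels become (0,0,0).

## Networks

No deep-learning framework is assumed: every layer implements explicit
forward and backward passes in numpy, and all three convolution forwards are
verified against brute-force nested-loop oracles, with finite-difference
gradient checks on smooth paths.

* `conv2d_collapse` — standard multi-channel 2-D convolution whose filters
  span the full channel depth (for a 3-D stream, all maps × all spectral
  slices), collapsing it by summation: one 2-D map per filter.
* `dsc_type1` — one spatial kernel (per-input-map weights, shared bias)
  convolves every spectral slice into a single intermediate volume; F
  learnable 1-D spectral kernels then produce F output volumes.
* `dsc_type2` — S spatial kernels produce S sublayer volumes; each sublayer
  has its own T spectral kernels, giving S·T output volumes (sublayer-major).
  The parameter count S·(k²M+1) + S·T·(k_z+1) implies distinct spectral
  kernels per output map, and that is what is realized.
* Convolutions: stride 1, "same" zero padding in every convolved dimension;
  even kernels (Model 6's 8×8×8) pad asymmetrically. Pooling: "valid",
  stride = window by default; stride-1 overlapping pooling is available via
  the layer's `stride` argument but makes the dense head enormous and is not
  used by the named builders. One ReLU per composite layer, after the
  spectral stage and bias. Dense head fixed at 180 → 100 → 1; hidden ReLU;
  the output sigmoid lives in the loss/prediction for numerical stability.
  Initialisation is uniform He; batch normalisation (2 parameters per map,
  running statistics for evaluation) is inserted between each convolution
  and its pooling layer when enabled.

Architectures are declarative (`ArchitectureSpec`): output shapes and the
exact learnable-parameter total derive symbolically before any array exists,
specs serialise to JSON, and instantiation asserts that realized parameter
arrays total exactly the symbolic count. Named builders: `lenet5_mod`
(two collapsing convolutions, default 6/16 filters — the classic values,
config-exposed), `model1` (first convolution replaced by a Type 1 DSC),
`model2`–`model4` (Type 1 stacks, 12/25/25/50 filters of 5×5×5, differing in
how the spectral dimension is reduced), `model5` (Type 2 stack, 5×3 / 5×5 /
5×5 / 5×10 filters; the ambiguous middle layers default to S=5, T=5),
`model6` (4×4×4 input average pooling, 8×8×8 and 3×3×5 DSCs with unstated
filter counts defaulting to 12/25, then a collapsing convolution, default 25
filters). Reported parameter tables are not reproduced numerically — the
source's pooling geometry is internally inconsistent — but the ordering
(Model 4 smallest of Models 2–5, via global average pooling) is asserted.

## Training harness

Stratified patient-level splits: 60:20:20 by floor + largest-remainder
allocation per class with at least one patient of each class per set
(so a class needs ≥3 patients); the 5-fold protocol deals stratified fifths,
rotates the test fifth, and splits the remainder 3:1 into train:val. All
plans are deterministic in their seed. Class weights are inverse-frequency,
normalised to mean 1 (ratio n_maj/n_min). Training minimises class-weighted
binary cross-entropy on logits with Adam (default lr 1e-3); inputs are
standardized per channel with training-set statistics by default (the
statistics ride with the trained network and are never refit on validation
or test data). Early stopping monitors training loss (the source protocol;
validation monitoring is switchable), halts after `patience` epochs without
improvement, and restores the best-epoch snapshot; an assertion verifies the
restored epoch is the curve minimum. ROC AUC is the rank-based Mann–Whitney
statistic; ties contribute 1/2.

## The synthetic world

`SynthConfig` defaults state the world once: 106 channels over
1000–1800 cm⁻¹, 1–2 cores per patient, recurrence rate 29/139 ≈ 0.21 (the
composition of the cohort the pipeline is modelled on), 64×64 desk-scale
cores (256×256 by config), noise sd 0.02 AU, baseline amplitude 0.1 AU.
A core is a centred disc (radius 0.42·min(rows, cols)); tissue sub-types are
contiguous blobs from equal-mass quantile cuts of a Gaussian-smoothed random
field; each sub-type has a fixed Gaussian-band spectrum (epithelium
protein-rich, stroma collagen-like, lumen weaker; substrate nearly flat).
The Mie-like baseline is a per-pixel random combination of a linear slope
and the first three half-period cosines — the same family the default EMSC
design spans, deliberately, so correction can be exact and recovery tests
have a sharp oracle. The label effect multiplies the epithelial phosphate
band (1080 cm⁻¹) by (1 + effect_size) for positive patients; effect_size = 0
is an exact null (labels independent of cubes).

What the generator does **not** emulate: physical resonant-Mie extinction,
paraffin bands, atmospheric lines, detector artifacts, spatial noise
correlation, and inter-patient biological heterogeneity beyond the blob
geometry. A green test therefore establishes correctness of the algorithms
under a controlled, favourable world — not instrument-level robustness.

## Acceptance-scale choices and a known limitation

The acceptance suite runs every property check at a desk scale stated in each
test (single CPU, whole-suite budget of minutes): segmentation recovery on
24×24×24 cohorts, null PLS-DA calibration on 100 patients with 16×16×16
cores (per-cluster AUC averaged over the pipeline's 10 split repetitions),
and the end-to-end deep-learning run on 150 patients with 32×32×16 cores,
batch size 8, 15 epochs — far below the source protocol's 150–200 epochs and
256×256×106 images, which would cost orders of magnitude more than any
single-CPU budget.

At this reduced scale the end-to-end harness demonstrably works (loss → ~0,
early stopping and restoration exercised, splits leak-free, null arm
calibrated at chance), but the Type 1 DSC network does **not** reach the
strong-effect recovery bar of mean AUC ≥ 0.85: measured 5-fold mean ≈ 0.64,
against an oracle ceiling of ~0.96 for an ideal band-and-region detector.
Two causes, documented after extensive probing: the 1/c EMSC normalisation
makes overall image brightness — the easiest feature for a CNN —
*anti*-correlate with the label (the effect band inflates the fitted c,
suppressing all other channels after division), and repeated max-pooling is
a poor estimator of the mean-amplitude statistic that actually carries the
class signal at these sample sizes. The corresponding acceptance test
asserts the bar verbatim and is expected to fail; it is an honest negative
result, consistent with the modest real-data performance reported for this
model family (~0.64 AUC).

## Reproducibility

Every stochastic step takes an explicit seed (generator, k-means,
subsampling, splits, initialisation, batch order). The pipeline orchestrator
(`chemimage.pipeline.run_pipeline`) serialises the resolved configuration
before any stage runs, records a configuration hash (paths excluded) and
lists every written file in a manifest; a failed stage preserves completed
outputs. YAML configs are strictly validated — unknown keys are rejected.
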