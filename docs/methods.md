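# Methods

This note documents the models, conventions and numerical choices behind
`histoswt`, and what its synthetic experiments do and do not demonstrate.

## Stationary wavelet enhancement

Images are H×W×3 float arrays with intensities in [0, 1]; 8-/16-bit integer
PNG/TIFF files are converted on read and quantized back on write. The
[0, 1] normalization is load-bearing: with the orthonormal-filter
(`norm=True`) convention of the one-level undecimated transform, detail
coefficients on such images are order-unity (step edges reach |w| ≈ 0.5),
which is the scale on which mapping constants bounded by 0.1 (and d ≤ 1)
act meaningfully.

Each RGB channel is decomposed independently (preserving stain color
information), producing four subband planes — LL (approximation) and
LH/HL/HH (details) — each with the input's spatial shape. Boundary handling
is periodic, which makes `reconstruct(decompose(x)) == x` exact to machine
precision; the test suite verifies the decomposition against an independent
two-pass 1-D à-trous filtering oracle (circular convolution with the
orthonormal-scaled analysis filters, phase-aligned by half the filter
length per axis). Odd image dimensions are edge-padded to even internally
and cropped back after reconstruction. Supported wavelets: haar, sym2, db2,
bior1.3, level 1 only.

The enhancement maps each signed detail coefficient through the cubic
polynomial y = a·w³ + b·w² + c·w + d (Horner evaluation) and leaves LL
untouched (bit-identical); reconstruction clips to [0, 1] because the
mapping can push values out of gamut.

Two consequences of applying the polynomial to *signed* coefficients as
written deserve note:

* **The constant d is inert in the enhance path.** The inverse undecimated
  transform averages polyphase branches, and a constant added to every
  detail subband reconstructs to exactly zero (the synthesis high-pass has
  zero DC gain; shift-averaging cancels the modulated residue). This holds
  at 1e-16 for all four supported wavelets and is asserted by a test. d
  still matters wherever the mapped coefficients themselves are consumed.
* **In-domain mappings are strong detail attenuations.** With c ≤ 0.1 and
  the cubic/quadratic terms similarly bounded, every mapping in the search
  domain shrinks detail amplitude roughly 10–100×; the enhanced image is
  dominated by its approximation pathway, with the a·w³ term selectively
  re-injecting large-magnitude coefficients. A magnitude-based variant of
  the mapping (weighting |w| with the sign restored) would behave
  differently but is not what the formula as printed specifies, so it is
  not implemented.

Segmentation preprocessing (`extract_ll`) converts the image to Rec. 601
luminance, takes the one-level LL plane, min–max rescales it and renders it
through an *inverted* gray map — the smallest coefficient white, the
largest black, matching the conventional "Greys" colormap orientation. A
constant LL plane (zero dynamic range) renders uniform mid-gray rather than
erroring. The orientation and rescaling were open choices; both are fixed
and documented here so runs are comparable.

## Augmentation and cross-validation

Seven geometric transforms per training image, in a fixed canonical order:
rot90, rot180, rot270 (anticlockwise), hflip (left–right mirror),
hflip+rot90, vflip, vflip+rot90 — with the flip applied before the rotation
in the combined transforms. Together with the identity these are the eight
symmetries of the square, so every output preserves the per-channel
intensity histogram exactly. Test folds are never augmented.

Stratified k-fold splitting shuffles each class with a seeded generator and
deals it round-robin across folds, so per-class fold sizes differ by at
most one. The round-robin starting fold is offset by the class's rank,
rotating the remainder samples of different classes into different folds:
on a 322-image cohort with class counts 161/106/55 this yields folds whose
training complements include exactly 257 images (test allocation 32/22/11),
reproducing the counting arithmetic 257 × 7 = 1799 new images, 2056 total.
Splitting is at image level, not patient level — grouped splitting is a
known limitation, not a supported mode.

Every sample carries provenance (`source_id`, `transform_tag`); the
experiment drivers re-run a source-level disjointness audit between train
and test inside every fold.

## Evaluation metrics

Multiclass grading is scored by one-vs-rest ROC analysis. Micro-averaging
pools TP/FP/FN/TN over the K binary sub-problems at each threshold and
integrates the pooled curve by the trapezoid rule (ties traverse
diagonally, equivalent to counting tied pairs as half-concordant).
Macro-averaging ships in two explicit variants:

* `variant="curve"` (default): per-class TPR and FPR averaged pointwise on
  the shared threshold grid, AUC of the averaged parametric curve;
* `variant="mean"`: unweighted mean of per-class one-vs-rest AUCs — the
  quantity a pairwise concordance count reproduces exactly.

These are different operations and do **not** coincide in general, not even
for balanced classes (averaging curves over a threshold parameter is not
averaging areas); oracle-equivalence tests therefore target the `mean`
variant, while the `curve` variant is tested for its own invariants (range,
perfect/chance behavior, invariance under strictly monotone score
transforms).

Segmentation uses per-class one-vs-rest confusion counts: IOU = TP/(TP+FP+FN),
F1 = 2TP/(2TP+FP+FN) (≡ 2·IOU/(1+IOU), asserted), accuracy, precision,
sensitivity, specificity, and mIOU as the unweighted mean of per-class IOU.
Zero-denominator metrics are reported as NaN with a warning and excluded
from class averages — never silently coerced to 0. Cohen's kappa uses
marginal-product expected agreement, with the degenerate p_e = 1 perfect
agreement case defined as 1.0. Fold aggregation reports the arithmetic mean
and the population (divide-by-n) standard deviation.

## Bayesian tuner

The search space is the box a, b, c ∈ [0, 0.1], d ∈ [0.001, 1] crossed with
the categorical wavelet. Phase 1 draws `n_random` seeded uniform samples;
phase 2 runs `n_bayes` proposals from a Gaussian-process surrogate
(Matérn-5/2 kernel with a small white-noise term, inputs scaled to the unit
box, normalized targets) under the expected-improvement acquisition
(ξ = 0.01), maximized over 192 uniform candidates plus 64 perturbations
(σ = 0.05) of the incumbent. The categorical wavelet is handled by one
surrogate per wavelet — proposals go to the wavelet with the best EI —
avoiding fake metric structure between unrelated filters; a wavelet with
fewer than two observations is treated as maximally uncertain (pure
exploration). Objective exceptions are recorded as failed iterations and
skipped by the surrogate; if the whole random phase fails the run aborts.
With `n_bayes=0` the tuner reduces exactly to seeded random search (tested
against an independent implementation drawing the same seed stream). Traces
(params, value, phase, running best) serialize to JSON for exact replay.

The pipeline objective enhances every image with the proposed constants,
runs the full augment/train/score cycle per fold, and returns fold-mean
micro-AUC — the monitored quantity. The reference protocol uses 25 random +
20 surrogate steps; demos and the acceptance run use smaller budgets (6+3)
because each evaluation is a complete cross-validated experiment.

## Reference models and plugin contracts

Deep backbones (Xception/ResNet/MobileNetv2 classifiers, DeepLabv3+
segmenters) are out-of-process plugins behind `ModelContract`; the
two-stage fine-tuning schedule (stage 1: new head only at lr 1e-3, decay
1e-6; stage 2: backbone at lr 1e-4) and the atrous configuration (rates
12/24/36, output stride 8, decoder output stride 4, Xception-65 backbone)
are serialized into plugin configs but never executed in-process. Batch
sizes and epoch counts are a plugin concern.

The built-in reference classifier maps each image to 22 features — detail
subband energies, mean magnitudes, 99th-percentile and maximum |w| per
detail band, LL mean/std, five luminance quantiles, three channel means —
and fits a standardized, L2-regularized multinomial logistic model
(deterministic lbfgs). Because per-feature standardization absorbs any
uniform linear rescaling of the detail bands, a purely linear mapping
(a=b=0) cannot change its decisions; what the A/B experiment measures is
the *nonlinear* part of the mapping plus the interplay between suppressed
detail bands and the approximation pathway. The reference segmenter
classifies pixels from local intensity, 5×5 mean/std and smoothed detail
magnitude, with a Gaussian smoothing vote on the predicted probability
plane; training subsamples 1500 pixels per image with a per-image fixed
seed, keeping fits deterministic and desk-scale.

## Synthetic data: what it emulates, what it does not

The graded generator superimposes, per image: a shared smooth background
(Gaussian-filtered noise, σ = H/6, rescaled to [0.2, 0.9]); a unit-variance
class texture — a power-law field with grade-specific spectral slope
(defaults 2.5/1.6/0.8: flatter slope = more high-frequency energy),
band-limited below 0.30 cycles/pixel and sparsified by the signed-square
nonlinearity so detail coefficients are heavy-tailed — scaled by 0.16; and
a class-independent nuisance of sparse impulses (4% of pixels) plus white
noise, with per-image amplitude uniform on [0, 0.25]. Mild eosin-like RGB
tinting with 3% jitter finishes the image. Grade-wise mean detail energies
are strictly ordered by slope (tested), and the spectral placement makes
the enhancement A/B experiment mechanistically meaningful at desk scale:
in-domain mappings remove mostly near-Nyquist nuisance while the
mid-frequency class texture survives the approximation pathway.

The segmentation generator draws epithelium as a Boolean model of disks on
the torus — Poisson(density·area) disks, radii uniform on [4, 8] px — so
its expected coverage has the closed form 1 − exp(−λ·E[πR²]) (verified by
Monte Carlo within 3σ); epithelium pixels are bright and smooth, stroma is
oriented fibrous texture (anisotropic Gaussian filtering, default
anisotropy 4). Masks are the exact blob indicator; single-class draws are
retried up to 10 times, then raise.

Neither generator attempts photorealism: no nuclei, glands, stain
deconvolution, patient-level correlation or scanner artifacts. Passing
tests demonstrate that the pipeline's machinery — transforms, protocol,
metrics, tuner — is correct and that enhancement helps *when the data
matches the spectral premise the method rests on*; they say nothing about
clinical performance, which requires real cohorts and the external deep
backbones.

## Problem sizes and determinism

Default experiment sizes (150 images of 32×32 for grading, 10–15 pairs of
48×48 for segmentation, tuning budgets of 6+3 outside the smooth-objective
checks) were chosen so every pipeline path, including the full A/B
experiment, runs in seconds to a few minutes on a single CPU. All
randomness flows from explicit integer seeds through `numpy` generators;
datasets are byte-reproducible (asserted via 8-bit-quantized SHA-256
hashes), model fits are deterministic, and repeated experiment runs produce
bit-identical metric reports. CLI runs record a JSON manifest (command,
config, seeds, input/output hashes, version) sufficient to replay and
verify any deterministic run.
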