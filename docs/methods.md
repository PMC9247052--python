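# Methods

## Data model and preprocessing

A recording is a datacube `[y, x, band]` of non-negative reflectance in
arbitrary units on the camera grid (100 bands, 500–995 nm, 5 nm steps).
Field-of-view dimensions are treated as metadata, never as constants.
Preprocessing is deliberately minimal, matching standard practice for this
camera class:

- **Pixel-level ℓ1 normalization.**  Each pixel spectrum is divided by its
  band sum, so a global illumination scale cancels exactly (scaling a raw
  cube by any positive constant leaves all downstream median spectra
  unchanged; this is a tested invariant).  All-zero pixels cannot be
  normalized; they are flagged in a QC mask and excluded from annotation
  masks rather than silently divided.
- **Median spectra.**  One spectrum per annotation: the band-wise median
  over the mask pixels.  The band-wise median of unit-sum spectra is not
  itself exactly unit-sum, so the median is re-normalized to sum 1 and the
  pre-renormalization sum is recorded (it is within ~1e-3 of 1 in
  practice).  Downstream models receive exactly unit-mass spectra.

Masks are boolean rasters (0-based, x = column, y = row).  Cubes are
stored as HDF5 (`/reflectance`, `/wavelengths_nm`); annotations as a JSON
sidecar with run-length-encoded masks.

## The acquisition design and its factors

The standardized protocol records, per pig and organ, 4 organ positions,
each from 3 camera angles (perpendicular, ±25°), each 3 times without any
change of scene: 36 recordings per organ per pig.  The grouping used in
all models is:

- **pig** — the animal (subject-level random intercept δ_i);
- **image** — one recorded scene, i.e. one (organ position, angle)
  combination (random intercept γ_ij nested in pig).  The repetition
  residual ε_ijk is the variability between identical re-recordings of
  that scene.  The camera angle is a *fixed* effect; because each scene is
  recorded at one angle, angle varies between images.

The identification of "image" with the (position, angle) scene rather
than with the position alone follows from the study bookkeeping: with 11
pigs holding 7–19 organs each, per-pig image counts of 84–228 summing to
1944 are only consistent with 12 images per organ per pig (4 positions ×
3 angles), not 4.

## Per-wavelength mixed model

For each wavelength an independent model is fitted to the annotation-level
median reflectance:

    y_ijk = α + organᵀβ + angleᵀθ + δ_i + γ_ij + ε_ijk

with treatment-coded fixed effects (references: stomach, perpendicular)
and independent Gaussian random terms.  Estimation is REML: variance
components are the quantity of interest and REML removes the fixed-effect
bias of plain ML.  Factors with a single observed level (the stratified
per-organ analysis drops "organ") are removed from the design matrix.

### Fitting algorithm

The fitter exploits the nested layout directly.  When every image has the
same number of repetitions r (the standardized protocol has r = 3), an
orthogonal transformation splits the data into three independent strata —
within image, between images within pig, between pigs — whose error
variances are

    a0 = σ_ε²,   a1 = σ_ε² + r σ_γ²,   a2_i = a1 + r m_i σ_δ²

(m_i images in pig i; pigs may hold different numbers of images).  The
restricted likelihood then reduces to weighted least squares over cached
cross-product blocks; evaluating it costs O(p²) after an O(n p²) setup, so
one fit takes milliseconds and the parametric bootstrap thousands of
refits in seconds.  The responses are standardized internally (REML
estimates are scale-equivariant; proportions are scale-invariant — a
tested property) and the three variances are optimized by L-BFGS-B from a
method-of-moments start, with a second fixed start as a fallback;
variances are constrained non-negative, and active constraints are
reported as truncations.  This is exact REML for the balanced-repetition
layout; data with unequal repetition counts fall back to statsmodels
`MixedLM`.  Both engines are cross-validated against each other in the
test suite, and against the balanced nested-ANOVA closed form, which REML
reproduces on balanced designs with interior estimates (in a spot check
the in-package fitter reached a slightly *lower* REML criterion than the
general-purpose optimizer).

### Explained-variation decomposition

Per wavelength, the variation is attributed as

- organ: empirical variance (over the observations, denominator n) of the
  fitted organ term organᵀβ̂;
- angle: empirical variance of angleᵀθ̂;
- the empirical cross-covariance of the two fixed terms is split equally
  between them — it vanishes by orthogonality in balanced designs, and a
  warning is raised if it exceeds 1% of the total;
- pig, image, repetition: σ̂_δ², σ̂_γ², σ̂_ε².

Proportions are each share over the sum, so they add to 1 by
construction.  The stratified (per-organ) analysis reports explained
*standard deviations* instead: sd(angleᵀθ̂), σ̂_δ, σ̂_γ, σ̂_ε.  The summary
statistic across wavelengths is the median.  Non-convergent wavelengths
are reported as gaps and never interpolated.

### Parametric bootstrap

Confidence bands redraw δ*, γ*, ε* from the fitted variances on top of
the fitted fixed part X β̂ (the fixed effects are not resampled — the
standard parametric scheme), refit, re-decompose, and take pointwise
percentile intervals (95%, B = 500 by default).  The run errors out if
more than 20% of refits fail.  Calibration is checked by a nested
Monte-Carlo study (5 pigs × 5 organs, B = 200, 50 outer replicates):
coverage of the true organ proportion must lie in [0.85, 0.99].

## Synthetic data generator

The generator's purpose is inferential, not biophysical: it produces data
for which the per-wavelength mixed model is *exactly correctly specified*,
so parameter recovery is a meaningful test of the decomposition.

- **Fingerprints.**  Each organ curve is the ℓ1-normalization of a gentle
  linear baseline, 1–3 Gaussian absorption dips centred in 520–600 nm
  (hemoglobin-like), and a logistic reflectance rise across 600–750 nm,
  with all shape parameters drawn per organ from seeded distributions.
  Libraries validate smoothness (max band-to-band step 0.01 on the
  100-band grid) and distinctness (mean pairwise ℓ1 distance > 0.05;
  typical libraries sit near 0.15).  The functional form is a visually
  faithful stand-in, not a tissue-optics model.
- **Random effects** are drawn independently per wavelength by default —
  that is what makes the per-wavelength model exactly specified.  An
  optional Gaussian-kernel smoothing across bands (variance-preserving up
  to edge effects) exists for realism experiments only; real within-organ
  spectral covariance is unknown, so this knob makes no empirical claim.
- **Calibration.**  `components_from_proportions` sets (σ_δ², σ_γ², σ_ε²,
  θ) relative to the between-organ fingerprint variance so that the
  generative explained-variation shares at the median wavelength equal the
  requested proportions; the shipped reference proportions are organ
  83.4%, image 13.8%, pig 2.3%, angle 0.1%, repetition 0.2%.  The two
  angle effects are ±t with t = √(1.5 · v_angle) (balanced three-angle
  design).
- **Clipping/normalization.**  The raw additive table (components exactly
  as specified; used for variance work) and the clipped, row-renormalized
  table (valid ℓ1 spectra; used for embedding and classification) are
  both available — clipping would otherwise distort the variance
  components.

What passing tests therefore show: the inference machinery recovers known
structure of the assumed model at study scale.  What they do not show:
robustness to features real data may have — spectrally correlated noise,
non-Gaussian effects, annotation errors, heteroscedasticity across organs.

## Embedding

t-SNE (scikit-learn, Barnes–Hut, PCA initialization, single-threaded for
determinism) on the annotation-level median spectra.  The staged random
search tunes early exaggeration (50 random integers in [5, 100]), then
the learning rate (100 in [10, 1000]), then the perplexity (50
equidistant integers spanning [2, 100]), each stage keeping previous
winners; untuned parameters sit at conventional defaults (12 / 200 / 30).
The original tuning criterion, visual inspection, is not automatable, so
the search scores candidates by mean same-organ purity among each point's
10 nearest embedded neighbours; the scoring hook is pluggable.  The tuned
triple (34, 92, 30) ships as the default configuration.  Ties keep the
first-drawn candidate; non-finite scores skip the candidate with a
warning.

## Classifier

Architecture (valid convolutions, batch norm before ELU): three conv
blocks (64/32/16 filters, kernel 5, average pooling 2 — spectral lengths
100 → 48 → 22 → 9), two fully connected blocks (100/50, dropout p), and a
final linear layer to 20 logits; softmax only at probability output.
With affine batch-norm parameters counted, the network has 34,326
trainable weights (conv out·(in·k+1), BN 2·ch, FC out·(in+1)); the
minimum admissible input is 36 bands.  The engine is a numpy
implementation with manual backpropagation, verified against central
finite differences in the tests.

Training: Adam (β₁ = 0.9, β₂ = 0.999), exponential learning-rate decay
applied per epoch, multiclass cross-entropy.  Optional class weighting
uses w_c ∝ 1/n_c normalized to mean 1; optional oversampling draws batch
instances with equal class probabilities.  Each epoch samples annotations
with replacement.  Because the desk-scale schedules train for few batches,
batch-norm running moments are re-estimated after training with one large
forward pass over (up to 4096 rows of) the training data — without this,
evaluation-mode statistics lag the final weights badly.  Desk-scale
defaults are 10⁵ samples/epoch × 5 epochs at batch 512;
`TrainingConfig.full_scale()` gives the production schedule (10⁷ × 10 at
batch 20,000).  The hyperparameter grids (dropout {0.1, 0.2}, η {1e-3,
1e-4}, γ {0.75, 0.9, 1.0}, N {20k, 40k}, weighting on/off, oversampling
on/off; 96 combinations) are searched exhaustively by aggregated LOPO
validation accuracy.

Splitting: test pigs are drawn from the standardized subset by seeded
rejection sampling until every organ class is represented on both sides
(test side: standardized pigs; training side: all remaining pigs);
rejected draws are logged, and the sampler errors after a declared
attempt cap when the constraint is unsatisfiable.

Evaluation unit is the annotation.  Micro accuracy over all test
annotations; per-class one-vs-rest sensitivity/specificity/F1 computed
per pig (undefined entries — e.g. sensitivity of an organ the pig lacks —
are excluded, not zero-filled), macro-averaged within pig and reported as
mean ± SD across pigs; confusion matrices are column-normalized per pig
(columns = true class) and averaged entrywise across the pigs possessing
that class.  Argmax ties break to the lowest class index.

## Problem sizes used in the shipped runs

The analysis scripts and the acceptance script run the full standardized
cohort (11 pigs × 20 organs × 36 recordings = 7920 annotations) for
simulation, atlas and variance work, a 20-wavelength view (every 5th
camera band) for the per-wavelength model fits, bootstrap calibration at
5 pigs × 5 organs with B = 200 and 50 outer replicates, and classifier
runs on 9 pigs × 20 organs × 18 recordings with 12,800 samples/epoch × 2
epochs per fold — sizes chosen so a complete reproduction runs on a
single CPU in minutes while leaving every estimator at a scale where its
sampling error is far below the decision thresholds.

## Known limitations

- The generator draws effects independently per wavelength; smooth-band
  realism is an option, not the default, and no claim is made about real
  spectral covariance.
- The fast REML path requires equal repetitions per image; general
  unbalanced data use the slower statsmodels engine (no bootstrap bands).
- ENVI header/binary cube pairs are not read; the HDF5 container is the
  supported format.
- The embedding's quantitative tuning score replaces an inherently
  subjective visual criterion; different scores can prefer different
  hyperparameters.
- Fingerprint curves are synthetic stand-ins; atlases computed from them
  describe the generator, not porcine tissue.
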