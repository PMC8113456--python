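# Methods

This note documents the models, numerical conventions and design choices
behind `ftirchem`, and what the synthetic-cohort tests do and do not show
about real data.

## Data model

A `SpectrumSet` couples a validated wavenumber grid (strictly monotone,
uniform spacing within 1e-6 relative, positive; stored ascending or
descending — instruments export descending and all algorithms are
orientation-agnostic) with an `(n_spectra, n_points)` absorbance matrix
and per-spectrum metadata (`spectrum_id`, `sample_id`, `replicate_index`,
`class_label`, `biofluid`). Metadata joins at I/O time are fail-soft
(unmatched spectra keep null class labels); modelling fails hard on
missing labels instead. JCAMP-DX support covers AFFN-encoded
`##XYDATA=(X++(Y..Y))` and `##XYPOINTS` blocks only; SQZ/DIF compression
is a documented non-goal.

## Preprocessing

Default chain: fingerprint truncation (900–1800 cm⁻¹) → AWLS baseline →
unit-vector normalization → replicate averaging. A second profile
(`second_derivative_profile()`) inserts Savitzky–Golay second
differentiation (window 9, polyorder 2 by default) between baseline
correction and normalization; differentiation-before-normalization is the
package's fixed ordering. Replicate averaging runs after per-spectrum
preprocessing and before any split, so train/test partitions are disjoint
at the sample level by construction and replicate leakage is impossible.

**AWLS.** Realized as an iteratively reweighted Whittaker smoother with a
second-difference penalty: solve `(W + λ D₂ᵀD₂) z = W y`, then set
weights to 0 where `y − z > τ` (signal above baseline) and 1 otherwise,
until the weight vector stabilizes (at most `tol` changes, default 0) or
`max_iter` (20) is reached; non-convergence flags a warning, never an
exception. Defaults `λ = 1e5` for ~200–900-point spectra. Two numerical
details matter: points classed as signal keep a tiny weight (1e-6)
instead of exactly 0, and the sparse-LU solve applies one step of
iterative refinement — the system's condition number is on the order of
λ/weight-floor, and without these the recovered baseline of an exactly
linear input is off by ~1e-5 instead of ~1e-10. The signal threshold τ is
1e-8 of the spectrum's range rather than literal zero: on an exact
straight line, comparing against zero lets floating-point noise
reclassify every point as signal over the iterations and the weight set
collapses.

**Savitzky–Golay.** Delegated to `scipy.signal.savgol_filter` with the
derivative scaled by the signed grid spacing (odd orders need the sign on
descending grids) and `mode="interp"` edge handling. The second
derivative is exact for polynomials up to the fit order; for oscillatory
signals the quadratic fit underestimates curvature (≈5 % at 0.2 rad/point),
so the analytic-accuracy test uses a quartic.

**Centering.** `mean_center(train, apply_to)` always centers by training
column means; inside cross-validation the centering is fold-local. The
convention for held-out data is train-anchored throughout the package —
the alternative (centering on the pooled data) leaks test information
into the model.

## PCA and PLS

PCA is computed from the eigendecomposition of the covariance matrix
(Gram matrix when points outnumber samples), components ordered by
variance, with the sign convention "largest-magnitude loading element
positive" so results are platform-stable. The test suite checks it
against an SVD oracle — deliberately a different algorithm.

PLS1 is NIPALS with X- and y-deflation: `w ∝ Eᵀf`, `t = Ew`,
`p = Eᵀt/tᵀt`, `q = fᵀt/tᵀt`, deflate, repeat. With a single response
each component's weight vector is reached in one pass; extraction stops
early (and `n_lv` is reduced) if the residual response is numerically
exhausted. The collapsed coefficient vector `b = W (PᵀW)⁻¹ q` is the
published prediction path; the score-space path is retained and the two
are asserted to agree to 1e-10. At full rank PLS equals OLS, which the
suite asserts against `numpy.linalg.lstsq`, and the coefficients are also
cross-checked against an independent PLS implementation.

## Splitting and model selection

* **Kennard–Stone**: start from the maximal-distance pair, then greedily
  add the point with the largest minimum distance to the selected set.
  All ties (including duplicate rows) resolve to the lowest index, making
  the selection fully deterministic.
* **MLM split**: per class, Kennard–Stone selects
  `round(train_frac · n_class)` training samples (clamped to
  `[1, n_class − 1]`, half-up rounding), then `⌈mutation_frac · n_train⌉`
  uniformly chosen train/test pairs are swapped with the run seed.
  `mutation_frac = 0` reduces exactly to stratified Kennard–Stone;
  default 0.1. Distances are computed in the preprocessed spectral space.
* **Venetian blinds**: fold of sample *i* (training order) is `i mod k`,
  k = 10 by default; for each latent-variable count 1..20 every fold is
  predicted from a model fit on the others (fold-local centering), and
  the count with the highest pooled CV accuracy wins, ties to fewer
  variables. A fold losing a class records a warning and contributes
  chance-level predictions rather than aborting.
* **PLS-DA**: two-class only (multi-group contrasts are paired
  one-vs-one); reference class coded 0, positive class 1, threshold ½,
  scores exactly at the threshold go to the reference class. Reports are
  emitted in both class orientations, since sensitivity/specificity swap
  meaning depending on which group is treated as positive.

## Validation metrics

Rates are stored as fractions and formatted as percentages (1 decimal)
only at serialization; undefined ratios (empty denominators) are `None`,
never 0. The F-score is F₁ of the declared positive class. ROC curves
sweep unique scores descending; tied scores move TP and FP jointly, so
the trapezoidal AUC equals the Mann–Whitney pair statistic with half
credit for ties (asserted exactly in the tests).

## Biomarker extraction

Peaks are the strict local extrema of the coefficient (or loading)
vector — sign changes of the first difference — ranked by absolute value;
no amplitude threshold is imposed, matching how coefficient plots are
read in practice. Direction is the coefficient sign under the 0/1
encoding ("up" = elevated in the positive class). Assignments come from a
shipped wavenumber → band table (tolerance one grid spacing, 4 cm⁻¹),
extendable via TSV; unmatched peaks are labelled "unassigned".

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not radiative physics:

* grid 1800 → 900 cm⁻¹ at 4 cm⁻¹ (226 points), 25 "AD" + 38 "DR" samples,
  10 replicates each;
* Gaussian bands: 8 common plasma bands (Amide I/II dominant) shared by
  both classes, plus 7 discriminative bands whose amplitude is multiplied
  by `class_effect` in the active class (nucleic-acid bands up: 1716,
  1558, 948 cm⁻¹; lipid/protein/phosphate bands down: 1748, 1662, 1481,
  1230 cm⁻¹). Centers closer than ~2 grid spacings are represented by a
  single band so each injected effect is in principle resolvable; the
  1662 cm⁻¹ shoulder under the main Amide I band is the deliberately hard
  case;
* per-sample lognormal band-amplitude jitter (σ = 0.12, biological
  heterogeneity), per-replicate multiplicative scale jitter (σ = 0.04,
  ATR contact-pressure variation), linear + broad-sine baseline with a
  random phase per replicate, additive noise (σ = 0.003), clipped at zero
  absorbance;
* clinical covariates drawn per sample: albumin (g/L, class-specific
  means 34.7/44.4) multiplies the Amide I amplitude by
  `exp(0.25 · z)` — plasma protein content is what that band measures —
  while creatinine, a disease-activity score and a three-level antibody
  serotype are spectrally inert.

Default effect sizes (×1.40 up, ×0.72–0.80 down) are calibrated so the
default pipeline reaches a test AUC of roughly 0.9–1.0 at these cohort
sizes, comparable to the separation reported for real plasma cohorts of
this scale. Everything is a deterministic function of (config, seed).

What passing tests show: the pipeline recovers class structure, injected
band positions and directions, and covariate-band links from data with
realistic noise topology and cohort sizes, and stays at chance under the
null (note the null must also pool the covariate distributions across
classes — a class-linked covariate that drives a band is itself a class
effect). What they do not show: robustness to scattering artifacts,
water-vapour lines, Mie distortion, instrument drift between sessions, or
biofluid-specific matrix effects — real spectra differ in all of these.

## Clinical correlation

Continuous variables: venetian-blinds CV PLS regression, latent count
minimizing RMSECV, R² computed on the cross-validated predictions (can be
negative; capped at 1 by definition). Categorical variables (two levels;
callers binarize richer ones one-vs-rest): CV PLS-DA, latent count
maximizing CV accuracy, with CV sensitivity/specificity. Samples missing
the variable are dropped (coverage below 80 % is an error); no
significance verdict is attached to an R².

## Power and sample size

`fisher_power(n1, n2, p1, p2, α)` is the exact unconditional power of the
two-sided Fisher exact test: the conditional hypergeometric two-sided
p-value (sum of all table probabilities not exceeding the observed one,
with a 1e-7 relative fuzz against floating-point ties) defines the
rejection region per column-total, and binomial enumeration over both
groups (all log-space via `gammaln`) integrates it. The doubled-one-tail
and mid-p conventions are available by flag because published power
statements rarely say which rule produced them.

`required_sample_size` scans totals upward inside a doubling bracket and
returns the smallest total whose power reaches the target, with group
sizes `n1 = floor(share1 · total)`, `n2 = total − n1` — the floor
convention is what reproduces conventional reporting of unequal designs
(0.4:0.6 of 199 → 79 + 120). For 0.4 vs 0.6 at α = 0.05 and 80 % power
with 0.4:0.6 allocation the exact computation gives **208 (83 + 125)**;
power at (79, 120) is 0.774. An uncorrected normal-approximation search
(`method="normal"`) gives 197 (79 + 118), and continuity-corrected
approximations land near the exact 208 — the familiar spread among
conventions for this design. The package reports the exact number by
default and exposes the variants rather than blending them.

## Pipeline and reproducibility

`run_pipeline` writes every stage artifact as plain TSV/JSON (class-mean
raw spectra, preprocessed matrix, PCA scores/loadings, split and CV
manifests, per-partition classification reports in both orientations,
discriminant scores, CV and test ROC points, the coefficient vector,
ranked biomarker peaks, clinical correlations) plus a manifest with
SHA-256 checksums per artifact, per-stage timings and all consumed
sub-seeds (synthetic = seed, split mutation = seed + 1). Two runs with
the same config and seed produce identical checksums; floats in
artifacts are fixed-format for this reason. PCA outlier candidates are
flagged by Hotelling T² (F-distribution limit) and Q residual
(moment-matched g·χ²ₕ limit) at the 99 % level but never removed
automatically — removal is an explicit user action.

## Known limitations

* AWLS weight iteration can oscillate on noisy spectra and stop at
  `max_iter` with a warning; the resulting baseline is still usable.
* PLS1 only (single response); multiclass PLS2, sparse/penalized PLS and
  orthogonal-signal correction are out of scope.
* The venetian-blinds accuracy curve is discrete and can tie over long LV
  stretches; ties resolve to the smallest count, which occasionally picks
  a visibly underfit model on small cohorts (and noisy curves can pick a
  large, ringing one — visible as unstable minor coefficient peaks).
* JCAMP reading is limited to AFFN encodings.
* The synthetic generator's band library is plasma-like; serum/urine
  would need their own presets.
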