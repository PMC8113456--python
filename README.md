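# ftirchem

Chemometrics for mid-infrared biofluid spectroscopy, built around the
workflow used to separate **active from quiescent ANCA-associated
vasculitis** in plasma ATR-FTIR spectra: spectral preprocessing, PCA
exploration, Kennard–Stone/MLM sample selection, venetian-blinds
cross-validated PLS-DA classification, validation metrics with ROC/AUC,
spectral-biomarker extraction from model coefficients, clinical-variable
correlation, and exact Fisher power/sample-size analysis. A ground-truth
synthetic cohort generator stands in for patient spectra, so the entire
pipeline is testable end to end.

It is a library first (with an `examples/` directory of narrative
scripts), plus a thin `ftirchem` CLI for the workflows worth running from
a shell (`simulate`, `preprocess`, `power`, `run-all`).

## Who this is for

Biospectroscopy groups who classify disease states from infrared biofluid
spectra and want a tested, reproducible, pure-Python implementation of the
standard MATLAB/PLS-Toolbox-style chain — and methodologists who want the
numerical core (NIPALS PLS, Whittaker-type AWLS baseline, exact
unconditional Fisher power) exposed as plain functions with oracles in the
test suite.

## The model in brief

* **Preprocessing.** Spectra are truncated to the 900–1800 cm⁻¹
  fingerprint region; the baseline is removed by *automatic weighted least
  squares* (AWLS): iterate the Whittaker smoother
  `min_z Σᵢ wᵢ (yᵢ − zᵢ)² + λ ‖Δ²z‖²` with weights re-set each round to 0
  above the baseline (signal) and 1 at or below it; each spectrum is then
  scaled to unit Euclidean norm, and the replicate spectra of a sample are
  averaged. Savitzky–Golay second differentiation is available as an
  alternative profile for resolving overlapping peaks.
* **Classification.** PLS-DA: classes coded y ∈ {0, 1}, PLS1 by NIPALS
  with X-deflation, collapsed coefficients `b = W (PᵀW)⁻¹ q`, decision
  threshold ½. The train/test split is Morais–Lima–Martin (per-class
  Kennard–Stone coverage selection plus a seeded mutation step); the
  latent-variable count maximizes venetian-blinds (i mod k) CV accuracy.
  Mean-centering is always anchored on the training partition.
* **Validation.** Accuracy, sensitivity, specificity, precision, F₁ from
  the confusion matrix (both class orientations reported); ROC by
  descending-threshold sweep with trapezoidal AUC, which equals the
  Mann–Whitney concordant-pair statistic.
* **Interpretation.** Candidate biomarkers are the local extrema of the
  PLS-DA coefficient vector (or a PCA loading), ranked by |b|; sign gives
  the direction of change in the positive class; peaks are annotated from
  a band-assignment table (nucleic-acid carbonyl/phosphate bands, Amide
  I/II, lipid esters, phosphodiester region).
* **Clinical correlation.** Cross-validated PLS regression (continuous
  variables; R², RMSECV) or PLS-DA (categorical; CV sensitivity and
  specificity) between spectra and per-sample covariates.
* **Power.** Exact unconditional power of the two-sided Fisher exact
  test — enumerate binomial(n₁, p₁) × binomial(n₂, p₂) in log space, sum
  the probability of tables with p ≤ α — inverted to a smallest-total
  search at a fixed allocation ratio.

## Worked example

`python examples/classify_activity.py` simulates a 25-active vs
38-remission plasma cohort (10 replicate spectra per sample), preprocesses
it, and trains a PLS-DA model on the MLM 60 % split:

```
split: 38 train / 25 test, per class {'AD': {'train': 15, 'test': 10}, 'DR': {'train': 23, 'test': 15}}
venetian-blinds CV chose 3 latent variables (CV accuracy 100.0%)
test set: accuracy 92.0%, sensitivity 80.0% / specificity 100.0% (AD-positive), F-score 88.9%, AUC 1.000
```

The blind 40 % test set is classified with 92 % accuracy and AUC 1.0 —
the injected class-dependent band effects are recovered from held-out
data. `python examples/extract_biomarkers.py` then reads the answer key
back from the fitted model:

```
rank  cm^-1   dir   injected?  assignment
   1    1716  up    yes        nu(C=O) DNA/RNA
   2     948  up    yes        phosphodiester region (collagen and glycogen)
   3    1748  down  yes        nu(C=C) lipids
   ...
recovered 7/7 injected band centers within one grid spacing
```

All seven bands planted by the generator (nucleic-acid bands up in active
disease, protein/lipid/phosphate bands down) appear among the top-ranked
coefficient extrema, with the correct directions. The other examples cover
simulation, clinical correlation (the albumin-like covariate that drives
the Amide I band is found at R² ≈ 0.86 while spectrally inert covariates
stay low) and power analysis.

The full pipeline with artifacts and a checksummed manifest:

```bash
ftirchem run-all --seed 1 --out out/
```

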