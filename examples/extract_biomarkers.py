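"""Extract candidate spectral biomarkers from PLS-DA coefficients.

The local extrema of the regression coefficient vector, ranked by absolute
value, mark the wavenumbers that drive the class separation; positive
extrema are elevated in active disease, negative ones in remission. Peaks
are annotated with tentative mid-infrared band assignments.
"""

import warnings

import numpy as np

from ftirchem import (
    SyntheticConfig, assign_bands, generate_cohort, mlm_split,
    preprocess_spectra, rank_coefficient_peaks, train_plsda,
)

warnings.filterwarnings("ignore")

spectra, _, truth = generate_cohort(SyntheticConfig(seed=42))
prep = preprocess_spectra(spectra)
X = prep.absorbance
labels = prep.meta["class_label"].to_numpy()

split = mlm_split(X, labels, sample_ids=prep.meta["sample_id"].tolist(),
                  seed=43)
pos = {s: i for i, s in enumerate(prep.meta["sample_id"])}
tr = np.array([pos[s] for s in split.train_ids])
model = train_plsda(X[tr], labels[tr], n_lv=3, positive_label="AD")

peaks = assign_bands(rank_coefficient_peaks(model.pls.coef,
                                            prep.grid.values, top_n=10))
truth_centers = {c for c, _ in truth.discriminative_centers}
print("rank  cm^-1   dir   injected?  assignment")
for p in peaks:
    injected = any(abs(p.wavenumber - c) <= 4 for c in truth_centers)
    print(f"{p.rank:>4}  {p.wavenumber:6.0f}  {p.direction:<5} "
          f"{'yes' if injected else '-':<9}  {p.assignment}")
hit = sum(any(abs(c - p.wavenumber) <= 4 for p in peaks) for c in truth_centers)
print(f"\nrecovered {hit}/{len(truth_centers)} injected band centers "
      "within one grid spacing — the generator's answer key read back "
      "from the fitted classifier.")
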