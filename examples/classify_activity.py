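"""Classify disease activity from plasma-like spectra with PLS-DA.

Chain: preprocess (fingerprint cut, AWLS baseline, vector normalization,
replicate averaging) -> MLM 60/40 train-test split -> venetian-blinds CV to
pick the latent-variable count -> PLS-DA -> validation metrics and AUC.
"""

import warnings

import numpy as np

from ftirchem import (
    SyntheticConfig, confusion_metrics, generate_cohort, mlm_split,
    predict_plsda, preprocess_spectra, roc_auc, train_plsda,
    venetian_blinds_cv,
)

warnings.filterwarnings("ignore")

spectra, samples, truth = generate_cohort(SyntheticConfig(seed=42))
prep = preprocess_spectra(spectra)          # one averaged spectrum per sample
X = prep.absorbance
labels = prep.meta["class_label"].to_numpy()
ids = prep.meta["sample_id"].tolist()

split = mlm_split(X, labels, sample_ids=ids, train_frac=0.6,
                  mutation_frac=0.1, seed=43)
pos = {s: i for i, s in enumerate(ids)}
tr = np.array([pos[s] for s in split.train_ids])
te = np.array([pos[s] for s in split.test_ids])
print(f"split: {len(tr)} train / {len(te)} test, per class "
      f"{split.per_class_counts}")

cv = venetian_blinds_cv(X[tr], labels[tr], k=10, max_lv=20,
                        positive_label="AD")
print(f"venetian-blinds CV chose {cv.chosen_n_lv} latent variables "
      f"(CV accuracy {cv.accuracy_per_lv[cv.chosen_n_lv - 1]:.1%})")

model = train_plsda(X[tr], labels[tr], n_lv=cv.chosen_n_lv,
                    positive_label="AD")
scores, pred = predict_plsda(model, X[te])
rep = confusion_metrics(labels[te], pred, "AD", "DR", partition="test")
_, auc = roc_auc(labels[te], scores, "AD")

d = rep.to_dict()
print(f"test set: accuracy {d['accuracy']}%, sensitivity {d['sensitivity']}% "
      f"/ specificity {d['specificity']}% (AD-positive), "
      f"F-score {d['f_score']}%, AUC {auc:.3f}")
# Accuracy and AUC near 1 mean the injected class-dependent band effects
# are large enough to separate the groups from a blind 40% holdout.
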