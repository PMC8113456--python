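"""Shared fixtures.

The expensive Monte-Carlo studies (20-seed effect and null cohorts through
the full classify-and-interpret chain) are session-scoped so acceptance
tests and property tests share one computation.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ftirchem as fc
from ftirchem.synthetic import _COMMON_BANDS, _EFFECT_BANDS

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def scaled_effect_bands(scale: float) -> list:
    """Effect bands with |log class_effect| scaled by ``scale``."""
    return [
        replace(b, class_effect=float(np.exp(scale * np.log(b.class_effect))))
        for b in _EFFECT_BANDS
    ]


def pooled_clinical_variables() -> list:
    """Clinical covariates with class-independent distributions.

    Under a true null every class-dependent spectral pathway must vanish,
    including covariates (like albumin) that both differ by class and
    drive a band amplitude; pooling their per-class parameters keeps the
    realistic variance but removes the class information.
    """
    ns = {"AD": 25, "DR": 38}
    out = []
    for v in fc.default_clinical_variables():
        if v.kind == "continuous":
            w = np.array([ns[c] for c in v.params])
            means = np.array([v.params[c][0] for c in v.params])
            sds = np.array([v.params[c][1] for c in v.params])
            pooled = (float((w * means).sum() / w.sum()),
                      float((w * sds).sum() / w.sum()))
            out.append(replace(v, params={c: pooled for c in v.params}))
        else:
            levels = sorted({l for p in v.params.values() for l in p})
            w = np.array([ns[c] for c in v.params])
            pooled = {
                l: float(sum(ns[c] * v.params[c].get(l, 0.0) for c in v.params)
                         / w.sum())
                for l in levels
            }
            out.append(replace(v, params={c: dict(pooled) for c in v.params}))
    return out


def run_cohort_study(bands, seed: int, n_lv=None, clinical_variables=None) -> dict:
    """One full study on a synthetic cohort: generate -> preprocess ->
    MLM split -> venetian-blinds LV choice -> PLS-DA -> test metrics and
    top-10 coefficient peaks."""
    kwargs = {}
    if clinical_variables is not None:
        kwargs["clinical_variables"] = clinical_variables
    cfg = fc.SyntheticConfig(bands=list(_COMMON_BANDS) + list(bands), seed=seed,
                             **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sset, table, truth = fc.generate_cohort(cfg)
        pp = fc.preprocess_spectra(sset)
        X = pp.absorbance
        labels = pp.meta["class_label"].to_numpy()
        ids = pp.meta["sample_id"].tolist()
        split = fc.mlm_split(X, labels, sample_ids=ids, train_frac=0.6,
                             mutation_frac=0.1, seed=seed + 1)
        pos = {s: i for i, s in enumerate(ids)}
        tr = np.array([pos[s] for s in split.train_ids])
        te = np.array([pos[s] for s in split.test_ids])
        cv = fc.venetian_blinds_cv(X[tr], labels[tr], k=10, max_lv=20,
                                   positive_label="AD")
        model = fc.train_plsda(X[tr], labels[tr],
                               n_lv=n_lv or cv.chosen_n_lv,
                               positive_label="AD")
        scores, pred = fc.predict_plsda(model, X[te])
        _, auc = fc.roc_auc(labels[te], scores, "AD")
        rep = fc.confusion_metrics(labels[te], pred, "AD", "DR")
        peaks = fc.rank_coefficient_peaks(model.pls.coef, pp.grid.values, top_n=10)
    top10 = [p.wavenumber for p in peaks]
    centers = [c for c, _ in truth.discriminative_centers]
    recovered = [
        c for c in centers if any(abs(c - w) <= 4.0 for w in top10)
    ]
    return {
        "auc": auc,
        "test_accuracy": rep.accuracy,
        "chosen_n_lv": cv.chosen_n_lv,
        "top10": top10,  # ranked by |coefficient|, largest first
        "centers": centers,
        "recovery_frac": len(recovered) / len(centers) if centers else float("nan"),
    }


@pytest.fixture(scope="session")
def effect_mc():
    """20-seed study under the default (calibrated) effect bands."""
    return [run_cohort_study(_EFFECT_BANDS, seed) for seed in range(20)]


@pytest.fixture(scope="session")
def null_mc():
    """20-seed study with every class-dependent pathway removed: all
    class_effect = 1 and class-pooled clinical covariates."""
    pooled = pooled_clinical_variables()
    return [
        run_cohort_study(scaled_effect_bands(0.0), seed,
                         clinical_variables=pooled)
        for seed in range(20)
    ]


@pytest.fixture()
def small_set():
    """A tiny deterministic SpectrumSet for I/O and preprocessing tests."""
    rng = np.random.default_rng(7)
    grid = fc.WavenumberGrid(np.arange(1800.0, 896.0, -4.0))
    import pandas as pd

    meta = pd.DataFrame(
        {
            "spectrum_id": [f"sp{i}" for i in range(6)],
            "sample_id": ["a", "a", "a", "b", "b", "b"],
            "replicate_index": [1, 2, 3, 1, 2, 3],
            "class_label": ["AD"] * 3 + ["DR"] * 3,
            "biofluid": ["plasma"] * 6,
        }
    )
    return fc.SpectrumSet(grid=grid, absorbance=rng.random((6, grid.n)), meta=meta)
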