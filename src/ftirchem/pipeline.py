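"""End-to-end study workflow.

:func:`run_pipeline` chains the whole analysis — simulate (or ingest) ->
preprocess -> PCA exploration -> MLM train/test split -> venetian-blinds
latent-variable selection -> PLS-DA training -> validation metrics/ROC ->
biomarker peak extraction -> clinical-variable correlation — and writes
every result as a plain TSV/JSON artifact plus a manifest with per-stage
SHA-256 checksums, so two runs with the same config and seed are verifiably
identical.

Every random draw descends from the single run seed: the synthetic cohort
uses the seed itself and the split mutation uses seed + 1; both sub-seeds
are listed in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .biomarkers import assign_bands, peaks_to_frame, rank_coefficient_peaks
from .clinical import correlate_variable
from .decomposition import PCAModel, fit_pca
from .errors import ConfigError, DataError, FtirchemError
from .io import SampleTable, SpectrumSet, read_csv_matrix
from .metrics import build_report
from .model_selection import (
    mlm_split,
    predict_plsda,
    train_plsda,
    venetian_blinds_cv,
)
from .preprocess import PreprocessConfig, preprocess_spectra
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "flag_pca_outliers"]

#: the six per-figure-panel data files every run emits
PANEL_FILES = (
    "raw_mean_spectra.tsv",        # raw class-mean spectra
    "preprocessed_spectra.tsv",    # per-sample preprocessed spectra
    "pca_scores.tsv",              # PC1/PC2 scores with class labels
    "discriminant_scores.tsv",     # PLS-DA continuous scores per partition
    "roc_test.tsv",                # test-set ROC points
    "plsda_coefficients.tsv",      # regression coefficients over wavenumbers
)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    spectra_csv: str | None = None          # alternative to synthetic input
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train_frac: float = 0.6
    mutation_frac: float = 0.1
    cv_folds: int = 10
    max_lv: int = 20
    n_lv: int | None = None                 # None -> choose by CV
    positive_class: str = "AD"
    pca_components: int = 2
    top_n_peaks: int = 10
    correlate: bool = True
    seed: int = 0

    def __post_init__(self):
        if (self.synthetic is None) == (self.spectra_csv is None):
            raise ConfigError("provide exactly one of synthetic config or spectra_csv")
        if self.spectra_csv is not None and not Path(self.spectra_csv).exists():
            raise ConfigError(f"spectra file not found: {self.spectra_csv}")


@dataclass
class RunManifest:
    version: str
    seed: int
    sub_seeds: dict
    config: dict
    checksums: dict          # artifact file name -> sha256
    timings: dict            # stage name -> seconds
    warnings: list
    chosen_n_lv: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _config_dict(obj) -> dict:
    if is_dataclass(obj):
        return {
            k: _config_dict(v) if is_dataclass(v) else v
            for k, v in asdict(obj).items()
        }
    return obj


def flag_pca_outliers(model: PCAModel, level: float = 0.99, ids=None) -> list:
    """Spectra exceeding the Hotelling T^2 or Q-residual control limit.

    T^2 uses the F-distribution limit ``a (n^2 - 1) / (n (n - a)) *
    F_{a, n-a}(level)``; the Q (orthogonal residual) limit is a
    moment-matched g*chi2_h quantile of the training residuals. Flagging is
    advisory — removal is an explicit caller action, never automatic.
    """
    n, a = model.scores.shape
    if n < 5:
        raise DataError("need at least 5 samples for outlier limits")
    if not 0 < level < 1:
        raise ConfigError("level must lie in (0, 1)")
    lam = np.where(model.explained_variance > 0, model.explained_variance, np.inf)
    t2 = np.sum(model.scores ** 2 / lam, axis=1)
    t2_lim = a * (n ** 2 - 1) / (n * (n - a)) * stats.f.ppf(level, a, n - a)
    q = model.residual_ss
    flags = t2 > t2_lim
    mq = float(q.mean())
    vq = float(q.var(ddof=1))
    if mq > 0 and vq > 0:
        g = vq / (2 * mq)
        h = 2 * mq ** 2 / vq
        q_lim = g * stats.chi2.ppf(level, h)
        flags = flags | (q > q_lim)
    idx = np.where(flags)[0]
    if ids is None:
        return idx.tolist()
    ids = list(ids)
    return [ids[i] for i in idx]


def run_pipeline(config: RunConfig, out_dir) -> RunManifest:
    """Run the full workflow and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings_log: list[str] = []
    checksums: dict[str, str] = {}
    sub_seeds = {"synthetic": config.seed, "split_mutation": config.seed + 1}
    current_stage = {"name": None, "t0": 0.0}

    def _stage(name):
        current_stage["name"] = name
        current_stage["t0"] = time.perf_counter()

    def _done(name):
        timings[name] = round(time.perf_counter() - current_stage["t0"], 4)

    def _emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        checksums[name] = _sha256(path)

    try:
        # ------------------------------------------------ input
        _stage("input")
        table: SampleTable | None = None
        if config.synthetic is not None:
            sset, table, _truth = generate_cohort(config.synthetic,
                                                  seed=sub_seeds["synthetic"])
        else:
            sset = read_csv_matrix(config.spectra_csv)
        if sset.meta["class_label"].isna().all():
            raise DataError("input spectra carry no class labels")
        grid = sset.grid
        raw_means = (
            pd.DataFrame(sset.absorbance, index=sset.meta["class_label"])
            .groupby(level=0).mean()
        )
        _emit("raw_mean_spectra.tsv", lambda p: _write_tsv(
            pd.concat(
                [pd.Series(grid.values, name="wavenumber_cm-1"), raw_means.T.reset_index(drop=True)],
                axis=1,
            ), p))
        _done("input")

        # ------------------------------------------------ preprocess
        _stage("preprocess")
        pp = preprocess_spectra(sset, config.preprocess)
        X = pp.absorbance
        labels = pp.meta["class_label"].to_numpy()
        sample_ids = pp.meta["sample_id"].tolist()
        _emit("preprocessed_spectra.tsv", lambda p: _write_tsv(
            pd.concat(
                [
                    pd.Series(pp.grid.values, name="wavenumber_cm-1"),
                    pd.DataFrame(X.T, columns=sample_ids),
                ],
                axis=1,
            ), p))
        _done("preprocess")

        # ------------------------------------------------ PCA exploration
        _stage("pca")
        pca = fit_pca(X, min(config.pca_components, X.shape[0] - 1))
        _emit("pca_scores.tsv", lambda p: _write_tsv(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "class_label": labels,
                    **{
                        f"PC{j + 1}": pca.scores[:, j]
                        for j in range(pca.n_components)
                    },
                }
            ), p))
        _emit("pca_loadings.tsv", lambda p: _write_tsv(
            pd.concat(
                [
                    pd.Series(pp.grid.values, name="wavenumber_cm-1"),
                    pd.DataFrame(
                        pca.loadings,
                        columns=[f"PC{j + 1}" for j in range(pca.n_components)],
                    ),
                ],
                axis=1,
            ), p))
        outliers = flag_pca_outliers(pca, 0.99, ids=sample_ids) if X.shape[0] >= 5 else []
        if outliers:
            warnings_log.append(f"PCA T2/Q outlier candidates (not removed): {outliers}")
        _done("pca")

        # ------------------------------------------------ split
        _stage("split")
        split = mlm_split(X, labels, sample_ids=sample_ids,
                          train_frac=config.train_frac,
                          mutation_frac=config.mutation_frac,
                          seed=sub_seeds["split_mutation"])
        id_pos = {s: i for i, s in enumerate(sample_ids)}
        tr = np.array([id_pos[s] for s in split.train_ids])
        te = np.array([id_pos[s] for s in split.test_ids])
        _emit("split.json", lambda p: p.write_text(json.dumps(
            {
                "train_ids": [str(s) for s in split.train_ids],
                "test_ids": [str(s) for s in split.test_ids],
                "train_frac": split.train_frac,
                "mutation_frac": split.mutation_frac,
                "seed": split.seed,
                "per_class_counts": split.per_class_counts,
            }, indent=2, sort_keys=True)))
        _done("split")

        # ------------------------------------------------ CV + training
        _stage("train")
        cv = venetian_blinds_cv(X[tr], labels[tr], k=min(config.cv_folds, tr.size),
                                max_lv=config.max_lv,
                                positive_label=config.positive_class)
        warnings_log.extend(cv.warnings)
        n_lv = config.n_lv or cv.chosen_n_lv
        _emit("cv.json", lambda p: p.write_text(json.dumps(
            {
                "k": cv.k,
                "accuracy_per_lv": cv.accuracy_per_lv.tolist(),
                "chosen_n_lv": cv.chosen_n_lv,
                "used_n_lv": n_lv,
            }, indent=2, sort_keys=True)))
        model = train_plsda(X[tr], labels[tr], n_lv=n_lv,
                            positive_label=config.positive_class)
        _done("train")

        # ------------------------------------------------ validation
        _stage("validate")
        tr_scores, tr_pred = predict_plsda(model, X[tr])
        te_scores, te_pred = predict_plsda(model, X[te])
        # cross-validated class predictions at the chosen LV count
        cv_scores = np.empty(tr.size)
        for f in range(cv.k):
            hold = cv.fold_assignment == f
            sub = train_plsda(X[tr][~hold], labels[tr][~hold],
                              n_lv=min(n_lv, int((~hold).sum()) - 1),
                              positive_label=config.positive_class)
            cv_scores[hold] = predict_plsda(sub, X[tr][hold])[0]
        cv_pred = np.where(cv_scores > model.threshold,
                           model.positive_label, model.negative_label)
        reports = build_report(
            {
                "training": (labels[tr], tr_pred, tr_scores),
                "cross-validation": (labels[tr], cv_pred, cv_scores),
                "test": (labels[te], te_pred, te_scores),
            },
            positive_label=model.positive_label,
            negative_label=model.negative_label,
        )
        rows = []
        for tag, rep in reports.items():
            d = rep.to_dict()
            d_sw = rep.swapped().to_dict()
            d["sensitivity_ref_swapped"] = d_sw["sensitivity"]
            d["specificity_ref_swapped"] = d_sw["specificity"]
            rows.append(d)
        _emit("classification_report.tsv", lambda p: _write_tsv(pd.DataFrame(rows), p))
        _emit("classification_report.json", lambda p: p.write_text(
            json.dumps(rows, indent=2, sort_keys=True)))
        _emit("discriminant_scores.tsv", lambda p: _write_tsv(
            pd.DataFrame(
                {
                    "sample_id": [sample_ids[i] for i in np.concatenate([tr, te])],
                    "partition": ["train"] * tr.size + ["test"] * te.size,
                    "class_label": np.concatenate([labels[tr], labels[te]]),
                    "score": np.concatenate([tr_scores, te_scores]),
                }
            ), p))
        _emit("roc_test.tsv", lambda p: _write_tsv(
            pd.DataFrame(reports["test"].roc_points, columns=["fpr", "tpr"]), p))
        _emit("roc_cv.tsv", lambda p: _write_tsv(
            pd.DataFrame(reports["cross-validation"].roc_points,
                         columns=["fpr", "tpr"]), p))
        _done("validate")

        # ------------------------------------------------ biomarkers
        _stage("interpret")
        _emit("plsda_coefficients.tsv", lambda p: _write_tsv(
            pd.DataFrame(
                {"wavenumber_cm-1": pp.grid.values, "coefficient": model.pls.coef}
            ), p))
        peaks = assign_bands(
            rank_coefficient_peaks(model.pls.coef, pp.grid.values,
                                   top_n=config.top_n_peaks)
        )
        _emit("biomarker_peaks.tsv", lambda p: _write_tsv(peaks_to_frame(peaks), p))
        _done("interpret")

        # ------------------------------------------------ clinical correlation
        _stage("correlate")
        if config.correlate and table is not None and table.variable_types:
            crows = []
            tdata = table.data.set_index("sample_id").loc[sample_ids]
            for name, kind in table.variable_types.items():
                vals = tdata[name].tolist()
                try:
                    if kind == "categorical":
                        levels = sorted({v for v in vals if v == v}, key=str)
                        for lv in levels if len(levels) > 2 else [None]:
                            use = ([1 if v == lv else 0 for v in vals]
                                   if lv is not None else vals)
                            res = correlate_variable(
                                X, use, kind="categorical",
                                name=f"{name}={lv}" if lv else name,
                                k_folds=min(config.cv_folds, len(vals)),
                                max_lv=config.max_lv,
                            )
                            crows.append(asdict(res))
                    else:
                        res = correlate_variable(
                            X, vals, kind="continuous", name=name,
                            k_folds=min(config.cv_folds, len(vals)),
                            max_lv=config.max_lv,
                        )
                        crows.append(asdict(res))
                except FtirchemError as exc:
                    warnings_log.append(f"correlation {name!r} skipped: {exc}")
            _emit("clinical_correlations.tsv",
                  lambda p: _write_tsv(pd.DataFrame(crows), p))
        _done("correlate")

    except FtirchemError as exc:
        # abort with the stage name and a partial manifest on disk
        partial = RunManifest(
            version=_version(), seed=config.seed, sub_seeds=sub_seeds,
            config=_config_dict(config), checksums=checksums, timings=timings,
            warnings=warnings_log
            + [f"aborted in stage {current_stage['name']!r}: {exc}"],
        )
        (out / "manifest.json").write_text(partial.to_json())
        raise

    manifest = RunManifest(
        version=_version(), seed=config.seed, sub_seeds=sub_seeds,
        config=_config_dict(config), checksums=checksums, timings=timings,
        warnings=warnings_log, chosen_n_lv=n_lv,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
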