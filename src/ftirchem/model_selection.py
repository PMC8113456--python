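"""Sample selection, cross-validation and PLS-DA training.

* :func:`kennard_stone` — deterministic maximin coverage selection.
* :func:`mlm_split` — the Morais-Lima-Martin train/test split: per-class
  Kennard-Stone selection of the training fraction followed by a seeded
  random "mutation" step that swaps a fraction of train/test pairs, keeping
  coverage while reintroducing a randomized element. ``mutation_frac=0``
  reduces exactly to stratified Kennard-Stone.
* :func:`venetian_blinds_cv` — k-fold cross-validation with fold
  assignment ``i mod k`` in training order, used to choose the number of
  PLS latent variables (highest CV accuracy, ties to the smaller count).
* :func:`train_plsda` / :func:`predict_plsda` — two-class PLS-DA with 0/1
  class encoding and a 0.5 decision threshold on the continuous score.

All mean-centering inside CV is fold-local (training folds only), and the
outer model centers on the training partition only, so held-out data never
influences a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decomposition import PLSModel, fit_pls_nipals, predict_pls
from .errors import ConfigError, DataError, DegenerateDataError
from .metrics import confusion_metrics

__all__ = [
    "SplitResult",
    "CVResult",
    "DiscriminantModel",
    "kennard_stone",
    "mlm_split",
    "venetian_blinds_cv",
    "train_plsda",
    "predict_plsda",
]


def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Kennard-Stone maximin selection.

    Starts from the pair at maximal Euclidean distance, then greedily adds
    the point whose minimum distance to the selected set is largest.
    Deterministic: all distance ties resolve to the lowest index (for the
    starting pair, lexicographically smallest pair).
    Returns indices in selection order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim > 2:
        raise DataError("X must be a 2-D matrix")
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ConfigError(f"n_select must be in [2, {n}]")
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    # starting pair: maximal distance; exact ties -> lexicographically smallest
    iu, ju = np.triu_indices(n, k=1)
    flat = d2[iu, ju]
    maxval = flat.max()
    pairs = sorted(
        (int(iu[h]), int(ju[h])) for h in np.where(flat == maxval)[0]
    )
    selected = list(pairs[0])
    remaining = [i for i in range(n) if i not in selected]
    while len(selected) < n_select:
        dmin = d2[np.ix_(remaining, selected)].min(axis=1)
        k = int(np.argmax(dmin))  # argmax returns the first (lowest-index) max
        selected.append(remaining.pop(k))
    return np.array(selected, dtype=int)


@dataclass
class SplitResult:
    """A reproducible train/test partition over sample ids."""

    train_ids: list
    test_ids: list
    train_frac: float
    mutation_frac: float
    seed: int
    per_class_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise DataError("train and test partitions overlap")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def mlm_split(X: np.ndarray, labels, sample_ids=None, train_frac: float = 0.6,
              mutation_frac: float = 0.1, seed: int = 0) -> SplitResult:
    """Morais-Lima-Martin stratified split.

    Per class: Kennard-Stone selects ``round(train_frac * n_class)``
    training samples (clamped to [1, n_class - 1]); then
    ``ceil(mutation_frac * n_train_class)`` uniformly chosen train/test
    pairs are swapped using ``seed``. Classes are processed in sorted label
    order so the result is a pure function of (X, labels, seed).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(list(labels))
    if not 0 < train_frac < 1:
        raise ConfigError("train_frac must be in (0, 1)")
    if mutation_frac < 0:
        raise ConfigError("mutation_frac must be >= 0")
    if sample_ids is None:
        sample_ids = np.arange(X.shape[0])
    sample_ids = np.asarray(list(sample_ids))
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    counts: dict = {}
    for cls in sorted(set(labels.tolist()), key=str):
        idx = np.where(labels == cls)[0]
        if idx.size < 2:
            raise DataError(
                f"class {cls!r} has {idx.size} sample(s); need >= 2 for a stratified split"
            )
        n_train = min(max(_round_half_up(train_frac * idx.size), 1), idx.size - 1)
        sel = kennard_stone(X[idx], n_train) if n_train >= 2 else np.array(
            [0], dtype=int
        )
        cls_train = list(idx[sel])
        cls_test = [i for i in idx if i not in set(cls_train)]
        n_swap = int(np.ceil(mutation_frac * n_train)) if mutation_frac > 0 else 0
        for _ in range(n_swap):
            a = int(rng.integers(len(cls_train)))
            b = int(rng.integers(len(cls_test)))
            cls_train[a], cls_test[b] = cls_test[b], cls_train[a]
        train_idx.extend(cls_train)
        test_idx.extend(cls_test)
        counts[cls] = {"train": len(cls_train), "test": len(cls_test)}
    return SplitResult(
        train_ids=[sample_ids[i] for i in sorted(train_idx)],
        test_ids=[sample_ids[i] for i in sorted(test_idx)],
        train_frac=train_frac, mutation_frac=mutation_frac, seed=seed,
        per_class_counts=counts,
    )


@dataclass
class CVResult:
    k: int
    fold_assignment: np.ndarray
    accuracy_per_lv: np.ndarray   # index a-1 -> accuracy with a latent variables
    error_per_lv: np.ndarray
    chosen_n_lv: int
    warnings: list = field(default_factory=list)


def venetian_blinds_folds(n: int, k: int) -> np.ndarray:
    """Fold of sample i (in training order) is ``i mod k``."""
    return np.arange(n) % k


def venetian_blinds_cv(X: np.ndarray, labels, k: int = 10, max_lv: int = 20,
                       positive_label=None) -> CVResult:
    """Choose the PLS-DA latent-variable count by venetian-blinds CV.

    For each fold, a PLS-DA model is fit on the remaining folds (fold-local
    mean-centering included in the fit) and the held-out fold is classified
    at every component count 1..max_lv; the pooled accuracy curve selects
    the LV count (maximum accuracy, ties to fewer LVs). ``max_lv`` is
    clamped to what the smallest training complement can support.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(list(labels))
    n = X.shape[0]
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > n:
        raise ConfigError("more folds than samples")
    classes = sorted(set(labels.tolist()), key=str)
    if len(classes) != 2:
        raise DataError(f"venetian_blinds_cv needs exactly 2 classes, got {len(classes)}")
    if positive_label is None:
        positive_label = classes[-1]
    negative_label = [c for c in classes if c != positive_label][0]
    y = (labels == positive_label).astype(float)
    folds = venetian_blinds_folds(n, k)
    largest_fold = int(np.max(np.bincount(folds)))
    lv_cap = min(max_lv, n - largest_fold - 1, X.shape[1])
    if lv_cap < 1:
        raise ConfigError("not enough samples for even one latent variable")
    warnings_log: list[str] = []
    pred = np.empty((n, lv_cap))
    for f in range(k):
        hold = folds == f
        if len(set(labels[~hold])) < 2:
            warnings_log.append(f"fold {f}: training complement lost a class")
            pred[hold, :] = 0.5  # uninformative; counted as reference below
            continue
        if len(set(labels[hold])) < 2:
            warnings_log.append(f"fold {f}: held-out fold has a single class")
        a_max = min(lv_cap, int((~hold).sum()) - 1)
        model = fit_pls_nipals(X[~hold], y[~hold], n_lv=a_max)
        per_lv = model.predictions_per_component(X[hold])
        if model.n_lv < lv_cap:  # early stop: later LVs repeat the last fit
            per_lv = np.hstack(
                [per_lv, np.repeat(per_lv[:, -1:], lv_cap - model.n_lv, axis=1)]
            )
        pred[hold, :] = per_lv[:, :lv_cap]
    correct = (pred > 0.5) == (y[:, None] > 0.5)
    acc = correct.mean(axis=0)
    chosen = int(np.argmax(acc)) + 1  # argmax -> first max -> fewest LVs
    return CVResult(
        k=k, fold_assignment=folds, accuracy_per_lv=acc, error_per_lv=1 - acc,
        chosen_n_lv=chosen, warnings=warnings_log,
    )


@dataclass
class DiscriminantModel:
    """A PLS-DA classifier: embedded PLS1 model plus class decoding."""

    pls: PLSModel
    negative_label: object
    positive_label: object
    threshold: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must lie strictly between the class codes 0 and 1")


def train_plsda(X_train: np.ndarray, labels, n_lv: int,
                positive_label=None) -> DiscriminantModel:
    """Fit a two-class PLS-DA model with classes encoded 0/1."""
    labels = np.asarray(list(labels))
    classes = sorted(set(labels.tolist()), key=str)
    if len(classes) != 2:
        raise DataError(
            f"PLS-DA here is two-class; got {len(classes)} classes "
            "(pair the contrasts one-vs-one)"
        )
    if positive_label is None:
        positive_label = classes[-1]
    if positive_label not in classes:
        raise DataError(f"positive label {positive_label!r} not among {classes}")
    negative_label = [c for c in classes if c != positive_label][0]
    y = (labels == positive_label).astype(float)
    if np.ptp(y) == 0:
        raise DegenerateDataError("all labels identical: zero-variance response")
    pls = fit_pls_nipals(np.asarray(X_train, dtype=float), y, n_lv=n_lv)
    pls.class_encoding = {negative_label: 0.0, positive_label: 1.0}
    return DiscriminantModel(pls=pls, negative_label=negative_label,
                             positive_label=positive_label)


def predict_plsda(model: DiscriminantModel, X: np.ndarray):
    """Continuous discriminant scores and decoded labels.

    A score exactly at the threshold goes to the reference (negative)
    class.
    """
    scores = predict_pls(model.pls, X)
    labels = np.where(scores > model.threshold, model.positive_label,
                      model.negative_label)
    return scores, labels
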