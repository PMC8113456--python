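"""Spectra-to-clinical-variable association and Fisher-exact power analysis.

Association is quantified by cross-validated PLS regression for continuous
variables (R^2 and RMSECV of the cross-validated predictions) and by
cross-validated PLS-DA for two-level categorical variables (CV accuracy,
sensitivity and specificity), with the latent-variable count chosen by
venetian-blinds cross-validation in both cases. No significance verdict is
attached to an R^2; values are reported as computed.

The power half of the module computes the exact unconditional power of the
two-sided Fisher's exact test — enumerate binomial(n1, p1) x binomial(n2, p2)
outcomes in log space and sum the probability of tables whose Fisher
p-value is <= alpha — and inverts it to a smallest-total-sample-size search
at a fixed group allocation ratio. The conventional two-sided p-value (sum
of all table probabilities not exceeding the observed one) is the default;
the doubled-one-tail and mid-p variants, and an uncorrected
normal-approximation search, are available because published power
statements rarely say which convention produced them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ndtri

from .decomposition import fit_pls_nipals
from .errors import ConfigError, DataError, DegenerateDataError, SearchError
from .metrics import confusion_metrics
from .model_selection import venetian_blinds_folds

__all__ = [
    "CorrelationResult",
    "PowerSpec",
    "correlate_variable",
    "fisher_power",
    "required_sample_size",
]


# ---------------------------------------------------------------------------
# PLS / PLS-DA correlation with clinical variables
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    name: str
    kind: str                  # "continuous" | "categorical"
    n_lv: int
    r2: float                  # determination coefficient of CV predictions
    rmsecv: float              # in the variable's units (or class-code units)
    sensitivity: float | None = None
    specificity: float | None = None
    n_used: int = 0
    n_dropped: int = 0

    def __post_init__(self):
        if self.r2 > 1 + 1e-12:
            raise DataError("R^2 cannot exceed 1")
        if self.rmsecv < 0:
            raise DataError("RMSECV cannot be negative")


def _cv_predictions(X: np.ndarray, y: np.ndarray, k: int, max_lv: int) -> np.ndarray:
    """(n, max_lv) venetian-blinds CV predictions, fold-local centering."""
    n = X.shape[0]
    folds = venetian_blinds_folds(n, k)
    largest = int(np.max(np.bincount(folds)))
    lv_cap = min(max_lv, n - largest - 1, X.shape[1])
    if lv_cap < 1:
        raise ConfigError("not enough samples for cross-validation")
    pred = np.empty((n, lv_cap))
    for f in range(k):
        hold = folds == f
        model = fit_pls_nipals(
            X[~hold], y[~hold], n_lv=min(lv_cap, int((~hold).sum()) - 1)
        )
        per_lv = model.predictions_per_component(X[hold])
        if model.n_lv < lv_cap:
            per_lv = np.hstack(
                [per_lv, np.repeat(per_lv[:, -1:], lv_cap - model.n_lv, axis=1)]
            )
        pred[hold] = per_lv[:, :lv_cap]
    return pred


def correlate_variable(X: np.ndarray, values, kind: str, name: str = "",
                       k_folds: int = 10, max_lv: int = 20,
                       positive_level=None) -> CorrelationResult:
    """Cross-validated PLS(-DA) association between spectra and a variable.

    Samples with a missing value are dropped (the count is reported);
    at least 80% coverage is required. Continuous variables choose the LV
    count minimizing RMSECV; categorical (two-level) variables maximize CV
    accuracy and additionally report CV sensitivity/specificity.
    """
    X = np.asarray(X, dtype=float)
    values = np.asarray(list(values), dtype=object)
    if values.size != X.shape[0]:
        raise DataError("one value per spectrum row is required")
    if kind == "continuous":
        v = np.array([np.nan if x is None else float(x) for x in values])
        keep = np.isfinite(v)
    elif kind == "categorical":
        keep = np.array([x is not None and x == x for x in values])
    else:
        raise ConfigError(f"unknown variable kind {kind!r}")
    n_dropped = int((~keep).sum())
    if keep.sum() < 0.8 * values.size:
        raise DataError(
            f"variable {name!r} defined for {int(keep.sum())}/{values.size} samples "
            "(below the 80% coverage floor)"
        )
    X = X[keep]
    n = X.shape[0]
    k_folds = min(k_folds, n)

    if kind == "continuous":
        y = v[keep]
        if np.ptp(y) == 0:
            raise DegenerateDataError(f"variable {name!r} is constant")
        pred = _cv_predictions(X, y, k_folds, max_lv)
        rmse = np.sqrt(np.mean((pred - y[:, None]) ** 2, axis=0))
        a = int(np.argmin(rmse))  # first minimum -> fewest LVs
        sstot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((pred[:, a] - y) ** 2)) / sstot
        return CorrelationResult(
            name=name, kind=kind, n_lv=a + 1, r2=r2, rmsecv=float(rmse[a]),
            n_used=n, n_dropped=n_dropped,
        )

    labels = values[keep]
    levels = sorted(set(labels.tolist()), key=str)
    if len(levels) < 2:
        raise DegenerateDataError(f"variable {name!r} has a single level")
    if len(levels) > 2:
        raise DataError(
            f"variable {name!r} has {len(levels)} levels; binarize it "
            "(one level vs rest) before correlating"
        )
    if positive_level is None:
        positive_level = levels[-1]
    y = (labels == positive_level).astype(float)
    if np.ptp(y) == 0:
        raise DegenerateDataError(f"variable {name!r} is constant")
    pred = _cv_predictions(X, y, k_folds, max_lv)
    acc = (((pred > 0.5) == (y[:, None] > 0.5))).mean(axis=0)
    a = int(np.argmax(acc))
    y_pred = np.where(pred[:, a] > 0.5, 1.0, 0.0)
    rep = confusion_metrics(y.tolist(), y_pred.tolist(), positive_label=1.0,
                            negative_label=0.0)
    rmse = float(np.sqrt(np.mean((pred[:, a] - y) ** 2)))
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((pred[:, a] - y) ** 2)) / sstot
    return CorrelationResult(
        name=name, kind=kind, n_lv=a + 1, r2=r2, rmsecv=rmse,
        sensitivity=rep.sensitivity, specificity=rep.specificity,
        n_used=n, n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test: exact unconditional power and sample size
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Result of a sample-size search for two independent proportions."""

    p1: float
    p2: float
    alpha: float
    power_target: float
    allocation: tuple
    n1: int
    n2: int
    total: int
    achieved_power: float
    method: str


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _fisher_reject_table(n1: int, n2: int, alpha: float, rule: str) -> np.ndarray:
    """Boolean (n1+1, n2+1) rejection region of the two-sided Fisher test.

    Entry [x1, x2] is True when the table [[x1, n1-x1], [x2, n2-x2]] has a
    two-sided p-value <= alpha. ``rule`` selects the two-sided convention:
    "fisher" (sum of table probabilities <= observed), "doubling"
    (twice the smaller tail, capped at 1) or "midp" (observed probability
    counted half). All hypergeometric mass is computed in log space.
    """
    M = n1 + n2
    reject = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    for s in range(M + 1):
        k = np.arange(max(0, s - n2), min(n1, s) + 1)
        logpmf = _log_binom(s, k) + _log_binom(M - s, n1 - k) - _log_binom(M, n1)
        pmf = np.exp(logpmf)
        if rule in ("fisher", "midp"):
            order = np.argsort(pmf, kind="stable")
            sp = pmf[order]
            cs = np.cumsum(sp)
            # include every table whose probability is <= observed (with a
            # small relative fuzz against floating-point ties)
            idx = np.searchsorted(sp, pmf * (1 + 1e-7), side="right")
            pv = cs[idx - 1]
            if rule == "midp":
                pv = pv - 0.5 * pmf
        elif rule == "doubling":
            lo = np.cumsum(pmf)
            hi = np.cumsum(pmf[::-1])[::-1]
            pv = np.minimum(1.0, 2.0 * np.minimum(lo, hi))
        else:
            raise ConfigError(f"unknown two-sided rule {rule!r}")
        reject[k, s - k] = pv <= alpha
    return reject


def fisher_power(n1: int, n2: int, p1: float, p2: float, alpha: float = 0.05,
                 rule: str = "fisher") -> float:
    """Exact unconditional power of the two-sided Fisher's exact test.

    Enumerates all (x1, x2) outcomes of binomial(n1, p1) x binomial(n2, p2)
    and sums the probability of landing in the rejection region.
    """
    if n1 < 1 or n2 < 1:
        raise ConfigError("group sizes must be >= 1")
    for p in (p1, p2):
        if not 0 < p < 1:
            raise ConfigError("proportions must lie strictly in (0, 1)")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    reject = _fisher_reject_table(n1, n2, alpha, rule)
    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    b1 = np.exp(_log_binom(n1, x1) + x1 * np.log(p1) + (n1 - x1) * np.log1p(-p1))
    b2 = np.exp(_log_binom(n2, x2) + x2 * np.log(p2) + (n2 - x2) * np.log1p(-p2))
    return float(b1 @ reject @ b2)


def _split_total(total: int, allocation: tuple) -> tuple[int, int]:
    """Group sizes at a fixed allocation: n1 = floor(share1 * total).

    Floor on the first group reproduces the conventional reporting of
    unequal designs (e.g. 0.4:0.6 of 199 -> 79 + 120).
    """
    w1 = allocation[0] / (allocation[0] + allocation[1])
    n1 = max(1, int(np.floor(w1 * total)))
    n2 = total - n1
    if n2 < 1:
        raise ConfigError("total too small for the requested allocation")
    return n1, n2


def required_sample_size(p1: float, p2: float, alpha: float = 0.05,
                         power: float = 0.8, allocation: tuple = (0.4, 0.6),
                         method: str = "exact", rule: str = "fisher",
                         max_total: int = 1_000_000) -> PowerSpec:
    """Smallest total sample size reaching the target power.

    ``method="exact"`` inverts :func:`fisher_power` with a doubling bracket
    followed by a linear scan (power is monotone in n up to a small
    sawtooth from the discrete rejection region, so the scan covers the
    whole bracket). ``method="normal"`` uses the uncorrected two-proportion
    normal approximation and rounds each group up.
    """
    if not 0 < power < 1:
        raise ConfigError("power must lie in (0, 1)")
    if p1 == p2:
        raise ConfigError("p1 and p2 must differ for a sample-size search")
    if method == "normal":
        w1 = allocation[0] / (allocation[0] + allocation[1])
        w2 = 1 - w1
        za = ndtri(1 - alpha / 2)
        zb = ndtri(power)
        total_real = (za + zb) ** 2 * (
            p1 * (1 - p1) / w1 + p2 * (1 - p2) / w2
        ) / (p1 - p2) ** 2
        n1 = int(np.ceil(w1 * total_real))
        n2 = int(np.ceil(w2 * total_real))
        return PowerSpec(p1, p2, alpha, power, tuple(allocation), n1, n2,
                         n1 + n2, float("nan"), method)
    if method != "exact":
        raise ConfigError(f"unknown method {method!r}")

    def power_at(total: int) -> float:
        n1, n2 = _split_total(total, allocation)
        return fisher_power(n1, n2, p1, p2, alpha, rule=rule)

    lo, hi = 2, 3
    while power_at(hi) < power:
        lo, hi = hi, hi * 2
        if hi > max_total:
            raise SearchError(f"target power unreachable within total <= {max_total}")
    for total in range(lo + 1, hi + 1):
        pw = power_at(total)
        if pw >= power:
            n1, n2 = _split_total(total, allocation)
            return PowerSpec(p1, p2, alpha, power, tuple(allocation), n1, n2,
                             total, pw, method)
    raise SearchError("bracketing failed")  # pragma: no cover
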