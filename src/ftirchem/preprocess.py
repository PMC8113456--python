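"""Spectral preprocessing.

The default chain mirrors standard biofluid ATR-FTIR practice: truncate to
the 900-1800 cm^-1 fingerprint region, automatic weighted least squares
(AWLS) baseline correction, optional Savitzky-Golay second differentiation
to resolve overlapping peaks, unit vector normalization (removes effective
pathlength / crystal-contact variation), and averaging of the replicate
spectra of each sample so models are built on a per-sample basis.
Mean-centering is anchored on the training partition and applied unchanged
to held-out data, so no test-set information leaks into the model.

AWLS is realized as an iteratively reweighted Whittaker smoother with a
second-difference roughness penalty: points above the current baseline are
treated as signal (weight 0), points at or below it as baseline (weight 1),
until the weight vector stabilizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.signal import savgol_filter

from .errors import ConfigError, DataError, MetadataError, NormalizationError, RangeError
from .io import SpectrumSet, WavenumberGrid

__all__ = [
    "PreprocessConfig",
    "truncate_range",
    "awls_baseline",
    "awls_correct",
    "savgol_derivative",
    "vector_normalize",
    "average_replicates",
    "mean_center",
    "preprocess_spectra",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``sg_enabled`` is off in the default profile (baseline correction +
    vector normalization only) and on in the second-derivative profile;
    differentiation, when enabled, runs before normalization.
    """

    cut_lo: float = 900.0
    cut_hi: float = 1800.0
    awls_lam: float = 1e5
    awls_max_iter: int = 20
    awls_tol: int = 0  # max number of weight changes accepted as "stable"
    sg_enabled: bool = False
    sg_window: int = 9
    sg_polyorder: int = 2
    sg_deriv: int = 2
    normalize: bool = True
    average: bool = True

    def __post_init__(self):
        if not self.cut_lo < self.cut_hi:
            raise ConfigError("cut_lo must be < cut_hi")
        if self.awls_lam <= 0:
            raise ConfigError("AWLS lambda must be > 0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigError("SG window must be odd and > polyorder")
        if self.sg_deriv > self.sg_polyorder:
            raise ConfigError("SG derivative order must be <= polyorder")


def truncate_range(sset: SpectrumSet, lo: float, hi: float) -> SpectrumSet:
    """Keep exactly the grid points with ``lo <= wavenumber <= hi``."""
    v = sset.grid.values
    mask = (v >= lo) & (v <= hi)
    if mask.sum() < 2:
        raise RangeError(f"range [{lo}, {hi}] does not overlap the grid")
    return sset.copy_with(
        grid=WavenumberGrid(v[mask]), absorbance=sset.absorbance[:, mask]
    )


_DTD_CACHE: dict[int, sparse.csc_matrix] = {}

#: small positive weight given to signal points; keeps the penalized system
#: well conditioned without materially pulling the baseline upward
_SIGNAL_WEIGHT = 1e-6


def _second_diff_penalty(n: int) -> sparse.csc_matrix:
    """D2' D2 for the (n-2) x n second-difference matrix, cached by n."""
    if n not in _DTD_CACHE:
        d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
        _DTD_CACHE[n] = (d2.T @ d2).tocsc()
    return _DTD_CACHE[n]


def awls_baseline(y, lam: float = 1e5, max_iter: int = 20, tol: int = 0):
    """Automatic weighted least squares baseline for one spectrum.

    Solves ``(W + lam * D2'D2) z = W y`` with a second-difference penalty
    (Whittaker smoother); after each solve, weights are set to 0 where the
    residual ``y - z`` is positive (signal above baseline) and 1 elsewhere,
    and iteration stops once at most ``tol`` weights change.

    Returns ``(baseline, corrected, converged)``; non-convergence within
    ``max_iter`` sets ``converged=False`` and emits a warning rather than
    raising.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise DataError("awls_baseline expects a single spectrum")
    if not np.all(np.isfinite(y)):
        raise DataError("spectrum contains non-finite values")
    if lam <= 0:
        raise ConfigError("lambda must be > 0")
    n = y.size
    penalty = (lam * _second_diff_penalty(n)).tocsc()

    def _solve(w):
        wf = np.maximum(w, _SIGNAL_WEIGHT)
        a = (penalty + sparse.diags(wf)).tocsc()
        lu = splu(a)
        rhs = wf * y
        z = lu.solve(rhs)
        # one step of iterative refinement: the system is ill conditioned
        # (penalty scale lam vs. weight floor), refinement restores ~1e-10
        # accuracy on smooth inputs
        return z + lu.solve(rhs - a @ z)

    # points count as signal only when they sit above the baseline by more
    # than a numerical tolerance; without it an exact straight line loses
    # all its baseline points to floating-point noise over the iterations
    tau = 1e-8 * float(np.ptp(y))
    w = np.ones(n)
    converged = False
    for _ in range(max_iter):
        z = _solve(w)
        w_new = (y - z <= tau).astype(float)
        if w_new.sum() == 0:  # pathological: everything above the smooth fit
            w_new[np.argmin(y - z)] = 1.0
        changes = int(np.sum(w_new != w))
        w = w_new
        if changes <= tol:
            converged = True
            break
    if not converged:
        warnings.warn("AWLS weights did not stabilize within max_iter", stacklevel=2)
    z = _solve(w)
    return z, y - z, converged


def awls_correct(sset: SpectrumSet, lam: float = 1e5, max_iter: int = 20,
                 tol: int = 0) -> SpectrumSet:
    """Apply :func:`awls_baseline` to every spectrum of the set."""
    out = np.empty_like(sset.absorbance)
    for i in range(sset.n_spectra):
        _, out[i], _ = awls_baseline(sset.absorbance[i], lam, max_iter, tol)
    return sset.copy_with(absorbance=out)


def savgol_derivative(sset: SpectrumSet, window: int = 9, polyorder: int = 2,
                      deriv: int = 2) -> SpectrumSet:
    """Savitzky-Golay differentiation with respect to wavenumber.

    The derivative is scaled by the actual grid spacing (signed, so odd
    derivative orders are correct on descending grids); edge points use the
    one-sided polynomial fit (``mode="interp"``).
    """
    if window % 2 == 0 or polyorder < deriv:
        raise ConfigError("window must be odd and polyorder >= deriv")
    if window > sset.grid.n:
        raise ConfigError("SG window exceeds the number of grid points")
    sign = 1.0 if sset.grid.ascending else -1.0
    out = savgol_filter(
        sset.absorbance, window_length=window, polyorder=polyorder,
        deriv=deriv, delta=sset.grid.spacing, axis=1, mode="interp",
    ) * (sign ** deriv)
    return sset.copy_with(absorbance=out)


def vector_normalize(sset: SpectrumSet) -> SpectrumSet:
    """Scale each spectrum to unit Euclidean norm."""
    norms = np.linalg.norm(sset.absorbance, axis=1)
    bad = np.where(norms == 0)[0]
    if bad.size:
        raise NormalizationError(
            f"zero-norm spectrum: {sset.spectrum_ids[bad[0]]!r}"
        )
    return sset.copy_with(absorbance=sset.absorbance / norms[:, None])


def average_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Arithmetic mean of the replicate spectra of each sample.

    The result has one spectrum per ``sample_id`` (in first-appearance
    order) and sample-level metadata; conflicting class labels within a
    sample are an error.
    """
    meta = sset.meta
    if meta["sample_id"].isna().any():
        raise MetadataError("every spectrum needs a sample_id to be averaged")
    order = meta["sample_id"].drop_duplicates().tolist()
    rows = []
    recs = []
    for sid in order:
        idx = np.where((meta["sample_id"] == sid).to_numpy())[0]
        labels = set(meta.iloc[idx]["class_label"].dropna())
        if len(labels) > 1:
            raise MetadataError(f"conflicting class labels for sample {sid!r}: {sorted(labels)}")
        fluids = set(meta.iloc[idx]["biofluid"].dropna())
        rows.append(sset.absorbance[idx].mean(axis=0))
        recs.append(
            {
                "spectrum_id": sid,
                "sample_id": sid,
                "replicate_index": 1,
                "class_label": labels.pop() if labels else None,
                "biofluid": fluids.pop() if len(fluids) == 1 else None,
                "n_replicates": len(idx),
            }
        )
    return SpectrumSet(grid=sset.grid, absorbance=np.vstack(rows), meta=pd.DataFrame(recs))


def mean_center(train: np.ndarray, apply_to: np.ndarray | None = None):
    """Center by the column means of ``train``; shift ``apply_to`` by the same.

    Returns ``(centered_train, centered_apply, mean_vector)``;
    ``centered_apply`` is ``None`` when ``apply_to`` is.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] == 0:
        raise DataError("mean_center needs a non-empty 2-D training matrix")
    mean = train.mean(axis=0)
    centered_apply = None
    if apply_to is not None:
        apply_to = np.asarray(apply_to, dtype=float)
        if apply_to.shape[1] != train.shape[1]:
            raise DataError("column count mismatch between train and apply_to")
        centered_apply = apply_to - mean
    return train - mean, centered_apply, mean


def preprocess_spectra(sset: SpectrumSet, config: PreprocessConfig | None = None) -> SpectrumSet:
    """Run the configured chain: cut -> AWLS -> [2nd derivative] -> vector
    norm -> replicate averaging. A pure function of its inputs."""
    cfg = config or PreprocessConfig()
    out = truncate_range(sset, cfg.cut_lo, cfg.cut_hi)
    out = awls_correct(out, cfg.awls_lam, cfg.awls_max_iter, cfg.awls_tol)
    if cfg.sg_enabled:
        out = savgol_derivative(out, cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv)
    if cfg.normalize:
        out = vector_normalize(out)
    if cfg.average:
        out = average_replicates(out)
    return out


def second_derivative_profile(**overrides) -> PreprocessConfig:
    """Preprocessing profile with Savitzky-Golay second differentiation on."""
    return replace(PreprocessConfig(sg_enabled=True), **overrides)
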