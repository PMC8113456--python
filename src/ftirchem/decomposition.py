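"""Principal component analysis and NIPALS partial least squares.

Both decompositions are written from first principles so every number the
rest of the package consumes (scores, loadings, regression coefficients) is
fully specified here:

* PCA by eigendecomposition of the covariance (or Gram, when points
  outnumber samples) matrix, components ordered by variance with a fixed
  sign convention (largest-magnitude loading element positive).
* PLS1 by NIPALS with X-deflation; the per-component weights/loadings
  (W, P, q) are collapsed to a single coefficient vector
  ``b = W (P'W)^-1 q`` over wavenumbers, which is what biomarker
  extraction reads.

There is no randomness anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError, DegenerateDataError

__all__ = ["PCAModel", "PLSModel", "fit_pca", "fit_pls_nipals", "predict_pls"]


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray              # (n_points, n_components), orthonormal
    explained_variance: np.ndarray    # per-component variance
    explained_variance_ratio: np.ndarray
    scores: np.ndarray                # (n_samples, n_components)
    residual_ss: np.ndarray           # per-training-sample squared residual norm

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean.size:
            raise DataError("column count mismatch with the fitted PCA")
        return (X - self.mean) @ self.loadings

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.loadings.T + self.mean


def _fix_signs(loadings: np.ndarray, scores: np.ndarray | None = None):
    """Make the largest-magnitude element of each loading vector positive."""
    for j in range(loadings.shape[1]):
        idx = np.argmax(np.abs(loadings[:, j]))
        if loadings[idx, j] < 0:
            loadings[:, j] = -loadings[:, j]
            if scores is not None:
                scores[:, j] = -scores[:, j]
    return loadings, scores


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA with ``n_components`` components.

    Components are ordered by decreasing variance; ties in eigenvalues keep
    the eigensolver order. A constant (zero total variance) matrix raises
    :class:`DegenerateDataError`.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ConfigError(
            f"n_components must be in [1, min(n_samples-1, n_points)] = "
            f"[1, {min(n - 1, p)}]"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float(np.sum(Xc ** 2)) / (n - 1)
    if total_var <= 0:
        raise DegenerateDataError("constant matrix: no variance to decompose")
    if p <= n:
        cov = Xc.T @ Xc / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:n_components]
        lam = np.clip(evals[order], 0.0, None)
        loadings = evecs[:, order]
    else:
        gram = Xc @ Xc.T / (n - 1)
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1][:n_components]
        lam = np.clip(evals[order], 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            loadings = Xc.T @ evecs[:, order] / np.sqrt((n - 1) * lam)[None, :]
        loadings = np.nan_to_num(loadings)
    scores = Xc @ loadings
    loadings, scores = _fix_signs(loadings, scores)
    resid = Xc - scores @ loadings.T
    return PCAModel(
        mean=mean,
        loadings=loadings,
        explained_variance=lam,
        explained_variance_ratio=lam / total_var,
        scores=scores,
        residual_ss=np.sum(resid ** 2, axis=1),
    )


@dataclass
class PLSModel:
    """NIPALS PLS1 model.

    ``coef`` is the collapsed regression vector over wavenumbers; the
    score-space path through (``weights``, ``loadings``, ``y_loadings``)
    gives identical predictions and is kept for diagnostics.
    """

    n_lv: int
    weights: np.ndarray        # W: (n_points, n_lv)
    loadings: np.ndarray       # P: (n_points, n_lv)
    y_loadings: np.ndarray     # q: (n_lv,)
    scores: np.ndarray         # T: (n_samples, n_lv)
    coef: np.ndarray           # b: (n_points,)
    x_mean: np.ndarray
    y_mean: float
    converged: list[bool] = field(default_factory=list)
    class_encoding: dict | None = None

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict_pls(self, X_new)

    def predict_via_scores(self, X_new: np.ndarray) -> np.ndarray:
        """Prediction through sequential score projection (W, P, q path)."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != self.x_mean.size:
            raise DataError("column count mismatch with the fitted PLS model")
        E = X_new - self.x_mean
        yhat = np.full(X_new.shape[0], self.y_mean)
        for a in range(self.n_lv):
            t = E @ self.weights[:, a]
            yhat = yhat + t * self.y_loadings[a]
            E = E - np.outer(t, self.loadings[:, a])
        return yhat

    def predictions_per_component(self, X_new: np.ndarray) -> np.ndarray:
        """(n_samples, n_lv) cumulative predictions after 1..n_lv components."""
        X_new = np.asarray(X_new, dtype=float)
        E = X_new - self.x_mean
        out = np.empty((X_new.shape[0], self.n_lv))
        yhat = np.full(X_new.shape[0], self.y_mean)
        for a in range(self.n_lv):
            t = E @ self.weights[:, a]
            yhat = yhat + t * self.y_loadings[a]
            E = E - np.outer(t, self.loadings[:, a])
            out[:, a] = yhat
        return out


def fit_pls_nipals(X: np.ndarray, y: np.ndarray, n_lv: int,
                   tol: float = 1e-10, max_iter: int = 500) -> PLSModel:
    """Fit a PLS1 regression by NIPALS with X- and y-deflation.

    X and y are centered internally (training means are stored on the
    model). With a single response the NIPALS weight vector for each
    component is reached in one pass; ``tol``/``max_iter`` bound the
    residual-weight norm below which extraction stops early (components
    after a perfect fit would be numerical noise and are dropped, with
    ``n_lv`` reduced accordingly).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise DataError("X row count and y length differ")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ConfigError(f"n_lv must be in [1, {min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise DegenerateDataError("zero-variance response")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    converged: list[bool] = []
    a_used = 0
    for a in range(n_lv):
        w = E.T @ f
        wnorm = np.linalg.norm(w)
        if wnorm < max(tol, 1e-14) * max(1.0, np.linalg.norm(f)):
            break  # response fully explained
        w /= wnorm
        t = E @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p_a = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        converged.append(True)
        a_used += 1
    if a_used == 0:
        raise DegenerateDataError("X carries no covariance with y")
    W, P, q, T = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_lv=a_used, weights=W, loadings=P, y_loadings=q, scores=T,
        coef=coef, x_mean=x_mean, y_mean=y_mean, converged=converged,
    )


def predict_pls(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """``yhat = y_mean + (X_new - x_mean) @ b``."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.x_mean.size:
        raise DataError("column count mismatch with the fitted PLS model")
    return model.y_mean + (X_new - model.x_mean) @ model.coef
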