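"""Partial least squares regression by NIPALS, with cross-validated
latent-variable selection.

The model decomposes mean-centered X and Y into latent variables::

    X = T P' + E        Y = U Q' + F

with unit-norm weight columns W, mutually orthogonal score columns T,
and regression coefficients B = W (P'W)^-1 Q', so prediction is the
centered linear map  y_hat = y_mean + (X - x_mean) B.

NIPALS is used (rather than SIMPLS) because variable-importance scoring
and the sequential multiblock models need the per-component weights W
and exactly nested component paths: the first ``a`` components of a
``max_lv`` fit are the ``a``-component fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "CVResult", "fit_pls", "predict", "select_lv", "make_folds"]

_EPS = np.finfo(float).eps


def _nipals(X0: np.ndarray, Y0: np.ndarray, n_lv: int, tol: float = 1e-12, max_iter: int = 500):
    """NIPALS on pre-centered X0, Y0.  Returns (W, T, P, U, Q, n_fitted)."""
    n, p = X0.shape
    q_resp = Y0.shape[1]
    X, Y = X0.copy(), Y0.copy()
    W = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    P = np.zeros((p, n_lv))
    U = np.zeros((n, n_lv))
    Q = np.zeros((q_resp, n_lv))
    x_ss0 = float(np.sum(X0 * X0))
    a = 0
    for a in range(n_lv):
        if np.sum(X * X) <= max(x_ss0, 1.0) * 1e-14:
            warnings.warn(
                f"X residual exhausted after {a} latent variables "
                f"(requested {n_lv}); truncating",
                stacklevel=3,
            )
            return W[:, :a], T[:, :a], P[:, :a], U[:, :a], Q[:, :a], a
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        if not np.any(u):
            warnings.warn(
                f"Y residual exhausted after {a} latent variables "
                f"(requested {n_lv}); truncating",
                stacklevel=3,
            )
            return W[:, :a], T[:, :a], P[:, :a], U[:, :a], Q[:, :a], a
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            w_norm = np.linalg.norm(w)
            if w_norm <= _EPS:
                break
            w /= w_norm
            t = X @ w
            tt = float(t @ t)
            if tt <= _EPS:
                break
            q = Y.T @ t / tt
            if q_resp == 1:
                t_old = t
                break  # single response: converged in one pass
            qq = float(q @ q)
            u = Y @ q / qq if qq > _EPS else u
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                t_old = t
                break
            t_old = t
        t = t_old if t_old is not None else X @ w
        tt = float(t @ t)
        if tt <= _EPS:
            return W[:, :a], T[:, :a], P[:, :a], U[:, :a], Q[:, :a], a
        p_load = X.T @ t / tt
        q_load = Y.T @ t / tt
        qq = float(q_load @ q_load)
        u_score = Y @ q_load / qq if qq > _EPS else np.zeros(n)
        W[:, a], T[:, a], P[:, a], Q[:, a], U[:, a] = w, t, p_load, q_load, u_score
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, q_load)
    return W, T, P, U, Q, n_lv


@dataclass(frozen=True)
class PLSModel:
    """Fitted NIPALS PLS model (single or multi response)."""

    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray  # channels x LV, unit-norm columns
    T: np.ndarray  # samples x LV, orthogonal columns
    P: np.ndarray  # channels x LV
    U: np.ndarray  # samples x LV
    Q: np.ndarray  # responses x LV
    n_lv: int

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def rotations(self) -> np.ndarray:
        """W* = W (P'W)^-1: maps centered X to scores T in one step."""
        if self.n_lv == 0:
            return np.zeros((self.n_channels, 0))
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients B with y_hat = y_mean + (X - x_mean) B."""
        return self.rotations @ self.Q.T

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_channels:
            raise ValueError(
                f"channel mismatch: model has {self.n_channels}, input has {X.shape[1]}"
            )
        return (X - self.x_mean) @ self.rotations

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_channels:
            raise ValueError(
                f"channel mismatch: model has {self.n_channels}, input has {X.shape[1]}"
            )
        return self.y_mean + (X - self.x_mean) @ self.coef

    def truncate(self, a: int) -> "PLSModel":
        """First ``a`` components (NIPALS paths are exactly nested)."""
        if not 0 <= a <= self.n_lv:
            raise ValueError(f"cannot truncate {self.n_lv}-LV model to {a}")
        return PLSModel(
            x_mean=self.x_mean,
            y_mean=self.y_mean,
            W=self.W[:, :a],
            T=self.T[:, :a],
            P=self.P[:, :a],
            U=self.U[:, :a],
            Q=self.Q[:, :a],
            n_lv=a,
        )

    def explained_y_ss(self) -> np.ndarray:
        """Per-component explained Y sum of squares, ||t_a||^2 ||q_a||^2."""
        return np.sum(self.T**2, axis=0) * np.sum(self.Q**2, axis=0)

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "W": self.W.tolist(),
            "T": self.T.tolist(),
            "P": self.P.tolist(),
            "U": self.U.tolist(),
            "Q": self.Q.tolist(),
            "n_lv": self.n_lv,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], float),
            y_mean=np.asarray(d["y_mean"], float),
            W=np.asarray(d["W"], float),
            T=np.asarray(d["T"], float),
            P=np.asarray(d["P"], float),
            U=np.asarray(d["U"], float),
            Q=np.asarray(d["Q"], float),
            n_lv=int(d["n_lv"]),
        )

    @classmethod
    def load(cls, path) -> "PLSModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _as_2d_y(Y) -> np.ndarray:
    Y = np.asarray(Y, float)
    return Y[:, None] if Y.ndim == 1 else Y


def fit_pls(X: np.ndarray, Y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit a PLS model with ``n_lv`` latent variables after mean-centering.

    If X runs out of rank before ``n_lv`` components the model is
    truncated with a warning.
    """
    X = np.asarray(X, float)
    Y = _as_2d_y(Y)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"X has {n} rows but Y has {Y.shape[0]}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
        raise ValueError("fit_pls: missing or non-finite values")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(
            f"n_lv must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {n_lv}"
        )
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    W, T, P, U, Q, a = _nipals(X - x_mean, Y - y_mean, n_lv)
    return PLSModel(x_mean=x_mean, y_mean=y_mean, W=W, T=T, P=P, U=U, Q=Q, n_lv=a)


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Deterministic linear prediction for new spectra."""
    return model.predict(X_new)


@dataclass(frozen=True)
class CVResult:
    """Cross-validation curve and the chosen latent-variable count."""

    rmsecv: np.ndarray  # indexed by LV count - 1
    r2cv: np.ndarray
    n_lv: int
    folds: tuple  # fold assignment, per sample
    seed: int
    max_lv: int = field(default=0)

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv[self.n_lv - 1])


def make_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Contiguous fold labels after a seeded shuffle."""
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    if n < 2 * folds:
        raise ValueError(f"{folds}-fold CV needs at least {2 * folds} samples, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    labels = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, folds)):
        labels[chunk] = f
    return labels


def select_lv(
    X: np.ndarray, Y: np.ndarray, max_lv: int = 20, folds: int = 10, seed: int = 0
) -> CVResult:
    """Choose the LV count minimizing k-fold RMSECV (ties: fewer LVs)."""
    X = np.asarray(X, float)
    Y = _as_2d_y(Y)
    n = X.shape[0]
    labels = make_folds(n, folds, seed)
    max_lv = min(max_lv, X.shape[1], n - int(np.bincount(labels).max()) - 1)
    if max_lv < 1:
        raise ValueError("max_lv reduced below 1 by sample/channel limits")
    preds = np.zeros((max_lv, n, Y.shape[1]))
    for f in range(folds):
        test = labels == f
        train = ~test
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rank truncation inside folds is fine
            model = fit_pls(X[train], Y[train], max_lv)
        for a in range(1, max_lv + 1):
            sub = model.truncate(min(a, model.n_lv))
            preds[a - 1, test] = sub.predict(X[test])
    resid = preds - Y[None, :, :]
    rmsecv = np.sqrt(np.mean(resid**2, axis=(1, 2)))
    ss_tot = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    r2cv = 1.0 - np.sum(resid**2, axis=(1, 2)) / ss_tot
    best = int(np.argmin(rmsecv)) + 1  # argmin takes the first = fewest LVs
    return CVResult(
        rmsecv=rmsecv, r2cv=r2cv, n_lv=best, folds=tuple(labels.tolist()),
        seed=seed, max_lv=max_lv,
    )
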