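"""Sequential orthogonalized PLS (SOPLS) for two predictor blocks.

The model  Y = X1 B1 + X2 C2 + E  is fitted sequentially:

1. fit Y to X1 by PLS with a1 latent variables;
2. orthogonalize centered X2 against the X1 scores T1, giving X2orth;
3. fit the step-1 Y residuals to X2orth by PLS with a2 latent variables;
4. predict by summing the two stage predictions.

Because stage 2 sees only what X1 could not explain, the contribution
of each block is incremental and the fit is invariant to the relative
scale of the blocks.  Block 1 defaults to the more informative sensor
(MIR first, XRF second in the soil-fusion workflow), but the functions
are block-agnostic.

The (a1, a2) pair is chosen by an exhaustive cross-validated grid
search in which centering, orthogonalization and both stage fits are
redone inside every fold, so no test-fold statistics leak into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pls import PLSModel, fit_pls, make_folds

__all__ = ["SOPLSModel", "SOPLSCVResult", "fit_sopls", "predict_sopls", "select_lv_grid"]

_PINV_RCOND = 1e-10


@dataclass(frozen=True)
class SOPLSModel:
    """Two-block sequential model: stage-1 PLS, orthogonalizer, stage-2 PLS."""

    block1: PLSModel | None  # None when a1 = 0
    block2: PLSModel | None  # None when a2 = 0
    x2_mean: np.ndarray
    ortho_coef: np.ndarray  # (a1 x p2) least-squares map T1 -> centered X2
    y_mean: np.ndarray
    a1: int
    a2: int

    def _stage_inputs(self, X1_new: np.ndarray, X2_new: np.ndarray):
        X1_new = np.atleast_2d(np.asarray(X1_new, float))
        X2_new = np.atleast_2d(np.asarray(X2_new, float))
        X2c = X2_new - self.x2_mean
        if self.block1 is not None:
            t1 = self.block1.scores(X1_new)
            X2orth = X2c - t1 @ self.ortho_coef
        else:
            X2orth = X2c
        return X1_new, X2orth

    def predict(self, X1_new: np.ndarray, X2_new: np.ndarray) -> np.ndarray:
        """Sum of the stage-1 and stage-2 predictions."""
        X1_new, X2orth = self._stage_inputs(X1_new, X2_new)
        n = X2orth.shape[0]
        y1 = (
            self.block1.predict(X1_new)
            if self.block1 is not None
            else np.tile(self.y_mean, (n, 1))
        )
        y2 = self.block2.predict(X2orth) if self.block2 is not None else 0.0
        return y1 + y2

    def stage_predictions(self, X1_new, X2_new) -> tuple[np.ndarray, np.ndarray]:
        """(stage-1 prediction, stage-2 increment); their sum is predict()."""
        X1_new, X2orth = self._stage_inputs(X1_new, X2_new)
        n = X2orth.shape[0]
        y1 = (
            self.block1.predict(X1_new)
            if self.block1 is not None
            else np.tile(self.y_mean, (n, 1))
        )
        y2 = (
            self.block2.predict(X2orth)
            if self.block2 is not None
            else np.zeros_like(y1)
        )
        return y1, y2


def _as_2d(Y) -> np.ndarray:
    Y = np.asarray(Y, float)
    return Y[:, None] if Y.ndim == 1 else Y


def fit_sopls(
    X1: np.ndarray, X2: np.ndarray, Y: np.ndarray, a1: int, a2: int
) -> SOPLSModel:
    """Fit the two-block sequential model with fixed LV counts (a1, a2)."""
    X1 = np.asarray(X1, float)
    X2 = np.asarray(X2, float)
    Y = _as_2d(Y)
    n = Y.shape[0]
    if X1.shape[0] != n or X2.shape[0] != n:
        raise ValueError(
            f"sample mismatch: X1 has {X1.shape[0]}, X2 has {X2.shape[0]}, "
            f"Y has {n} rows"
        )
    if a1 < 0 or a2 < 0:
        raise ValueError(f"LV counts must be >= 0, got a1={a1}, a2={a2}")
    if a1 == 0 and a2 == 0:
        raise ValueError("a1 = a2 = 0 would be an empty model")

    y_mean = Y.mean(axis=0)
    x2_mean = X2.mean(axis=0)
    X2c = X2 - x2_mean

    if a1 > 0:
        m1 = fit_pls(X1, Y, a1)
        resid = Y - m1.predict(X1)
        t1 = m1.T
        # least-squares projection of centered X2 onto the stage-1 scores
        ortho_coef = np.linalg.pinv(t1, rcond=_PINV_RCOND) @ X2c
        X2orth = X2c - t1 @ ortho_coef
    else:
        m1 = None
        resid = Y - y_mean
        ortho_coef = np.zeros((0, X2.shape[1]))
        X2orth = X2c

    m2 = fit_pls(X2orth, resid, a2) if a2 > 0 else None
    return SOPLSModel(
        block1=m1,
        block2=m2,
        x2_mean=x2_mean,
        ortho_coef=ortho_coef,
        y_mean=y_mean,
        a1=a1 if m1 is None else m1.n_lv,
        a2=0 if m2 is None else m2.n_lv,
    )


def predict_sopls(model: SOPLSModel, X1_new: np.ndarray, X2_new: np.ndarray) -> np.ndarray:
    return model.predict(X1_new, X2_new)


@dataclass(frozen=True)
class SOPLSCVResult:
    """Cross-validated RMSE surface over the (a1, a2) grid."""

    rmsecv: np.ndarray  # (max_a1 + 1) x (max_a2 + 1); [0, 0] is NaN
    a1: int
    a2: int
    folds: tuple
    seed: int

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv[self.a1, self.a2])


def select_lv_grid(
    X1: np.ndarray,
    X2: np.ndarray,
    Y: np.ndarray,
    max_a1: int = 10,
    max_a2: int = 10,
    folds: int = 5,
    seed: int = 0,
    rel_tol: float = 0.01,
) -> SOPLSCVResult:
    """Exhaustive (a1, a2) grid search minimizing k-fold RMSECV.

    Selection is parsimonious: among all grid points whose RMSECV is
    within ``rel_tol`` (relative) of the minimum, the smallest total
    a1 + a2 wins, then the smaller a1 — so an uninformative second
    block gets a2 = 0 rather than a chance sliver of CV improvement.
    Stage-1 fits are computed once per fold at max_a1 and truncated
    (NIPALS nesting); everything, including the orthogonalizer, is
    learned inside the training fold only.
    """
    X1 = np.asarray(X1, float)
    X2 = np.asarray(X2, float)
    Y = _as_2d(Y)
    n = Y.shape[0]
    if X1.shape[0] != n or X2.shape[0] != n:
        raise ValueError("sample mismatch between X1, X2 and Y")
    if max_a1 < 0 or max_a2 < 0 or (max_a1 == 0 and max_a2 == 0):
        raise ValueError("grid bounds must be >= 0 and not both zero")
    labels = make_folds(n, folds, seed)
    sse = np.zeros((max_a1 + 1, max_a2 + 1))
    for f in range(folds):
        test = labels == f
        train = ~test
        cap1 = min(max_a1, int(train.sum()) - 1, X1.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path1 = fit_pls(X1[train], Y[train], cap1) if cap1 > 0 else None
        y_mean = Y[train].mean(axis=0)
        x2_mean = X2[train].mean(axis=0)
        X2c_tr = X2[train] - x2_mean
        X2c_te = X2[test] - x2_mean
        for a1 in range(max_a1 + 1):
            if a1 > 0 and (path1 is None or a1 > path1.n_lv):
                sse[a1, :] = np.inf  # rank exhausted in this fold
                continue
            if a1 > 0:
                m1 = path1.truncate(a1)
                y1_tr = m1.predict(X1[train])
                y1_te = m1.predict(X1[test])
                t1 = m1.T
                ortho = np.linalg.pinv(t1, rcond=_PINV_RCOND) @ X2c_tr
                X2o_tr = X2c_tr - t1 @ ortho
                X2o_te = X2c_te - m1.scores(X1[test]) @ ortho
            else:
                y1_tr = np.tile(y_mean, (int(train.sum()), 1))
                y1_te = np.tile(y_mean, (int(test.sum()), 1))
                X2o_tr, X2o_te = X2c_tr, X2c_te
            resid_tr = Y[train] - y1_tr
            sse[a1, 0] += float(np.sum((Y[test] - y1_te) ** 2))
            cap2 = min(max_a2, int(train.sum()) - 1, X2.shape[1])
            if cap2 > 0:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    path2 = fit_pls(X2o_tr, resid_tr, cap2)
                for a2 in range(1, max_a2 + 1):
                    m2 = path2.truncate(min(a2, path2.n_lv))
                    y2_te = m2.predict(X2o_te)
                    sse[a1, a2] += float(np.sum((Y[test] - y1_te - y2_te) ** 2))
            elif max_a2 > 0:
                sse[a1, 1:] = np.inf
    rmsecv = np.sqrt(sse / (n * Y.shape[1]))
    rmsecv[0, 0] = np.nan  # empty model excluded
    best_val = np.nanmin(rmsecv)
    candidates = np.argwhere(rmsecv <= best_val * (1.0 + rel_tol))
    order = sorted(
        (int(a1) + int(a2), int(a1), int(a2)) for a1, a2 in candidates
    )
    _, a1_best, a2_best = order[0]
    return SOPLSCVResult(
        rmsecv=rmsecv, a1=a1_best, a2=a2_best, folds=tuple(labels.tolist()), seed=seed
    )
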