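"""Variable importance in projection (VIP) scoring and the
variable-selected sequential fusion model.

For a fitted PLS model with A components, unit-norm weight vectors
w_a and per-component explained response sum of squares SSY_a, the
importance of variable j is::

    VIP_j = sqrt( p * sum_a w_ja^2 * SSY_a / sum_a SSY_a )

The mean of the squared VIP scores over all p variables is exactly 1,
which motivates the conventional selection threshold of 1: variables
scoring above it contribute more than an average variable.

``fit_sf_vip_sopls`` runs the full variable-selected fusion workflow:
per-block PLS with cross-validated LV counts, per-block VIP, strict
thresholding, then a fresh cross-validated sequential two-block fit on
the reduced blocks.  All selection happens on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import PLSModel, fit_pls, select_lv
from .sopls import SOPLSModel, fit_sopls, select_lv_grid, SOPLSCVResult

__all__ = ["VIPResult", "VIPSOPLSModel", "compute_vip", "select_variables", "fit_sf_vip_sopls"]


@dataclass(frozen=True)
class VIPResult:
    """Per-channel VIP scores with an optional selection mask."""

    scores: np.ndarray
    threshold: float = 1.0
    strict: bool = True
    boundaries: tuple[int, ...] = ()

    @property
    def mask(self) -> np.ndarray:
        if self.strict:
            return self.scores > self.threshold
        return self.scores >= self.threshold

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def to_frame(self, axis: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"vip": self.scores, "selected": self.mask})
        if axis is not None:
            df.insert(0, "channel", np.asarray(axis))
        return df


def compute_vip(
    model: PLSModel, threshold: float = 1.0, strict: bool = True
) -> VIPResult:
    """VIP scores of a fitted PLS model (requires >= 1 latent variable)."""
    if model.n_lv < 1:
        raise ValueError("compute_vip requires a model with at least 1 latent variable")
    ssy = model.explained_y_ss()
    total = float(ssy.sum())
    if total <= 0:
        raise ValueError("compute_vip: model explains no response variance")
    p = model.n_channels
    scores = np.sqrt(p * (model.W**2) @ (ssy / total))
    return VIPResult(scores=scores, threshold=threshold, strict=strict)


def select_variables(
    vip1: VIPResult, vip2: VIPResult, threshold: float = 1.0, strict: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block selection masks at a common threshold.

    The default rule is strict (score > threshold), so channels scoring
    exactly at the threshold are dropped.  An empty selection in either
    block is rejected: lower the threshold rather than fitting a model
    with a zero-channel block.
    """
    masks = []
    for i, vip in enumerate((vip1, vip2), start=1):
        mask = vip.scores > threshold if strict else vip.scores >= threshold
        if not mask.any():
            raise ValueError(
                f"block {i}: no variables score {'>' if strict else '>='} "
                f"{threshold}; lower the threshold"
            )
        masks.append(mask)
    return masks[0], masks[1]


@dataclass(frozen=True)
class VIPSOPLSModel:
    """Sequential two-block model on VIP-selected channels."""

    sopls: SOPLSModel
    mask1: np.ndarray
    mask2: np.ndarray
    vip1: VIPResult
    vip2: VIPResult
    cv1_n_lv: int
    cv2_n_lv: int
    grid: SOPLSCVResult

    @property
    def n_variables(self) -> int:
        return int(self.mask1.sum() + self.mask2.sum())

    def predict(self, X1_new: np.ndarray, X2_new: np.ndarray) -> np.ndarray:
        X1_new = np.atleast_2d(np.asarray(X1_new, float))
        X2_new = np.atleast_2d(np.asarray(X2_new, float))
        return self.sopls.predict(X1_new[:, self.mask1], X2_new[:, self.mask2])


def fit_sf_vip_sopls(
    X1: np.ndarray,
    X2: np.ndarray,
    Y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    threshold: float = 1.0,
    strict: bool = True,
    max_lv: int = 10,
    max_a1: int = 10,
    max_a2: int = 10,
) -> VIPSOPLSModel:
    """Variable-selected sequential fusion: per-block VIP, then SOPLS.

    Each block gets its own PLS model at the cross-validation-selected
    LV count; VIP is computed from that model and channels above the
    threshold are kept.  The reduced blocks then get a fresh
    cross-validated (a1, a2) grid search and sequential fit.
    """
    X1 = np.asarray(X1, float)
    X2 = np.asarray(X2, float)
    cv1 = select_lv(X1, Y, max_lv=max_lv, folds=folds, seed=seed)
    cv2 = select_lv(X2, Y, max_lv=max_lv, folds=folds, seed=seed)
    vip1 = compute_vip(fit_pls(X1, Y, cv1.n_lv), threshold, strict)
    vip2 = compute_vip(fit_pls(X2, Y, cv2.n_lv), threshold, strict)
    mask1, mask2 = select_variables(vip1, vip2, threshold, strict)
    X1r, X2r = X1[:, mask1], X2[:, mask2]
    grid = select_lv_grid(
        X1r, X2r, Y,
        max_a1=min(max_a1, X1r.shape[1]),
        max_a2=min(max_a2, X2r.shape[1]),
        folds=folds, seed=seed,
    )
    model = fit_sopls(X1r, X2r, Y, grid.a1, grid.a2)
    return VIPSOPLSModel(
        sopls=model, mask1=mask1, mask2=mask2, vip1=vip1, vip2=vip2,
        cv1_n_lv=cv1.n_lv, cv2_n_lv=cv2.n_lv, grid=grid,
    )
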