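"""Chemometric model-evaluation metrics: RMSE, R2, RPD, RPIQ.

RPD (residual prediction deviation) is the standard deviation of the
measured values over the RMSE; RPIQ replaces the SD with the
interquartile range Q3 - Q1, which is more robust for skewed soil
attributes.  Both are unit-free.  Conventions pinned here: SD uses the
n-1 denominator; quartiles use linear interpolation between order
statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["rmse", "r_squared", "residual_ratio", "rpd", "rpiq", "summarize", "evaluate"]


def _pair(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.size != y_hat.size:
        raise ValueError(f"length mismatch: y has {y.size}, y_hat has {y_hat.size}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, y_hat


def rmse(y, y_hat) -> float:
    """Root mean squared prediction error, in the units of y."""
    y, y_hat = _pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def residual_ratio(y, y_hat) -> float:
    """SS_res / SS_tot (0 for a perfect prediction, complements R2)."""
    y, y_hat = _pair(y, y_hat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("residual_ratio: constant y has no variance to explain")
    return float(np.sum((y - y_hat) ** 2) / ss_tot)


def r_squared(y, y_hat) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    return 1.0 - residual_ratio(y, y_hat)


def rpd(y, y_hat) -> float:
    """Residual prediction deviation: SD(y) / RMSE (SD with n-1)."""
    y, y_hat = _pair(y, y_hat)
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("rpd: constant y has zero standard deviation")
    err = rmse(y, y_hat)
    if err == 0:
        warnings.warn("rpd: zero RMSE, returning +inf", stacklevel=2)
        return float("inf")
    return sd / err


def rpiq(y, y_hat) -> float:
    """Ratio of performance to interquartile distance: (Q3 - Q1) / RMSE."""
    y, y_hat = _pair(y, y_hat)
    if y.size < 4:
        raise ValueError("rpiq requires at least 4 observations")
    q1, q3 = np.percentile(y, [25, 75])  # linear interpolation convention
    if q3 - q1 == 0:
        raise ValueError("rpiq: zero interquartile range")
    err = rmse(y, y_hat)
    if err == 0:
        warnings.warn("rpiq: zero RMSE, returning +inf", stacklevel=2)
        return float("inf")
    return float((q3 - q1) / err)


def summarize(y, y_hat) -> dict:
    """R2, RMSE, RPD, RPIQ and n for one prediction set."""
    y, y_hat = _pair(y, y_hat)
    out = {
        "R2": r_squared(y, y_hat),
        "RMSE": rmse(y, y_hat),
        "RPD": rpd(y, y_hat),
        "n": int(y.size),
    }
    out["RPIQ"] = rpiq(y, y_hat) if y.size >= 4 else float("nan")
    return out


#: column order of the evaluation report
REPORT_COLUMNS = [
    "attribute", "model", "R2_cv", "RMSEC", "RPD_cal",
    "R2_p", "RMSEP", "RPD", "RPIQ", "n_train", "n_test", "variables",
]


def evaluate(entries) -> pd.DataFrame:
    """Assemble the attribute x model evaluation grid.

    ``entries`` is an iterable of dicts with keys ``attribute``,
    ``model``, ``variables``, plus measured/predicted pairs
    ``y_train``/``y_cv`` (cross-validated training predictions) and
    ``y_test``/``y_pred``.  One row is emitted per entry, with training
    cross-validation statistics (R2_cv, RMSEC, RPD_cal) and test-set
    statistics (R2_p, RMSEP, RPD, RPIQ).
    """
    rows = []
    for e in entries:
        cal = summarize(e["y_train"], e["y_cv"])
        test = summarize(e["y_test"], e["y_pred"])
        rows.append(
            {
                "attribute": e["attribute"],
                "model": e["model"],
                "R2_cv": cal["R2"],
                "RMSEC": cal["RMSE"],
                "RPD_cal": cal["RPD"],
                "R2_p": test["R2"],
                "RMSEP": test["RMSE"],
                "RPD": test["RPD"],
                "RPIQ": test["RPIQ"],
                "n_train": cal["n"],
                "n_test": test["n"],
                "variables": int(e["variables"]),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
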