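"""Spectral pre-treatment operators and per-sensor recipes.

Operators are pure functions ``SpectraBlock -> SpectraBlock`` that never
change the sample count or ordering.  The only stateful operator is MSC,
whose reference spectrum must be learned on training data and frozen for
test data; the recipe machinery (:class:`PreprocessSpec`,
:func:`fit_recipe`) handles that.

The named presets map each soil attribute to the pre-treatment chain
found to work best per sensor: MIR spectra get a moving average followed
by an attribute-specific normalization (max-normalize, SNV, MSC, or
nothing); XRF spectra are first baseline-corrected (asymmetric least
squares) and Compton-normalized, then treated like MIR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .blocks import SpectraBlock

__all__ = [
    "moving_average",
    "max_normalize",
    "snv",
    "msc",
    "msc_reference",
    "savitzky_golay",
    "baseline_correct",
    "compton_normalize",
    "mask_channels",
    "PreprocessSpec",
    "FittedRecipe",
    "fit_recipe",
    "apply_recipe",
    "mir_preset",
    "xrf_preset",
]


def moving_average(block: SpectraBlock, window: int = 5) -> SpectraBlock:
    """Centered moving-average smoothing; edges use a shrinking window."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"moving_average window must be odd and >= 1, got {window}")
    if window > block.n_channels:
        raise ValueError(
            f"moving_average window {window} exceeds channel count {block.n_channels}"
        )
    smoothed = (
        pd.DataFrame(block.values.T)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
        .T
    )
    return block.with_values(smoothed)


def max_normalize(block: SpectraBlock) -> SpectraBlock:
    """Divide each spectrum by its own maximum so values lie within unity."""
    peaks = block.values.max(axis=1)
    bad = np.flatnonzero(peaks <= 0)
    if bad.size:
        raise ValueError(
            f"max_normalize: non-positive maximum for sample(s) "
            f"{[block.samples[i] for i in bad[:5]]}"
        )
    return block.with_values(block.values / peaks[:, None])


def snv(block: SpectraBlock) -> SpectraBlock:
    """Standard normal variate: center and scale each spectrum (sd, n-1)."""
    mean = block.values.mean(axis=1, keepdims=True)
    sd = block.values.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(
            f"snv: constant spectrum for sample(s) {[block.samples[i] for i in bad[:5]]}"
        )
    return block.with_values((block.values - mean) / sd)


def msc_reference(block: SpectraBlock) -> np.ndarray:
    """MSC reference = mean spectrum of the fitting (training) set."""
    return block.values.mean(axis=0)


def msc(block: SpectraBlock, reference: np.ndarray | None = None) -> SpectraBlock:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference by ordinary least
    squares, x = a + b*ref + e, and replaced by (x - a)/b.  When no
    reference is given the block's own mean spectrum is used (fitting-set
    behaviour); for test data pass the frozen training reference.
    """
    ref = msc_reference(block) if reference is None else np.asarray(reference, float)
    if ref.size != block.n_channels:
        raise ValueError("msc: reference length must equal channel count")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("msc: constant reference spectrum")
    b = (block.values - block.values.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(b == 0)
    if bad.size:
        raise ValueError(
            f"msc: zero slope for sample(s) {[block.samples[i] for i in bad[:5]]}"
        )
    a = block.values.mean(axis=1) - b * ref.mean()
    return block.with_values((block.values - a[:, None]) / b[:, None])


def savitzky_golay(block: SpectraBlock, window: int = 11, polyorder: int = 2) -> SpectraBlock:
    """Savitzky-Golay polynomial smoothing (scipy convolution)."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError(
            f"savitzky_golay: window must be odd and > polyorder, got "
            f"window={window}, polyorder={polyorder}"
        )
    if window > block.n_channels:
        raise ValueError(
            f"savitzky_golay: window {window} exceeds channel count {block.n_channels}"
        )
    return block.with_values(savgol_filter(block.values, window, polyorder, axis=1))


def _asls_penalty_bands(m: int, lam: float) -> np.ndarray:
    """Upper banded form of lam * D2' D2 (pentadiagonal, SPD)."""
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m))
    pen = (lam * (D.T @ D)).tocsc()
    ab = np.zeros((3, m))
    ab[0, 2:] = pen.diagonal(2)
    ab[1, 1:] = pen.diagonal(1)
    ab[2, :] = pen.diagonal(0)
    return ab


def _asls_baseline(y: np.ndarray, penalty_bands: np.ndarray, p: float, niter: int) -> np.ndarray:
    """Asymmetric least squares baseline (Eilers-Boelens weighting)."""
    w = np.ones(y.size)
    z = y
    for _ in range(niter):
        ab = penalty_bands.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def baseline_correct(
    block: SpectraBlock, smoothness: float = 1e5, asymmetry: float = 0.01, niter: int = 10
) -> SpectraBlock:
    """Subtract a slowly-varying baseline estimated by asymmetric least squares.

    ``smoothness`` is the second-difference penalty weight (larger =
    stiffer baseline); ``asymmetry`` the weight given to points above the
    baseline, so peaks are mostly ignored while the continuum is tracked.
    """
    if not np.all(np.isfinite(block.values)):
        raise ValueError("baseline_correct: non-finite values")
    if smoothness <= 0 or not 0 < asymmetry < 1:
        raise ValueError("baseline_correct: smoothness > 0 and 0 < asymmetry < 1 required")
    if block.n_channels < 3:
        raise ValueError("baseline_correct needs at least 3 channels")
    bands = _asls_penalty_bands(block.n_channels, smoothness)
    out = np.empty_like(block.values)
    for i, row in enumerate(block.values):
        if np.ptp(row) == 0:
            out[i] = row - row  # flat spectrum is its own baseline
        else:
            out[i] = row - _asls_baseline(row, bands, asymmetry, niter)
    return block.with_values(out)


def compton_normalize(block: SpectraBlock, window: tuple[float, float] = (18.0, 22.0)) -> SpectraBlock:
    """Divide each spectrum by its integrated intensity in the scatter window.

    The default window brackets the Rh-source Compton scatter region
    around 20 keV.  After the transform the trapezoidal integral of each
    spectrum over the window equals 1.
    """
    lo, hi = min(window), max(window)
    axis_lo, axis_hi = block.axis.min(), block.axis.max()
    if lo < axis_lo or hi > axis_hi:
        raise ValueError(
            f"compton_normalize: window [{lo}, {hi}] outside axis range "
            f"[{axis_lo}, {axis_hi}]"
        )
    inside = (block.axis >= lo) & (block.axis <= hi)
    if inside.sum() < 2:
        raise ValueError("compton_normalize: window covers fewer than 2 channels")
    integrals = np.trapezoid(block.values[:, inside], block.axis[inside], axis=1)
    integrals = np.abs(integrals)  # descending axes integrate negatively
    bad = np.flatnonzero(integrals <= 0)
    if bad.size:
        raise ValueError(
            f"compton_normalize: zero window integral for sample(s) "
            f"{[block.samples[i] for i in bad[:5]]}"
        )
    return block.with_values(block.values / integrals[:, None])


def mask_channels(block: SpectraBlock, interval: tuple[float, float] = (2.3, 2.7)) -> SpectraBlock:
    """Drop channels inside ``interval`` (e.g. a detector-noise spike)."""
    lo, hi = min(interval), max(interval)
    keep = (block.axis < lo) | (block.axis > hi)
    if not keep.any():
        raise ValueError("mask_channels: interval removes every channel")
    return block.select_channels(keep)


# --- recipe machinery ----------------------------------------------------

_STATELESS = {
    "moving_average": moving_average,
    "max_normalize": max_normalize,
    "snv": snv,
    "savitzky_golay": savitzky_golay,
    "baseline_correct": baseline_correct,
    "compton_normalize": compton_normalize,
    "mask_channels": mask_channels,
}
_STATEFUL = {"msc"}


@dataclass(frozen=True)
class PreprocessSpec:
    """Ordered operator chain for one sensor, e.g. from a preset table."""

    steps: tuple
    sensor: str = ""
    attributes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        steps = tuple(
            (
                name,
                {k: tuple(v) if isinstance(v, list) else v for k, v in dict(params).items()},
            )
            for name, params in self.steps
        )
        object.__setattr__(self, "steps", steps)
        for name, _ in steps:
            if name not in _STATELESS and name not in _STATEFUL:
                raise ValueError(f"unknown preprocessing operator {name!r}")

    def to_dict(self) -> dict:
        return {
            "sensor": self.sensor,
            "attributes": list(self.attributes),
            "steps": [{"op": name, **params} for name, params in self.steps],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        steps = tuple(
            (s["op"], {k: v for k, v in s.items() if k != "op"}) for s in d["steps"]
        )
        return cls(steps=steps, sensor=d.get("sensor", ""), attributes=tuple(d.get("attributes", ())))

    @classmethod
    def load(cls, path) -> "PreprocessSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class FittedRecipe:
    """A recipe with its training statistics (MSC reference) frozen."""

    spec: PreprocessSpec
    state: dict = field(default_factory=dict)

    def transform(self, block: SpectraBlock) -> SpectraBlock:
        for i, (name, params) in enumerate(self.spec.steps):
            if name == "msc":
                block = msc(block, reference=self.state[f"msc_reference_{i}"], **params)
            else:
                block = _STATELESS[name](block, **params)
        return block


def fit_recipe(block: SpectraBlock, spec: PreprocessSpec) -> FittedRecipe:
    """Run the chain on training data, learning any stateful statistics."""
    state: dict = {}
    for i, (name, params) in enumerate(spec.steps):
        if name == "msc":
            ref = msc_reference(block)
            state[f"msc_reference_{i}"] = ref
            block = msc(block, reference=ref, **params)
        else:
            block = _STATELESS[name](block, **params)
    return FittedRecipe(spec=spec, state=state)


def apply_recipe(block: SpectraBlock, spec: PreprocessSpec) -> SpectraBlock:
    """Fit the chain on ``block`` itself and return the transformed block."""
    return fit_recipe(block, spec).transform(block)


# --- presets: best chain per attribute and sensor ------------------------

_MIR_TAILS = {
    "pH": ("max_normalize",),
    "OC": ("max_normalize",),
    "Mg": ("max_normalize",),
    "MC": ("max_normalize",),
    "P": ("snv",),
    "K": (),
    "Ca": ("msc",),
}


def mir_preset(attribute: str) -> PreprocessSpec:
    """MIR chain for one attribute: moving average, then its normalization."""
    if attribute not in _MIR_TAILS:
        raise KeyError(f"no MIR preset for attribute {attribute!r}")
    steps = (("moving_average", {"window": 5}),) + tuple(
        (op, {}) for op in _MIR_TAILS[attribute]
    )
    return PreprocessSpec(steps=steps, sensor="MIR", attributes=(attribute,))


def xrf_preset(
    attribute: str, compton_window: tuple[float, float] = (18.0, 22.0)
) -> PreprocessSpec:
    """XRF chain: baseline + Compton normalization, then the MIR-style tail."""
    if attribute not in _MIR_TAILS:
        raise KeyError(f"no XRF preset for attribute {attribute!r}")
    steps = (
        ("baseline_correct", {}),
        ("compton_normalize", {"window": compton_window}),
        ("moving_average", {"window": 5}),
    ) + tuple((op, {}) for op in _MIR_TAILS[attribute])
    return PreprocessSpec(steps=steps, sensor="XRF", attributes=(attribute,))
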