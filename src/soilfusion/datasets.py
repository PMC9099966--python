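"""Synthetic paired MIR/XRF soil spectra with known latent structure.

The generator emulates the statistical structure that multiblock soil
calibration assumes: a small number of latent "chemical" factors drive
both the spectra and the seven fertility attributes (pH, OC, P, K, Mg,
Ca, MC).

Latent layout
-------------
With ``k = n_latents`` factors, the last ``n_xrf_latents`` (default
``k // 2``) are *XRF-exclusive*: they shape XRF emission peaks but leave
the MIR block untouched.  The remaining MIR factors shape Gaussian
absorption bands at the classic soil wavenumbers (O-H stretch
3800-3000, C-H 3000-2820, carbonate/C=O 1873 and 1730, O-H/C-H bend
1632-1530, fingerprint 1409 and 1157 cm^-1); a subset of them is also
visible to XRF, so the two sensors overlap without being redundant.

Each attribute mixes a standardized combination of MIR factors with a
standardized combination of XRF-exclusive factors::

    y = mean + sd * ( sqrt(1-c) * s_mir + sqrt(c) * s_xrf + noise )

so ``complementarity`` (c) is exactly the fraction of attribute signal
variance carried only by the XRF block.  Setting ``noise_sd=0`` yields a
fully deterministic, noise-free dataset in which every attribute is an
exact linear function of the latent concentrations.

Artifacts: MIR spectra get a per-sample multiplicative gain, an additive
offset and white Gaussian noise (absorbance-like); XRF spectra get a
smooth continuum with an Rh-scatter bump near 20 keV, a fixed detector
spike at 2.5 keV, a per-sample gain (the matrix effect that Compton
normalization corrects) and variance-proportional noise as a Poisson
surrogate.  Both spectra families are nonnegative before preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .blocks import SpectraBlock, AttributeTable

__all__ = ["SynthConfig", "SynthDataset", "generate", "attribute_ranges"]

ATTRIBUTES = ("pH", "OC", "P", "K", "Mg", "Ca", "MC")

#: target marginal (mean, sd) per attribute, patterned on field-survey scale
DEFAULT_ATTRIBUTE_MOMENTS = {
    "pH": (8.02, 0.50),
    "OC": (1.34, 0.30),
    "P": (19.21, 18.77),
    "K": (41.56, 22.46),
    "Mg": (62.25, 23.78),
    "Ca": (1380.0, 956.93),
    "MC": (16.75, 4.33),
}

# MIR absorption band library: (center cm^-1, width cm^-1)
MIR_BANDS = (
    (3620.0, 90.0),
    (3400.0, 160.0),
    (3150.0, 120.0),
    (2925.0, 35.0),
    (2850.0, 30.0),
    (1873.0, 30.0),
    (1730.0, 28.0),
    (1600.0, 45.0),
    (1560.0, 35.0),
    (1409.0, 40.0),
    (1157.0, 35.0),
)

# XRF emission peak library: (center keV, width keV) -- K/Ca lines in the
# 3-5 keV region, Fe lines in 5-8 keV, a few light/heavy element lines
XRF_PEAKS = (
    (2.01, 0.09),   # P K-alpha
    (3.31, 0.10),   # K K-alpha
    (3.69, 0.10),   # Ca K-alpha
    (4.01, 0.11),   # Ca K-beta
    (5.90, 0.12),   # Mn K-alpha
    (6.40, 0.12),   # Fe K-alpha
    (7.06, 0.13),   # Fe K-beta
    (8.64, 0.14),   # Zn K-alpha
    (14.16, 0.17),  # Sr K-alpha
    (25.27, 0.22),  # Sn K-alpha region
)

DETECTOR_SPIKE_KEV = 2.5


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the paired-spectra generator.

    ``complementarity`` is the fraction of attribute signal variance
    carried only by the XRF block; ``attr_snr`` the signal-to-noise
    variance ratio of each attribute when noise is enabled.
    """

    n_samples: int = 196
    n_mir_channels: int = 900
    n_xrf_channels: int = 2048
    mir_axis: tuple[float, float] = (4000.0, 650.0)
    xrf_axis: tuple[float, float] = (0.0, 30.0)
    n_latents: int = 6
    n_xrf_latents: int | None = None
    n_shared_latents: int | None = None
    complementarity: float = 0.5
    noise_sd: float = 0.01
    scatter_sd: float = 0.05
    attr_snr: float = 10.0
    attribute_moments: dict = field(
        default_factory=lambda: dict(DEFAULT_ATTRIBUTE_MOMENTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_mir_channels", "n_xrf_channels", "n_latents"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 2:
                raise ValueError(f"{name} must be an integer >= 2, got {v!r}")
        if not 0.0 <= self.complementarity <= 1.0:
            raise ValueError(
                f"complementarity must be in [0, 1], got {self.complementarity!r}"
            )
        for name in ("noise_sd", "scatter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not self.attr_snr > 0:
            raise ValueError(f"attr_snr must be > 0, got {self.attr_snr!r}")
        if self.mir_axis[0] == self.mir_axis[1]:
            raise ValueError("mir_axis endpoints must differ (strictly monotonic axis)")
        if self.xrf_axis[0] == self.xrf_axis[1]:
            raise ValueError("xrf_axis endpoints must differ (strictly monotonic axis)")
        object.__setattr__(
            self,
            "attribute_moments",
            {k: tuple(v) for k, v in self.attribute_moments.items()},
        )
        object.__setattr__(self, "mir_axis", tuple(self.mir_axis))
        object.__setattr__(self, "xrf_axis", tuple(self.xrf_axis))
        kx = self.n_latents // 2 if self.n_xrf_latents is None else self.n_xrf_latents
        if not 0 <= kx <= self.n_latents - 1:
            raise ValueError(
                f"n_xrf_latents must be in [0, n_latents-1], got {self.n_xrf_latents!r}"
            )
        if self.complementarity > 0 and kx == 0:
            raise ValueError(
                "complementarity > 0 requires n_xrf_latents >= 1 "
                "(no XRF-exclusive factors to carry block-2 variance)"
            )
        km = self.n_latents - kx
        shared = km // 2 if self.n_shared_latents is None else self.n_shared_latents
        if not 0 <= shared <= km:
            raise ValueError(
                f"n_shared_latents must be in [0, n_latents - n_xrf_latents], "
                f"got {self.n_shared_latents!r}"
            )

    @property
    def n_xrf_exclusive(self) -> int:
        return self.n_latents // 2 if self.n_xrf_latents is None else self.n_xrf_latents

    @property
    def n_mir_latents(self) -> int:
        return self.n_latents - self.n_xrf_exclusive

    @property
    def n_shared(self) -> int:
        """MIR factors also visible to XRF (redundant cross-block signal)."""
        if self.n_shared_latents is None:
            return self.n_mir_latents // 2
        return self.n_shared_latents

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mir_axis"] = list(self.mir_axis)
        d["xrf_axis"] = list(self.xrf_axis)
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SynthConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["mir_axis"] = tuple(d["mir_axis"])
        d["xrf_axis"] = tuple(d["xrf_axis"])
        return cls(**d)


@dataclass(frozen=True)
class SynthDataset:
    """Generated paired blocks, attributes and the ground-truth latents."""

    mir: SpectraBlock
    xrf: SpectraBlock
    attributes: AttributeTable
    latents: np.ndarray
    config: SynthConfig

    @property
    def seed(self) -> int:
        return self.config.seed


def _gaussians(axis: np.ndarray, peaks) -> np.ndarray:
    """Peak-library profile matrix, one unit-height Gaussian per row."""
    centers = np.array([c for c, _ in peaks])[:, None]
    widths = np.array([w for _, w in peaks])[:, None]
    return np.exp(-0.5 * ((axis[None, :] - centers) / widths) ** 2)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate(config: SynthConfig) -> SynthDataset:
    """Draw one dataset; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.n_latents
    km, kx = config.n_mir_latents, config.n_xrf_exclusive
    n_shared = config.n_shared  # MIR factors also visible to XRF

    samples = tuple(f"s{i:04d}" for i in range(n))
    mir_axis = np.linspace(config.mir_axis[0], config.mir_axis[1], config.n_mir_channels)
    xrf_axis = np.linspace(config.xrf_axis[0], config.xrf_axis[1], config.n_xrf_channels)

    # latent concentrations, nonnegative and exchangeable across samples
    Z = rng.uniform(0.2, 1.0, size=(n, k))
    Z_mir = Z[:, :km]
    Z_xrf_excl = Z[:, km:]

    # --- MIR block: latent-weighted Gaussian absorption bands ------------
    band_profiles = _gaussians(mir_axis, MIR_BANDS)            # B x p1
    mir_loadings = rng.gamma(0.6, 1.0, size=(km, len(MIR_BANDS)))
    mir_clean = Z_mir @ (mir_loadings @ band_profiles)         # n x p1
    mir_clean *= 1.0 / max(mir_clean.max(), 1e-12)             # absorbance ~ O(1)

    # --- XRF block: emission peaks + continuum + detector spike ----------
    peak_profiles = _gaussians(xrf_axis, XRF_PEAKS)            # Q x p2
    xrf_loadings = rng.gamma(0.6, 1.0, size=(n_shared + kx, len(XRF_PEAKS)))
    Z_xrf_vis = np.hstack([Z_mir[:, :n_shared], Z_xrf_excl])
    if Z_xrf_vis.shape[1]:
        xrf_peaks = Z_xrf_vis @ (xrf_loadings @ peak_profiles)  # n x p2
    else:  # no XRF-visible factors: continuum and spike only
        xrf_peaks = np.full((n, config.n_xrf_channels), 1e-12)
    # bremsstrahlung-like continuum with a broad Rh-scatter bump near 20 keV
    e = np.clip(xrf_axis, 0.0, None)
    continuum = 0.3 * e * np.exp(-e / 8.0) + 0.25 * np.exp(
        -0.5 * ((e - 20.0) / 2.5) ** 2
    )
    spike = 0.6 * np.exp(-0.5 * ((e - DETECTOR_SPIKE_KEV) / 0.05) ** 2)
    xrf_clean = 800.0 * xrf_peaks / max(np.max(xrf_peaks), 1e-12)
    xrf_clean = xrf_clean + 200.0 * continuum[None, :] + 300.0 * spike[None, :]

    # --- artifacts and noise ---------------------------------------------
    mir = mir_clean
    xrf = xrf_clean
    if config.scatter_sd > 0:
        gain_mir = np.exp(config.scatter_sd * rng.standard_normal(n))
        offset = np.abs(rng.standard_normal(n)) * config.scatter_sd * 0.5
        mir = gain_mir[:, None] * mir + offset[:, None]
        gain_xrf = np.exp(config.scatter_sd * rng.standard_normal(n))
        xrf = gain_xrf[:, None] * xrf
    if config.noise_sd > 0:
        mir = mir + config.noise_sd * rng.standard_normal(mir.shape)
        xrf = xrf + config.noise_sd * 10.0 * np.sqrt(xrf_clean + 1.0) * rng.standard_normal(
            xrf.shape
        )
        mir = np.clip(mir, 0.0, None)
        xrf = np.clip(xrf, 0.0, None)

    # --- attributes: complementarity-weighted latent mixtures ------------
    c = config.complementarity
    names = tuple(config.attribute_moments)
    Y = np.empty((n, len(names)))
    for j, name in enumerate(names):
        mean, sd = config.attribute_moments[name]
        u = rng.standard_normal(km)
        s1 = _standardize(Z_mir @ u)
        if kx:
            v = rng.standard_normal(kx)
            s2 = _standardize(Z_xrf_excl @ v)
        else:
            s2 = np.zeros(n)
        signal = np.sqrt(1.0 - c) * s1 + np.sqrt(c) * s2
        eps = rng.standard_normal(n) / np.sqrt(config.attr_snr)
        if config.noise_sd == 0:
            eps = np.zeros(n)
        Y[:, j] = mean + sd * (signal + eps)

    return SynthDataset(
        mir=SpectraBlock(samples=samples, axis=mir_axis, values=mir, label="MIR"),
        xrf=SpectraBlock(samples=samples, axis=xrf_axis, values=xrf, label="XRF"),
        attributes=AttributeTable(samples=samples, names=names, values=Y),
        latents=Z,
        config=config,
    )


def attribute_ranges(dataset: SynthDataset) -> pd.DataFrame:
    """Descriptive statistics (min/max/mean/sd) per attribute.

    The standard deviation uses the n-1 denominator and is reported as
    0.0 for a single-sample dataset.
    """
    tab = dataset.attributes
    if tab.n_samples == 0:
        raise ValueError("attribute_ranges: dataset has no samples")
    v = tab.values
    sd = v.std(axis=0, ddof=1) if tab.n_samples > 1 else np.zeros(v.shape[1])
    return pd.DataFrame(
        {
            "min": v.min(axis=0),
            "max": v.max(axis=0),
            "mean": v.mean(axis=0),
            "sd": sd,
            "unit": [tab.units.get(name, "") for name in tab.names],
        },
        index=list(tab.names),
    )
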