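"""Sample-by-channel spectra blocks and soil attribute tables.

A :class:`SpectraBlock` holds one sensor's spectra: an ordered list of
sample ids, a physical channel axis (wavenumbers in cm^-1 for MIR,
descending by instrument convention; energies in keV for XRF, ascending)
and the sample x channel value matrix.  Fused blocks produced by
:func:`concatenate` keep the axes of their constituents and record the
block boundary so downstream variable selection can report per-block
counts.

An :class:`AttributeTable` holds the per-sample responses (pH, OC, P, K,
Mg, Ca, MC) with their units.

All I/O is plain CSV: header row of axis values (or attribute names),
first column the sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectraBlock",
    "AttributeTable",
    "concatenate",
    "read_spectra",
    "write_spectra",
    "read_attributes",
    "write_attributes",
]

#: conventional units for the seven modeled soil attributes
DEFAULT_UNITS = {
    "pH": "",
    "OC": "%",
    "P": "mg/100 g",
    "K": "mg/100 g",
    "Mg": "mg/100 g",
    "Ca": "mg/100 g",
    "MC": "%",
}


def _segments(n_channels: int, boundaries: tuple[int, ...]) -> list[slice]:
    edges = [0, *boundaries, n_channels]
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _check_monotonic(axis: np.ndarray, label: str) -> None:
    if axis.size < 2:
        return
    d = np.diff(axis)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(
            f"block {label!r}: axis must be strictly monotonic "
            f"(first offending step at channel {int(np.argmin(np.abs(d) > 0))})"
        )


@dataclass(frozen=True)
class SpectraBlock:
    """One sensor's spectra: ids, physical axis and value matrix.

    Parameters
    ----------
    samples
        Ordered, unique sample identifiers (length n).
    axis
        Per-channel physical coordinate (length p).  Strictly monotonic
        within each segment (fused blocks have one segment per sensor).
    values
        n x p matrix, finite, no missing values.
    label
        Block name, e.g. ``"MIR"`` or ``"XRF"``.
    boundaries
        Channel indices where constituent blocks meet (empty for a
        single-sensor block).
    """

    samples: tuple[str, ...]
    axis: np.ndarray
    values: np.ndarray
    label: str
    boundaries: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(str(s) for s in self.samples))
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"block {self.label!r}: values must be 2-D")
        object.__setattr__(self, "values", values)
        if len(set(self.samples)) != len(self.samples):
            dup = [s for s in self.samples if self.samples.count(s) > 1]
            raise ValueError(f"block {self.label!r}: duplicate sample ids {sorted(set(dup))}")
        if values.shape[0] != len(self.samples):
            raise ValueError(
                f"block {self.label!r}: {len(self.samples)} sample ids but "
                f"{values.shape[0]} rows"
            )
        if values.shape[1] != self.axis.size:
            raise ValueError(
                f"block {self.label!r}: axis length {self.axis.size} != "
                f"channel count {values.shape[1]}"
            )
        if values.size and not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"block {self.label!r}: non-finite value at sample "
                f"{self.samples[i]!r}, channel index {j}"
            )
        for seg in _segments(self.axis.size, self.boundaries):
            _check_monotonic(self.axis[seg], self.label)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def subset(self, sample_ids) -> "SpectraBlock":
        """Rows restricted to ``sample_ids``, in the given order."""
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"block {self.label!r}: unknown sample ids {missing}")
        idx = [pos[s] for s in sample_ids]
        return replace(self, samples=tuple(sample_ids), values=self.values[idx])

    def select_channels(self, mask: np.ndarray) -> "SpectraBlock":
        """Columns restricted to boolean ``mask`` (boundaries recomputed)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.n_channels:
            raise ValueError("mask length must equal channel count")
        new_bounds = tuple(
            int(mask[:b].sum()) for b in self.boundaries if 0 < mask[:b].sum() < mask.sum()
        )
        return replace(
            self, axis=self.axis[mask], values=self.values[:, mask], boundaries=new_bounds
        )

    def with_values(self, values: np.ndarray) -> "SpectraBlock":
        return replace(self, values=values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.samples), columns=self.axis)


@dataclass(frozen=True)
class AttributeTable:
    """Per-sample responses for the modeled soil attributes."""

    samples: tuple[str, ...]
    names: tuple[str, ...]
    values: np.ndarray
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(str(s) for s in self.samples))
        object.__setattr__(self, "names", tuple(self.names))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not self.units:
            object.__setattr__(
                self, "units", {n: DEFAULT_UNITS.get(n, "") for n in self.names}
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in attribute table")
        if values.shape != (len(self.samples), len(self.names)):
            raise ValueError(
                f"attribute values shape {values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.names)} attributes"
            )
        if values.size and not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing/non-finite value for sample {self.samples[i]!r}, "
                f"attribute {self.names[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def subset(self, sample_ids) -> "AttributeTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids {missing}")
        idx = [pos[s] for s in sample_ids]
        return replace(self, samples=tuple(sample_ids), values=self.values[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.samples), columns=list(self.names))


def concatenate(block1: SpectraBlock, block2: SpectraBlock) -> SpectraBlock:
    """Low-level fusion: column-wise concatenation of two paired blocks.

    Sample ids and order must match exactly.  The block boundary is
    recorded so variable selection can be reported per sensor.
    """
    if block1.samples != block2.samples:
        offending = sorted(set(block1.samples) ^ set(block2.samples)) or [
            s1 for s1, s2 in zip(block1.samples, block2.samples) if s1 != s2
        ]
        raise ValueError(
            f"cannot concatenate {block1.label!r} and {block2.label!r}: sample ids "
            f"differ or are ordered differently (offending ids: {offending[:10]})"
        )
    if block2.n_channels == 0:
        return block1
    if block1.n_channels == 0:
        return block2
    bounds = (
        block1.boundaries
        + (block1.n_channels,)
        + tuple(block1.n_channels + b for b in block2.boundaries)
    )
    return SpectraBlock(
        samples=block1.samples,
        axis=np.concatenate([block1.axis, block2.axis]),
        values=np.hstack([block1.values, block2.values]),
        label=f"{block1.label}+{block2.label}",
        boundaries=bounds,
    )


def write_spectra(block: SpectraBlock, path) -> None:
    """CSV with axis values as header and sample ids as first column."""
    df = block.to_dataframe()
    df.to_csv(path, index_label="sample_id", float_format="%.10g")


def read_spectra(path, label: str) -> SpectraBlock:
    """Read and validate a spectra CSV written by :func:`write_spectra`."""
    df = pd.read_csv(path, index_col=0)
    try:
        axis = df.columns.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: header must be numeric axis values ({exc})") from exc
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at sample {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return SpectraBlock(
        samples=tuple(str(s) for s in df.index), axis=axis, values=values, label=label
    )


def write_attributes(table: AttributeTable, path) -> None:
    table.to_dataframe().to_csv(path, index_label="sample_id", float_format="%.10g")


def read_attributes(path, units: dict | None = None) -> AttributeTable:
    df = pd.read_csv(path, index_col=0)
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at sample {df.index[i]!r}, "
            f"attribute {df.columns[j]!r}"
        )
    return AttributeTable(
        samples=tuple(str(s) for s in df.index),
        names=tuple(df.columns),
        values=values,
        units=units or {},
    )
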