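"""Core domain types for absorbance spectra and their wide-CSV serialization.

A :class:`Spectrum` is a single absorbance trace on a strictly increasing
axis (wavelength in nm for UV/Vis and NIR, wavenumber in cm^-1 for MIR).
A :class:`SpectraSet` bundles many traces that share one axis together with
the per-sample reference analyte concentrations (mmol/L) used for
calibration.

The interchange format is a wide CSV: the first column holds the axis
values, each following column one sample, and the header row carries the
reference concentrations.  Mid-infrared axes are conventionally plotted
descending (4000 -> 500 cm^-1); on read they are normalized to the
package-wide ascending convention, with absorbance rows reordered to match.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "AxisKind",
    "Region",
    "REGION_GRIDS",
    "Spectrum",
    "SpectraSet",
    "BandAssignment",
    "read_spectra_csv",
    "write_spectra_csv",
    "restrict_to_axis_window",
]


class AxisKind(str, enum.Enum):
    WAVELENGTH_NM = "wavelength_nm"
    WAVENUMBER_CM1 = "wavenumber_cm1"


class Region(str, enum.Enum):
    UVVIS = "uvvis"
    NIR = "nir"
    MIR = "mir"

    @property
    def axis_kind(self) -> AxisKind:
        return (
            AxisKind.WAVENUMBER_CM1 if self is Region.MIR else AxisKind.WAVELENGTH_NM
        )


#: Canonical acquisition grids per spectral region: (lo, hi, step) in axis units.
#: UV/Vis 300-800 nm and NIR 800-2600 nm at 1 nm; MIR 4000-500 cm^-1 at
#: 1 cm^-1, stored ascending.
REGION_GRIDS: dict[Region, tuple[float, float, float]] = {
    Region.UVVIS: (300.0, 800.0, 1.0),
    Region.NIR: (800.0, 2600.0, 1.0),
    Region.MIR: (500.0, 4000.0, 1.0),
}


def region_axis(region: Region) -> np.ndarray:
    """Return the canonical ascending axis for ``region``."""
    lo, hi, step = REGION_GRIDS[Region(region)]
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class Spectrum:
    """One absorbance trace on a strictly increasing axis."""

    axis_values: np.ndarray
    axis_kind: AxisKind
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.axis_values = _as_float_array(self.axis_values, "axis_values")
        self.absorbance = _as_float_array(self.absorbance, "absorbance")
        self.axis_kind = AxisKind(self.axis_kind)
        if self.axis_values.ndim != 1 or self.absorbance.ndim != 1:
            raise ValidationError("axis and absorbance must be one-dimensional")
        if self.axis_values.size != self.absorbance.size:
            raise ValidationError(
                "axis and absorbance lengths differ: "
                f"{self.axis_values.size} vs {self.absorbance.size}"
            )
        if self.axis_values.size >= 2 and not np.all(np.diff(self.axis_values) > 0):
            raise ValidationError("axis must be strictly increasing")


@dataclass
class SpectraSet:
    """N absorbance traces on a shared axis plus reference concentrations."""

    axis: np.ndarray
    samples: np.ndarray  # shape (N, P)
    concentrations: np.ndarray  # shape (N,), mmol/L
    region: Region

    def __post_init__(self) -> None:
        self.axis = _as_float_array(self.axis, "axis")
        self.samples = np.atleast_2d(_as_float_array(self.samples, "samples"))
        self.concentrations = np.atleast_1d(
            _as_float_array(self.concentrations, "concentrations")
        )
        self.region = Region(self.region)
        if self.axis.size >= 2 and not np.all(np.diff(self.axis) > 0):
            raise ValidationError("axis must be strictly increasing")
        if self.samples.shape[1] != self.axis.size:
            raise ValidationError(
                f"sample rows of length {self.samples.shape[1]} do not match "
                f"axis of length {self.axis.size}"
            )
        if self.samples.shape[0] != self.concentrations.size:
            raise ValidationError("one concentration per sample is required")
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be non-negative")

    @property
    def axis_kind(self) -> AxisKind:
        return self.region.axis_kind

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(
            axis_values=self.axis,
            axis_kind=self.axis_kind,
            absorbance=self.samples[i],
            label=f"{self.concentrations[i]:g} mmol/L",
        )

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(
            axis_values=self.axis,
            axis_kind=self.axis_kind,
            absorbance=self.samples.mean(axis=0),
            label="mean",
        )

    def with_samples(self, samples: np.ndarray, axis: np.ndarray | None = None) -> "SpectraSet":
        """Copy of this set with new absorbance data (and optionally axis)."""
        return SpectraSet(
            axis=self.axis if axis is None else axis,
            samples=samples,
            concentrations=self.concentrations.copy(),
            region=self.region,
        )


class SourceComponent(str, enum.Enum):
    WATER = "water"
    LACTATE = "lactate"
    OTHER = "other"


@dataclass
class BandAssignment:
    """A vibrational-band assignment: position, bond, harmonic, origin."""

    center: float
    bond: str
    harmonic_label: str = ""
    source_component: SourceComponent = SourceComponent.OTHER

    def __post_init__(self) -> None:
        self.source_component = SourceComponent(self.source_component)


def read_spectra_csv(path, region: Region) -> SpectraSet:
    """Read a wide spectra CSV.

    Layout: header row ``axis_label, c_1, ..., c_N`` with reference
    concentrations in mmol/L; body rows ``axis_value, A_1, ..., A_N``.
    Descending axes (the native MIR ordering) are reversed to ascending,
    reordering the rows consistently.
    """
    region = Region(region)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
    if not header:
        raise FormatError(f"{path}: empty file")
    tokens = header.split(",")
    if len(tokens) < 2:
        raise FormatError(f"{path}: header must list at least one sample column")
    try:
        concentrations = np.array([float(t) for t in tokens[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: header concentrations not numeric: {exc}") from exc

    try:
        body = pd.read_csv(path, skiprows=1, header=None, dtype=str,
                           keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed rows: {exc}") from exc
    if body.shape[1] != len(tokens):
        raise FormatError(
            f"{path}: body has {body.shape[1]} columns but header has {len(tokens)}"
        )
    raw = body.to_numpy()
    try:
        # numpy's string-to-float conversion is correctly rounded, so a
        # repr-precision CSV round-trips bit-exactly
        values = raw.astype(np.float64)
    except ValueError:
        for r in range(raw.shape[0]):
            for c in range(raw.shape[1]):
                try:
                    float(raw[r, c])
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell {raw[r, c]!r} at data "
                        f"row {r + 1}, column {c + 1}"
                    ) from None
        raise FormatError(f"{path}: non-numeric data") from None
    axis = values[:, 0]
    data = values[:, 1:]
    if axis.size >= 2 and np.all(np.diff(axis) < 0):
        axis = axis[::-1].copy()
        data = data[::-1].copy()
    return SpectraSet(
        axis=axis, samples=data.T, concentrations=concentrations, region=region
    )


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """Write a :class:`SpectraSet` as a wide CSV at full float precision."""
    if spectra.n_samples == 0:
        raise ValidationError("cannot write a set with no samples")
    header = ",".join(
        [spectra.axis_kind.value] + [repr(float(c)) for c in spectra.concentrations]
    )
    cols = spectra.samples.T  # (P, N)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header + "\n")
            for x, row in zip(spectra.axis, cols):
                fh.write(
                    ",".join([repr(float(x))] + [repr(float(v)) for v in row]) + "\n"
                )
    except OSError as exc:
        raise IOError(f"cannot write spectra CSV to {path}: {exc}") from exc


def restrict_to_axis_window(spectra: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Restrict a set to axis points in the closed interval [lo, hi]."""
    if not lo < hi:
        raise ValidationError(f"window requires lo < hi, got [{lo}, {hi}]")
    keep = (spectra.axis >= lo) & (spectra.axis <= hi)
    if not np.any(keep):
        raise ValidationError(
            f"window [{lo}, {hi}] does not overlap axis "
            f"[{spectra.axis[0]}, {spectra.axis[-1]}]"
        )
    return spectra.with_samples(spectra.samples[:, keep], axis=spectra.axis[keep])
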