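"""Synthetic sodium-lactate-in-PBS spectra via a Beer-Lambert band model.

The generator emulates the measurement study this package analyzes:
37 equivolume samples of sodium lactate (NaLac) in isotonic PBS spanning
0-20 mmol/L (plus a six-sample 100-600 mmol/L high-concentration series),
measured in three spectral regions.  Each region's spectrum is modeled as a
sum of water O-H bands and much weaker lactate C-H / C-C / C-O / CH3 / COO-
bands, each a Gaussian or Lorentzian profile.

Two physical features matter for calibration:

* **Beer-Lambert linearity** - every lactate band scales linearly with the
  analyte concentration ``c``.
* **Water displacement** - samples are prepared by serially diluting a
  600 mmol/L NaLac stock with PBS, so the water fraction falls linearly as
  lactate rises: the water amplitude is scaled by ``w(c) = 1 - c/600``.
  This confound means even water-only channels carry concentration
  information, which dominates the UV/Vis calibration.

On top of the chemistry, an :class:`InstrumentModel` adds per-sample
multiplicative gain (scatter), a linear baseline, white detector noise, and
inflated noise inside detector-saturation regions (where water absorbs so
strongly that the detectors starve; these are the regions masked during
preprocessing).  All randomness flows from a single integer seed.

Band widths and absorptivities are not reported by any reference at this
concentration range; the defaults in the tables below are chosen so that at
20 mmol/L the largest lactate band is ~1e-3 of the dominant water band,
i.e. the analyte signal is invisible to the eye and must be recovered by
multivariate calibration.  See ``docs/methods.md`` for the full constants
table and rationale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .spectra_core import (
    BandAssignment,
    Region,
    REGION_GRIDS,
    SourceComponent,
    SpectraSet,
    region_axis,
)

__all__ = [
    "BandShape",
    "BandModel",
    "BandLibrary",
    "InstrumentModel",
    "SamplePlan",
    "PlanKind",
    "ATOMIC_WEIGHTS",
    "NALAC_MOLAR_MASS",
    "STOCK_CONCENTRATION_MMOL_L",
    "build_sample_plan",
    "stock_mass_for",
    "atr_reflection_count",
    "build_band_library",
    "default_instrument",
    "generate_spectra",
]

#: Standard atomic weights (g/mol), sufficient for sodium L-lactate C3H5NaO3.
ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "Na": 22.98977, "O": 15.999}

#: Molar mass of sodium L-lactate (C3H5NaO3), g/mol, to the printed precision.
NALAC_MOLAR_MASS = round(
    3 * ATOMIC_WEIGHTS["C"]
    + 5 * ATOMIC_WEIGHTS["H"]
    + ATOMIC_WEIGHTS["Na"]
    + 3 * ATOMIC_WEIGHTS["O"],
    2,
)

#: Concentration of the NaLac stock solution all samples are diluted from.
STOCK_CONCENTRATION_MMOL_L = 600.0


class BandShape(str, enum.Enum):
    GAUSSIAN = "gaussian"
    LORENTZIAN = "lorentzian"


@dataclass
class BandModel:
    """One absorption band: center, FWHM, line shape and strength.

    ``absorptivity`` is the band-center amplitude in AU per (mmol/L) for
    analyte bands; for water bands it is the amplitude in AU of the
    undisplaced (pure-solvent) spectrum.
    """

    center: float
    fwhm: float
    absorptivity: float
    shape: BandShape = BandShape.GAUSSIAN

    def __post_init__(self) -> None:
        self.shape = BandShape(self.shape)
        if self.fwhm <= 0:
            raise ValidationError("band fwhm must be positive")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-amplitude line shape evaluated on ``axis``."""
        x = (axis - self.center) / self.fwhm
        if self.shape is BandShape.GAUSSIAN:
            return np.exp(-4.0 * math.log(2.0) * x * x)
        return 1.0 / (1.0 + 4.0 * x * x)

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        return self.absorptivity * self.profile(axis)


@dataclass
class BandLibrary:
    """Region-specific collection of water and lactate bands."""

    region: Region
    water_bands: list[BandModel]
    lactate_bands: list[BandModel]
    assignments: list[BandAssignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.region = Region(self.region)
        lo, hi, _ = REGION_GRIDS[self.region]
        for band in self.water_bands + self.lactate_bands:
            if not lo <= band.center <= hi:
                raise ValidationError(
                    f"band center {band.center} outside {self.region.value} "
                    f"axis range [{lo}, {hi}]"
                )

    @property
    def all_bands(self) -> list[BandModel]:
        return list(self.water_bands) + list(self.lactate_bands)

    def assignment_for(self, center: float) -> BandAssignment | None:
        for a in self.assignments:
            if a.center == center:
                return a
        return None

    def to_csv(self, path) -> None:
        rows = []
        for comp, bands in (("water", self.water_bands), ("lactate", self.lactate_bands)):
            for b in bands:
                a = self.assignment_for(b.center)
                rows.append(
                    {
                        "center": b.center,
                        "fwhm": b.fwhm,
                        "shape": b.shape.value,
                        "absorptivity": b.absorptivity,
                        "bond": a.bond if a else "",
                        "harmonic": a.harmonic_label if a else "",
                        "component": comp,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, region: Region) -> "BandLibrary":
        df = pd.read_csv(path)
        water, lactate, assignments = [], [], []
        for _, row in df.iterrows():
            band = BandModel(
                center=float(row["center"]),
                fwhm=float(row["fwhm"]),
                absorptivity=float(row["absorptivity"]),
                shape=BandShape(row["shape"]),
            )
            comp = SourceComponent(row["component"])
            (water if comp is SourceComponent.WATER else lactate).append(band)
            assignments.append(
                BandAssignment(
                    center=band.center,
                    bond=str(row.get("bond", "")),
                    harmonic_label=str(row.get("harmonic", "")),
                    source_component=comp,
                )
            )
        return cls(region=Region(region), water_bands=water,
                   lactate_bands=lactate, assignments=assignments)


@dataclass
class InstrumentModel:
    """Stochastic instrument imperfections layered onto the clean spectra.

    All standard deviations are per-sample draw widths; ``noise_sd`` is the
    per-channel white-noise width, inflated to ``inflated_noise_sd`` inside
    ``saturation_regions`` (closed intervals in axis units).
    """

    baseline_offset_sd: float = 0.0  # AU
    baseline_slope_sd: float = 0.0  # AU per axis unit
    scatter_slope_sd: float = 0.0  # relative multiplicative gain spread
    noise_sd: float = 0.0  # AU
    saturation_regions: list[tuple[float, float]] = field(default_factory=list)
    inflated_noise_sd: float = 0.0  # AU, inside saturation regions
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_offset_sd", "baseline_slope_sd",
                     "scatter_slope_sd", "noise_sd", "inflated_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def scaled(self, factor: float) -> "InstrumentModel":
        """All stochastic widths multiplied by ``factor`` (0 = noiseless)."""
        if factor < 0:
            raise ValidationError("noise scale factor must be non-negative")
        return replace(
            self,
            baseline_offset_sd=self.baseline_offset_sd * factor,
            baseline_slope_sd=self.baseline_slope_sd * factor,
            scatter_slope_sd=self.scatter_slope_sd * factor,
            noise_sd=self.noise_sd * factor,
            inflated_noise_sd=self.inflated_noise_sd * factor,
        )


class PlanKind(str, enum.Enum):
    MAIN37 = "main37"
    HC6 = "hc6"
    CUSTOM = "custom"


@dataclass
class SamplePlan:
    """Ordered list of sample concentrations (mmol/L)."""

    concentrations: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.atleast_1d(
            np.asarray(self.concentrations, dtype=float)
        )
        if self.concentrations.size == 0:
            raise ValidationError("sample plan must contain at least one level")
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be non-negative")

    def __len__(self) -> int:
        return self.concentrations.size


def build_sample_plan(
    kind: PlanKind | str, custom_levels: Sequence[float] | None = None
) -> SamplePlan:
    """Build the dilution plan for a measurement series.

    ``main37``: 21 samples from 0 to 5 mmol/L in 0.25 mmol/L steps followed
    by 16 samples from 5 to 20 mmol/L in 1 mmol/L steps (5 mmol/L appears in
    both sub-ranges as two distinct physical samples, giving 37 in total).
    ``hc6``: the six high-concentration validation samples 100-600 mmol/L.
    """
    kind = PlanKind(kind)
    if kind is PlanKind.CUSTOM:
        if custom_levels is None:
            raise ValidationError("custom plan requires custom_levels")
        return SamplePlan(np.asarray(custom_levels, dtype=float), "custom plan")
    if custom_levels is not None:
        raise ValidationError("custom_levels only valid with kind='custom'")
    if kind is PlanKind.MAIN37:
        low = 0.25 * np.arange(21)  # 0 .. 5 in 0.25 steps
        high = 5.0 + np.arange(16)  # 5 .. 20 in 1 steps
        return SamplePlan(
            np.concatenate([low, high]),
            "37 NaLac-in-PBS samples, 0-20 mmol/L serial dilution",
        )
    return SamplePlan(
        100.0 * np.arange(1, 7), "6 high-concentration validation samples"
    )


def stock_mass_for(concentration: float, volume: float, molar_mass: float) -> float:
    """Mass (g) of solute to dissolve for a stock of the given strength.

    ``concentration`` in mmol/L, ``volume`` in L, ``molar_mass`` in g/mol.
    """
    if concentration <= 0 or volume <= 0 or molar_mass <= 0:
        raise ValidationError("concentration, volume and molar mass must be positive")
    return concentration / 1000.0 * volume * molar_mass


def atr_reflection_count(
    crystal_length: float, crystal_thickness: float, incidence_angle: float
) -> int:
    """Number of internal reflections in an ATR crystal.

    Ray geometry: one bounce advances the ray by ``2 t tan(theta)`` along an
    internally reflecting slab of thickness ``t`` (mm) at incidence angle
    ``theta`` (degrees); the count over a crystal of the given length (mm)
    is the floor of the ratio.
    """
    if crystal_length <= 0 or crystal_thickness <= 0:
        raise ValidationError("crystal dimensions must be positive")
    if not 0 < incidence_angle < 90:
        raise ValidationError("incidence angle must be in (0, 90) degrees")
    advance = 2.0 * crystal_thickness * math.tan(math.radians(incidence_angle))
    return int(math.floor(crystal_length / advance))


# --- band tables ------------------------------------------------------------
# (center, fwhm, amplitude, bond, harmonic label); axis units nm or cm^-1.
# Water amplitudes are pure-solvent AU; lactate values are AU per mmol/L and
# sized so 20 mmol/L reaches ~1e-3 of the dominant water band of the region.

_UVVIS_WATER = [
    (300.0, 40.0, 0.040, "O–H electronic/vibronic absorption edge", "UV edge"),
    (401.0, 18.0, 0.0005, "O–H stretch", "8th harmonic"),
    (449.0, 20.0, 0.0008, "O–H overtone", "unassigned order"),
    (485.0, 20.0, 0.0012, "O–H stretch + bend (ν3)", "6th harmonic (text-only)"),
    (513.0, 22.0, 0.0015, "O–H stretch (ν1/ν3)", "6th harmonic"),
    (605.0, 25.0, 0.004, "O–H stretch", "5th harmonic"),
    (662.0, 25.0, 0.008, "O–H stretch + bend (ν3)", "4th harmonic (text-only)"),
    (742.0, 30.0, 0.025, "O–H stretch (ν1/ν3)", "4th harmonic"),
]
_UVVIS_LACTATE = [
    (747.0, 25.0, 1.0e-6, "lactate absorption (water-masked)", ""),
]

_NIR_WATER = [
    (970.0, 45.0, 0.06, "O–H stretch", "2nd overtone"),
    (1180.0, 60.0, 0.12, "O–H stretch", "2nd overtone"),
    (1450.0, 90.0, 1.2, "O–H stretch", "1st overtone"),
    (1920.0, 130.0, 1.5, "O–H stretch + O–H bend", "combination"),
]
_NIR_LACTATE = [
    (1215.0, 30.0, 2.5e-5, "C–H stretch", "2nd overtone"),
    (1684.0, 40.0, 4.0e-5, "C–H stretch", "1st overtone"),
    (1730.0, 40.0, 4.5e-5, "C–H stretch", "1st overtone"),
    (2259.0, 35.0, 6.0e-5, "C–H stretch + C–H bend", "combination"),
    (2299.0, 35.0, 5.0e-5, "C–H stretch + C–H bend", "combination"),
]

_MIR_WATER = [
    (1638.0, 85.0, 0.35, "O–H bend", "fundamental"),
    (3283.0, 400.0, 1.0, "O–H stretch", "fundamental"),
]
# Fingerprint bands (< 1500 cm^-1) rendered Lorentzian, diagnostic Gaussian.
_MIR_LACTATE_FINGERPRINT = [
    (779.0, 25.0, 2.0e-5, "C–H bend", "fingerprint"),
    (854.0, 25.0, 2.5e-5, "C–H bend", "fingerprint"),
    (940.0, 30.0, 2.0e-5, "C–C stretch", "fingerprint"),
    (1040.0, 30.0, 4.0e-5, "C–O stretch", "fingerprint"),
    (1126.0, 25.0, 5.0e-5, "C–O / C–OH stretch", "fingerprint"),
    (1157.0, 25.0, 4.5e-5, "C–OH stretch", "fingerprint"),
    (1315.0, 30.0, 3.0e-5, "CH3 stretch (medium)", "fingerprint"),
    (1365.0, 25.0, 3.5e-5, "CH3 stretch (medium)", "fingerprint"),
    (1416.0, 30.0, 4.0e-5, "CH3 / COO– symmetric stretch", "fingerprint"),
    (1455.0, 30.0, 4.5e-5, "CH3 stretch (medium)", "fingerprint"),
]
_MIR_LACTATE_DIAGNOSTIC = [
    (2852.0, 40.0, 2.0e-5, "C–H stretch", "diagnostic"),
    (2930.0, 40.0, 2.5e-5, "CH3 symmetric stretch", "diagnostic"),
    (2988.0, 40.0, 2.0e-5, "CH3 asymmetric stretch", "diagnostic"),
    (3159.0, 60.0, 1.5e-5, "C–H stretch (O–H shoulder)", "diagnostic"),
]


def _bands(table, shape: BandShape) -> list[BandModel]:
    return [
        BandModel(center=c, fwhm=f, absorptivity=a, shape=shape)
        for c, f, a, _, _ in table
    ]


def _assignments(table, component: SourceComponent) -> list[BandAssignment]:
    return [
        BandAssignment(center=c, bond=bond, harmonic_label=harm,
                       source_component=component)
        for c, _, _, bond, harm in table
    ]


def build_band_library(region: Region | str) -> BandLibrary:
    """Band library for one region, encoding the study's peak assignments."""
    region = Region(region)
    if region is Region.UVVIS:
        water_t, lactate_t = _UVVIS_WATER, _UVVIS_LACTATE
        water = _bands(water_t, BandShape.GAUSSIAN)
        lactate = _bands(lactate_t, BandShape.GAUSSIAN)
    elif region is Region.NIR:
        water_t, lactate_t = _NIR_WATER, _NIR_LACTATE
        water = _bands(water_t, BandShape.GAUSSIAN)
        lactate = _bands(lactate_t, BandShape.GAUSSIAN)
    else:
        water_t = _MIR_WATER
        lactate_t = _MIR_LACTATE_FINGERPRINT + _MIR_LACTATE_DIAGNOSTIC
        water = _bands(water_t, BandShape.GAUSSIAN)
        lactate = _bands(_MIR_LACTATE_FINGERPRINT, BandShape.LORENTZIAN) + _bands(
            _MIR_LACTATE_DIAGNOSTIC, BandShape.GAUSSIAN
        )
    assignments = _assignments(water_t, SourceComponent.WATER) + _assignments(
        lactate_t, SourceComponent.LACTATE
    )
    return BandLibrary(
        region=region, water_bands=water, lactate_bands=lactate,
        assignments=assignments,
    )


#: Saturation (masked) regions per spectral region, axis units.
SATURATION_REGIONS: dict[Region, list[tuple[float, float]]] = {
    Region.UVVIS: [],
    Region.NIR: [(1900.0, 1960.0), (2350.0, 2600.0)],
    Region.MIR: [(500.0, 700.0)],
}


def default_instrument(region: Region | str, seed: int = 0) -> InstrumentModel:
    """Default instrument imperfections for a region (documented defaults)."""
    region = Region(region)
    return InstrumentModel(
        baseline_offset_sd=1.0e-3,
        baseline_slope_sd=1.0e-6,
        scatter_slope_sd=1.0e-3,
        noise_sd=5.0e-5 if region is Region.UVVIS else 1.0e-4,
        saturation_regions=list(SATURATION_REGIONS[region]),
        inflated_noise_sd=5.0e-3,
        seed=seed,
    )


def generate_spectra(
    plan: SamplePlan,
    library: BandLibrary,
    instrument: InstrumentModel,
    grid: tuple[float, float, float] | None = None,
) -> SpectraSet:
    """Generate a synthetic :class:`SpectraSet` for a dilution plan.

    For a sample at lactate concentration ``c`` (mmol/L)::

        A(x) = gain * [ w(c) * sum(water bands) + c * sum(lactate bands)
                        + baseline(x) ] + noise(x)

    with ``w(c) = 1 - c / 600`` (equivolume dilution of a 600 mmol/L stock
    displaces solvent), per-sample ``gain ~ 1 + N(0, scatter_slope_sd)``,
    ``baseline`` an affine trace with random offset and slope, and channel
    noise whose width is inflated inside the instrument's saturation
    regions.  Identical inputs (including the seed) give identical output.
    """
    region = library.region
    lo, hi, step = REGION_GRIDS[region]
    if grid is None:
        axis = region_axis(region)
    else:
        glo, ghi, gstep = grid
        if glo < lo or ghi > hi or not glo < ghi or gstep <= 0:
            raise ValidationError(
                f"grid {grid} incompatible with {region.value} range "
                f"[{lo}, {hi}]"
            )
        n = int(round((ghi - glo) / gstep)) + 1
        axis = glo + gstep * np.arange(n)

    for slo, shi in instrument.saturation_regions:
        if shi < axis[0] or slo > axis[-1]:
            raise ValidationError(
                f"saturation region [{slo}, {shi}] outside axis range"
            )

    water = np.zeros_like(axis)
    for band in library.water_bands:
        water += band.evaluate(axis)
    lactate = np.zeros_like(axis)
    for band in library.lactate_bands:
        lactate += band.evaluate(axis)

    noise_sd = np.full_like(axis, instrument.noise_sd)
    for slo, shi in instrument.saturation_regions:
        noise_sd[(axis >= slo) & (axis <= shi)] = instrument.inflated_noise_sd

    rng = np.random.default_rng(instrument.seed)
    mid = 0.5 * (axis[0] + axis[-1])
    rows = np.empty((len(plan), axis.size))
    for i, c in enumerate(plan.concentrations):
        gain = 1.0 + instrument.scatter_slope_sd * rng.standard_normal()
        offset = instrument.baseline_offset_sd * rng.standard_normal()
        slope = instrument.baseline_slope_sd * rng.standard_normal()
        baseline = offset + slope * (axis - mid)
        w = 1.0 - c / STOCK_CONCENTRATION_MMOL_L
        clean = w * water + c * lactate + baseline
        noise = noise_sd * rng.standard_normal(axis.size)
        rows[i] = gain * clean + noise

    return SpectraSet(
        axis=axis, samples=rows, concentrations=plan.concentrations.copy(),
        region=region,
    )
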