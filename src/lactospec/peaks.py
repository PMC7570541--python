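"""Peak detection, band assignment and Beer-Lambert linearity checks.

After baseline subtraction a difference spectrum carries positive-going
analyte bands and negative-going solvent (water) bands, so detection
supports both polarities.  Peaks are local extrema filtered by topographic
prominence (height above the higher of the two flanking valleys); the
default prominence threshold is 3x the median absolute deviation of the
first-differenced signal, a robust estimate of the channel-to-channel
noise floor.  Detected peaks are assigned to the nearest library band
within a tolerance (default 10 axis units, narrower than any inter-band
gap in the libraries).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import ValidationError
from .spectra_core import BandAssignment, SpectraSet, Spectrum
from .synth_spectra import BandLibrary

__all__ = ["Polarity", "PeakCall", "detect_peaks", "assign_bands",
           "linearity_check", "peaks_to_csv"]


class Polarity(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    BOTH = "both"


@dataclass
class PeakCall:
    """One detected peak, optionally matched to a known vibrational band."""

    position: float  # axis units
    height: float  # signed absorbance at the extremum, AU
    prominence: float  # AU, always >= 0
    polarity: Polarity = Polarity.POSITIVE
    assignment: BandAssignment | None = None
    assignment_distance: float = float("nan")
    ambiguous: bool = False  # the matched band also matched another call


def _default_prominence(y: np.ndarray) -> float:
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return 3.0 * float(mad)


def detect_peaks(
    spectrum: Spectrum,
    min_prominence: float | None = None,
    polarity: Polarity | str = Polarity.POSITIVE,
) -> list[PeakCall]:
    """Local extrema of the requested polarity, sorted by axis position."""
    polarity = Polarity(polarity)
    y = spectrum.absorbance
    if y.size < 3:
        raise ValidationError("peak detection needs at least 3 axis points")
    if min_prominence is None:
        min_prominence = _default_prominence(y)
    if min_prominence < 0:
        raise ValidationError("min_prominence must be non-negative")

    calls: list[PeakCall] = []
    tasks = []
    if polarity in (Polarity.POSITIVE, Polarity.BOTH):
        tasks.append((y, Polarity.POSITIVE))
    if polarity in (Polarity.NEGATIVE, Polarity.BOTH):
        tasks.append((-y, Polarity.NEGATIVE))
    for signal, pol in tasks:
        idx, props = find_peaks(signal, prominence=min_prominence)
        for j, i in enumerate(idx):
            calls.append(
                PeakCall(
                    position=float(spectrum.axis_values[i]),
                    height=float(y[i]),
                    prominence=float(props["prominences"][j]),
                    polarity=pol,
                )
            )
    calls.sort(key=lambda c: c.position)
    return calls


def assign_bands(
    calls: Sequence[PeakCall], library: BandLibrary, tolerance: float = 10.0
) -> list[PeakCall]:
    """Match each call to the nearest library band within ``tolerance``.

    Unmatched calls keep ``assignment=None``.  When one band matches more
    than one call, all of its calls are flagged ``ambiguous``.
    """
    if tolerance <= 0:
        raise ValidationError("assignment tolerance must be positive")
    assignments = library.assignments
    if not assignments:
        return [replace(c) for c in calls]
    centers = np.array([a.center for a in assignments])
    out: list[PeakCall] = []
    matched_center_counts: dict[float, int] = {}
    for call in calls:
        dist = np.abs(centers - call.position)
        j = int(np.argmin(dist))
        if dist[j] <= tolerance:
            out.append(
                replace(
                    call,
                    assignment=assignments[j],
                    assignment_distance=float(dist[j]),
                )
            )
            matched_center_counts[centers[j]] = (
                matched_center_counts.get(centers[j], 0) + 1
            )
        else:
            out.append(replace(call, assignment=None,
                               assignment_distance=float("nan")))
    for k, call in enumerate(out):
        if call.assignment is not None and (
            matched_center_counts.get(call.assignment.center, 0) > 1
        ):
            out[k] = replace(call, ambiguous=True)
    return out


def linearity_check(
    spectra: SpectraSet, center: float, half_window: float
) -> tuple[float, float, float]:
    """OLS line of the window-max absorbance against concentration.

    Returns ``(slope, intercept, r2)`` for the maximum absorbance within
    ``[center - half_window, center + half_window]`` per sample.
    """
    if half_window <= 0:
        raise ValidationError("half_window must be positive")
    lo, hi = center - half_window, center + half_window
    if lo < spectra.axis[0] or hi > spectra.axis[-1]:
        raise ValidationError("window extends outside the axis")
    if spectra.n_samples < 3:
        raise ValidationError("linearity check needs at least 3 samples")
    sel = (spectra.axis >= lo) & (spectra.axis <= hi)
    feature = spectra.samples[:, sel].max(axis=1)
    c = spectra.concentrations
    slope, intercept = np.polyfit(c, feature, 1)
    fitted = slope * c + intercept
    ss_res = float(np.sum((feature - fitted) ** 2))
    ss_tot = float(np.sum((feature - feature.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def peaks_to_csv(calls: Sequence[PeakCall], path) -> None:
    """Export a peak table (position, height, prominence, assignment)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("position,height,prominence,polarity,bond,component,"
                 "assignment_distance,ambiguous\n")
        for c in calls:
            bond = c.assignment.bond if c.assignment else ""
            comp = (
                c.assignment.source_component.value if c.assignment else ""
            )
            fh.write(
                f"{c.position!r},{c.height!r},{c.prominence!r},"
                f"{c.polarity.value},{bond},{comp},"
                f"{c.assignment_distance!r},{c.ambiguous}\n"
            )
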