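"""Spectral preprocessing: masking, baseline subtraction, RLMSC, SG filter.

The chain mirrors standard chemometric practice for absorbance spectra of
aqueous samples:

1. **mask** - drop detector-saturation regions (NIR 1900-1960 nm and
   2350-2600 nm; MIR 500-700 cm^-1) where water absorbs so strongly that
   only noise is recorded;
2. **baseline subtraction** - subtract the 0 mmol/L (pure matrix) spectrum
   from every sample, suppressing the dominant water features;
3. **RLMSC** - robust linear multiplicative scatter correction: each
   spectrum is robustly regressed on a reference (the set mean) as
   ``x ~ a*r + b`` and corrected to ``(x - b)/a``, removing per-sample gain
   and offset;
4. **Savitzky-Golay** derivative filtering (order 2, first derivative;
   window 21/51/31 points for UV-Vis/NIR/MIR) to remove residual baseline
   and high-frequency noise.

SG weights are computed here from the least-squares polynomial design
directly (not delegated to a library filter), since the derivative filter
is part of the method under study; tests cross-check them against an
independent implementation.  After masking, the axis consists of disjoint
uniform blocks; the filter is applied per block so no information leaks
across a masked gap, and edges are handled by evaluating the local
polynomial fitted to the nearest full window (no padding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .errors import DegenerateSampleError, ValidationError
from .spectra_core import Region, Spectrum, SpectraSet

__all__ = [
    "PreprocessConfig",
    "PreprocessResult",
    "DEFAULT_SG_WINDOWS",
    "DEFAULT_MASK_REGIONS",
    "mask_noise_regions",
    "baseline_subtract",
    "rlmsc",
    "robust_affine_fit",
    "sg_coefficients",
    "apply_savgol",
    "preprocess_pipeline",
]

#: SG window length (points) per region; polynomial order 2, derivative 1.
DEFAULT_SG_WINDOWS: dict[Region, int] = {
    Region.UVVIS: 21,
    Region.NIR: 51,
    Region.MIR: 31,
}

#: Detector-saturation intervals masked before any other step (axis units).
DEFAULT_MASK_REGIONS: dict[Region, list[tuple[float, float]]] = {
    Region.UVVIS: [],
    Region.NIR: [(1900.0, 1960.0), (2350.0, 2600.0)],
    Region.MIR: [(500.0, 700.0)],
}


@dataclass
class PreprocessConfig:
    """Region-specific preprocessing settings."""

    region: Region
    mask_regions: list[tuple[float, float]] = field(default_factory=list)
    do_baseline_subtract: bool = True
    do_rlmsc: bool = True
    do_savgol: bool = True
    sg_window: int = 21
    sg_polyorder: int = 2
    sg_deriv: int = 1

    def __post_init__(self) -> None:
        self.region = Region(self.region)
        self.mask_regions = [(float(lo), float(hi)) for lo, hi in self.mask_regions]
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValidationError(
                "sg_window must be odd and greater than sg_polyorder"
            )
        if self.sg_deriv > self.sg_polyorder:
            raise ValidationError("sg_deriv must not exceed sg_polyorder")

    @classmethod
    def default(cls, region: Region | str) -> "PreprocessConfig":
        """The full visualization/calibration chain with region defaults."""
        region = Region(region)
        return cls(
            region=region,
            mask_regions=list(DEFAULT_MASK_REGIONS[region]),
            sg_window=DEFAULT_SG_WINDOWS[region],
        )

    @classmethod
    def calibration_default(cls, region: Region | str) -> "PreprocessConfig":
        """Default chain for PLS calibration: RLMSC disabled.

        After baseline subtraction the between-sample variation of these
        spectra is (to first order) proportional to the analyte
        concentration; an affine normalization against the mean difference
        spectrum would then remove exactly the signal the calibration needs
        (see docs/methods.md).  RLMSC therefore stays available for
        visualization and gain diagnostics but is off for calibration.
        """
        cfg = cls.default(region)
        return replace(cfg, do_rlmsc=False)

    def to_dict(self) -> dict:
        return {
            "region": self.region.value,
            "mask_regions": [list(r) for r in self.mask_regions],
            "do_baseline_subtract": self.do_baseline_subtract,
            "do_rlmsc": self.do_rlmsc,
            "do_savgol": self.do_savgol,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "sg_deriv": self.sg_deriv,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "PreprocessConfig":
        data = dict(data)
        data["mask_regions"] = [tuple(r) for r in data.get("mask_regions", [])]
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PreprocessConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def mask_noise_regions(
    spectra: SpectraSet, regions: Sequence[tuple[float, float]]
) -> SpectraSet:
    """Remove axis points inside any of the closed intervals ``regions``."""
    if not regions:
        return spectra.with_samples(spectra.samples.copy())
    keep = np.ones(spectra.n_channels, dtype=bool)
    for lo, hi in regions:
        keep &= ~((spectra.axis >= lo) & (spectra.axis <= hi))
    if not np.any(keep):
        raise ValidationError("masking removed every axis point")
    return spectra.with_samples(spectra.samples[:, keep], axis=spectra.axis[keep])


def baseline_subtract(spectra: SpectraSet) -> SpectraSet:
    """Subtract the 0 mmol/L base spectrum (mean of them, if several)."""
    zero = spectra.concentrations == 0.0
    if not np.any(zero):
        raise ValidationError(
            "baseline subtraction requires at least one 0 mmol/L sample"
        )
    base = spectra.samples[zero].mean(axis=0)
    return spectra.with_samples(spectra.samples - base)


def robust_affine_fit(
    x: np.ndarray,
    r: np.ndarray,
    tuning_constant: float = 4.685,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Robustly fit ``x ~ a*r + b`` by IRLS with the Tukey bisquare weight.

    Initialized at the OLS fit; the residual scale is re-estimated each
    iteration as MAD/0.6745.  Returns ``(a, b)``.

    The bisquare downweights gross channel outliers; when a spectrum has no
    affine relation to the reference at all, the shrinking scale can end up
    rejecting nearly every channel, leaving an arbitrary fit.  A robust
    estimate is only accepted while a majority of the channel weight mass
    survives; otherwise the OLS fit is returned.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if x.size != r.size or x.size < 2:
        raise ValidationError("robust fit needs two equal-length vectors, n >= 2")
    design = np.column_stack([r, np.ones_like(r)])
    beta_ols, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta = beta_ols
    for _ in range(max_iter):
        resid = x - design @ beta
        scale = np.median(np.abs(resid)) / 0.6745  # MAD about zero
        scale = max(scale, 1e-12)
        u = resid / (tuning_constant * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
        if w.sum() < 0.5 * x.size:
            beta = beta_ols
            break
        wd = design * w[:, None]
        try:
            beta_new = np.linalg.solve(wd.T @ design, wd.T @ x)
        except np.linalg.LinAlgError:
            beta = beta_ols
            break
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            break
    if not np.all(np.isfinite(beta)):
        beta = beta_ols
    return float(beta[0]), float(beta[1])


def rlmsc(spectra: SpectraSet, reference: Spectrum | np.ndarray | None = None) -> SpectraSet:
    """Robust linear multiplicative scatter correction against a reference.

    Each sample ``x`` is robustly fitted as ``x ~ a*r + b`` and replaced by
    ``(x - b)/a``.  The reference defaults to the set's mean spectrum.
    """
    if spectra.n_channels < 2:
        raise ValidationError("RLMSC needs at least two axis points")
    if reference is None:
        ref = spectra.samples.mean(axis=0)
    elif isinstance(reference, Spectrum):
        ref = reference.absorbance
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.size != spectra.n_channels:
        raise ValidationError("reference length does not match set channels")
    corrected = np.empty_like(spectra.samples)
    for i in range(spectra.n_samples):
        if not np.any(spectra.samples[i]):
            # an identically-null spectrum (e.g. the base sample after
            # baseline subtraction) has no scatter to correct
            corrected[i] = 0.0
            continue
        a, b = robust_affine_fit(spectra.samples[i], ref)
        if abs(a) < 1e-12:
            raise DegenerateSampleError(
                f"sample {i}: multiplicative term |a|={abs(a):.3e} is degenerate"
            )
        corrected[i] = (spectra.samples[i] - b) / a
    return spectra.with_samples(corrected)


def sg_coefficients(
    window: int, polyorder: int, deriv: int, spacing: float = 1.0
) -> np.ndarray:
    """Savitzky-Golay convolution weights from the polynomial LS design.

    A degree-``polyorder`` polynomial is fitted to the ``window`` points at
    offsets ``-h..h`` (h = window//2); the returned weights ``w`` give the
    filtered value at the window center as ``sum_j w[j] * y[center-h+j]``,
    estimating the ``deriv``-th derivative for a grid spacing ``spacing``.
    Smoothing weights (deriv=0) sum to 1; derivative weights sum to 0.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValidationError("window must be odd and greater than polyorder")
    if deriv > polyorder or deriv < 0:
        raise ValidationError("deriv must satisfy 0 <= deriv <= polyorder")
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    h = window // 2
    offsets = np.arange(-h, h + 1, dtype=float)
    design = offsets[:, None] ** np.arange(polyorder + 1)[None, :]
    # Row `deriv` of the pseudoinverse maps samples to the fitted
    # polynomial coefficient of x^deriv; scale to the derivative value.
    weights = np.linalg.pinv(design)[deriv]
    return weights * math.factorial(deriv) / spacing**deriv


def _contiguous_blocks(axis: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [start, stop) of uniformly spaced contiguous blocks.

    A new block starts wherever the axis step changes (masking carves a
    uniform grid into disjoint uniform segments separated by larger gaps).
    """
    n = axis.size
    if n < 3:
        return [(0, n)]
    blocks = []
    start = 0
    while start < n:
        if start == n - 1:
            blocks.append((start, n))
            break
        spacing = axis[start + 1] - axis[start]
        stop = start + 1
        while stop < n and math.isclose(
            axis[stop] - axis[stop - 1], spacing, rel_tol=1e-9, abs_tol=1e-12
        ):
            stop += 1
        blocks.append((start, stop))
        start = stop
    return blocks


def _savgol_block(y: np.ndarray, spacing: float, window: int, polyorder: int,
                  deriv: int) -> np.ndarray:
    """Apply the SG filter to one uniformly spaced block."""
    n = y.size
    h = window // 2
    center = sg_coefficients(window, polyorder, deriv, spacing)
    out = np.empty_like(y)
    # interior: sliding dot product
    if n >= window:
        windows = np.lib.stride_tricks.sliding_window_view(y, window)
        out[h : n - h] = windows @ center
    # edges: evaluate the polynomial fitted to the nearest full window
    offsets = spacing * np.arange(window)
    powers = np.arange(polyorder + 1)
    design = offsets[:, None] ** powers[None, :]
    pinv = np.linalg.pinv(design)
    dfact = math.factorial(deriv)
    head = pinv @ y[:window]
    tail = pinv @ y[n - window :]
    for i in range(h):
        # derivative of the fitted polynomial at position offsets[i]
        out[i] = _poly_deriv_at(head, offsets[i], deriv, dfact)
    for i in range(n - window + h + 1, n):
        out[i] = _poly_deriv_at(tail, offsets[i - (n - window)], deriv, dfact)
    return out


def _poly_deriv_at(coeffs: np.ndarray, x: float, deriv: int, dfact: int) -> float:
    """deriv-th derivative of sum_k coeffs[k] x^k at x."""
    val = 0.0
    for k in range(deriv, coeffs.size):
        fall = 1.0
        for j in range(deriv):
            fall *= k - j
        val += coeffs[k] * fall * x ** (k - deriv)
    return val


def apply_savgol(spectra: SpectraSet, config: PreprocessConfig) -> SpectraSet:
    """SG-filter every sample, independently per contiguous axis block."""
    blocks = _contiguous_blocks(spectra.axis)
    out = np.empty_like(spectra.samples)
    for start, stop in blocks:
        length = stop - start
        if length < config.sg_window:
            raise ValidationError(
                f"axis block [{spectra.axis[start]}, {spectra.axis[stop - 1]}] "
                f"has {length} points, shorter than SG window {config.sg_window}"
            )
        spacing = float(spectra.axis[start + 1] - spectra.axis[start])
        for i in range(spectra.n_samples):
            out[i, start:stop] = _savgol_block(
                spectra.samples[i, start:stop], spacing,
                config.sg_window, config.sg_polyorder, config.sg_deriv,
            )
    return spectra.with_samples(out)


@dataclass
class PreprocessResult:
    """A processed set together with the ordered log of applied steps."""

    spectra: SpectraSet
    log: list[str]


def preprocess_pipeline(
    spectra: SpectraSet, config: PreprocessConfig
) -> PreprocessResult:
    """Apply mask -> baseline subtraction -> RLMSC -> SG, honoring flags."""
    if config.region != spectra.region:
        raise ValidationError(
            f"config region {config.region.value} does not match set region "
            f"{spectra.region.value}"
        )
    log: list[str] = []
    out = spectra
    if config.mask_regions:
        out = mask_noise_regions(out, config.mask_regions)
        log.append(f"mask_noise_regions: {config.mask_regions}")
    if config.do_baseline_subtract:
        out = baseline_subtract(out)
        log.append("baseline_subtract: 0 mmol/L base spectrum deducted")
    if config.do_rlmsc:
        out = rlmsc(out)
        log.append("rlmsc: robust affine correction against set mean")
    if config.do_savgol:
        out = apply_savgol(out, config)
        log.append(
            f"savitzky_golay: window={config.sg_window} "
            f"polyorder={config.sg_polyorder} deriv={config.sg_deriv}"
        )
    if out is spectra:
        out = spectra.with_samples(spectra.samples.copy())
    return PreprocessResult(spectra=out, log=log)
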