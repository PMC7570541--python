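# Methods

## The measurement study being emulated

The pipeline targets the in-vitro setting used to establish optical
lactate sensing: 37 equivolume samples of sodium L-lactate (NaLac,
C₃H₅NaO₃, molar mass 112.06 g/mol) in isotonic PBS, serially diluted from
a 600 mmol/L stock (67.236 g of powder per liter), spanning 0–20 mmol/L —
0 to 5 mmol/L in 0.25 mmol/L steps (21 samples) followed by 5 to 20 mmol/L
in 1 mmol/L steps (16 samples). The 5 mmol/L level closes the fine
sub-range and opens the coarse one, so it appears twice as two distinct
physical samples; this is the only reading consistent with 21 + 16 = 37.
A six-sample high-concentration series (100–600 mmol/L) exists for peak
validation. Spectra are taken on three grids: UV/visible 300–800 nm and
NIR 800–2600 nm at 1 nm, and MIR 4000–500 cm⁻¹ at 1 cm⁻¹ via a ZnSe ATR
trough (80 mm long, 4 mm thick, 45° incidence, hence
⌊80/(2·4·tan 45°)⌋ = 10 internal reflections). Axes are always stored
ascending; descending MIR axes are normalized on read.

## Synthetic spectra

Each spectrum is a sum of band profiles (Gaussian, or Lorentzian for the
MIR fingerprint bands) over the region's band table:

    A(x) = g · [ w(c) · Σ_water A_b φ_b(x) + c · Σ_lactate ε_b φ_b(x)
                 + β₀ + β₁ (x − x_mid) ] + n(x)

- `φ_b` is a unit-amplitude profile with the band's center and FWHM;
  water-band amplitudes `A_b` are pure-solvent AU, lactate absorptivities
  `ε_b` are AU per mmol/L.
- **Water displacement**: `w(c) = 1 − c/600`. Equivolume dilution of a
  600 mmol/L stock replaces solvent with solute, so the water signal falls
  linearly with lactate. This confound means water-dominated channels also
  carry concentration information; it is why a UV/visible calibration can
  look good while reflecting mostly the solvent, not the analyte.
- Per-sample draws from one `numpy` generator stream (single integer
  seed): gain `g ~ 1 + N(0, σ_gain)`, affine baseline offset/slope, and
  channel noise whose width is inflated inside the detector-saturation
  regions (NIR 1900–1960 and 2350–2600 nm; MIR 500–700 cm⁻¹) — the
  regions later masked. Identical inputs (seed included) reproduce the
  output bit for bit; scaling every σ by 0 gives the deterministic clean
  model.

### Constants

Band centers follow the literature assignments encoded in
`synth_spectra.py` (water O–H overtones/combinations at 401–742 nm,
970/1180/1450/1920 nm, 1638/3283 cm⁻¹; lactate C–H/C–C/C–O/CH₃ bands at
1215, 1684, 1730, 2259, 2299 nm and the ten fingerprint plus four
diagnostic MIR centers; a 747 nm lactate band hidden under water). Band
widths and absorptivities are not quantified anywhere at this
concentration range, so they are package choices, fixed once: widths of
18–130 nm (UV/Vis/NIR) and 25–400 cm⁻¹ (MIR) typical of solution-phase
bands, and absorptivities sized so that at 20 mmol/L the strongest lactate
band reaches ~10⁻³ of the region's dominant water band. That ratio pins
the difficulty regime: the analyte is invisible in the raw traces and
must be recovered multivariately. Instrument defaults: channel noise
1×10⁻⁴ AU (5×10⁻⁵ for UV/Vis), saturation-region noise 5×10⁻³ AU,
baseline offset σ 1×10⁻³ AU, baseline slope σ 1×10⁻⁶ AU per axis unit,
gain spread 0.1%. These magnitudes are typical of benchtop dual-beam and
FTIR instruments after averaging repeat scans.

### What the generator does not model

No radiative-transfer or ATR evanescent-wave physics, no temperature/pH
band shifts, no nonlinear detector response, no band-shape changes with
ionic strength, and difference spectra that are — by construction —
exactly proportional to concentration in the clean limit. Passing tests
therefore demonstrate that the analysis chain is correct and recovers
known parameters under realistic noise, not that a laboratory instrument
would achieve the same figures.

## Preprocessing chain

Order: mask → baseline subtraction → RLMSC → Savitzky–Golay, each
honoring a config flag.

- **Masking** removes closed intervals (endpoint-inclusive, matching the
  usual "1900–1960 nm" phrasing); on the NIR grid this leaves
  1801 − 61 − 251 = 1489 channels.
- **Baseline subtraction** deducts the 0 mmol/L sample's spectrum (the
  mean, if several) from every sample. The base sample's own difference
  becomes identically zero.
- **RLMSC** fits each spectrum against a reference (default: the set
  mean) as `x ≈ a·r + b` by iteratively reweighted least squares with the
  Tukey bisquare (c = 4.685), scale = MAD/0.6745 about zero, initialized
  at OLS, ≤ 50 iterations, convergence at 1e−10; corrected spectrum
  `(x − b)/a`. Two safeguards beyond the textbook recipe: a robust
  solution is only accepted while a majority of the channel weight mass
  survives (otherwise the OLS fit is kept — the bisquare can otherwise
  spiral into rejecting every informative channel of a spectrum that has
  no affine relation to the reference), and an identically-null spectrum
  passes through unchanged, since a null trace has no scatter to correct.
  A non-null spectrum whose fitted |a| < 1e−12 raises a degenerate-sample
  error.
- **Savitzky–Golay** weights are computed from the windowed polynomial
  least-squares design directly (row `d` of the design pseudoinverse
  times d!/Δ^d); defaults are order 2, derivative 1, windows 21/51/31
  points for UV-Vis/NIR/MIR. After masking the axis is a union of uniform
  blocks; the filter runs per block (no leakage across gaps, verified by
  test) and edge points are evaluated from the polynomial fitted to the
  nearest full window — no signal padding, so polynomials of degree ≤
  order are reproduced exactly everywhere, edges included.

### Why calibration runs without RLMSC by default

`PreprocessConfig.default` enables the full four-step chain, which is the
right tool for visualizing difference spectra. `calibration_default`
(used by the runner and the acceptance script) disables RLMSC, for a
structural reason: after baseline subtraction, the between-sample
variation of these spectra is proportional to the analyte concentration
(both the Beer–Lambert term and the linear water displacement scale with
c). Affine normalization of each difference spectrum against the mean
difference spectrum then fits a ≈ c_i/c̄ and maps every sample onto the
reference — it removes exactly the signal the regression needs, and in
the noiseless limit collapses the design matrix entirely. Scatter
correction belongs to settings where the dominant spectral shape is
concentration-independent (e.g. raw solvent-dominated spectra); on
concentration-proportional difference spectra it is self-defeating. The
step remains available for gain diagnostics and high-concentration
visualization.

The chain exposes no automatic outlier-removal step: no defensible
rejection rule is available for it, so outlier handling is left to the
user upstream.

## Calibration

PLS1 by NIPALS on mean-centered X and y (no unit-variance scaling —
channels share units, and variance scaling would amplify empty regions).
Deflation gives mutually orthogonal scores; the regression vector is
collapsed as b = W(PᵀW)⁻¹q and verified in tests against (i) the
score-by-score prediction route, (ii) minimum-norm least squares at full
rank, and (iii) an independent PLS implementation. If the residual
cross-covariance vanishes before the requested component count (relative
floor 1e−12), fitting raises a rank-exhausted error carrying the
achievable count; the cross-validation helpers catch this case and keep
the deepest achievable model, so PRESS curves go flat past the effective
rank instead of failing.

PRESS(k) is the sum of squared leave-one-out errors with k latent
variables, folds enumerated in index order; the chosen k is the smallest
whose PRESS is within 5% of the curve minimum (ties toward fewer LVs).
The 5% one-sided tolerance automates the usual practice of reading the
elbow off a PRESS chart. Search depth defaults to min(15, N − 2). The
final report evaluates the chosen k by LOOCV: R² = 1 − SS_res/SS_tot on
the cross-validated predictions (the "coefficient of determination"
reading, adopted over squared-correlation) and RMSECV = √(SS_res/N).
Preprocessing is applied to the full set before cross-validation, the
standard chemometric workflow for these figures of merit.

## Peak analysis

Peaks are local extrema filtered by topographic prominence; negative
polarity runs detection on the negated trace, so water bands inverted by
baseline subtraction are found symmetrically. The default prominence
threshold is 3× the MAD of the first-differenced signal — a robust noise
floor that adapts to each spectrum. Assignment maps each call to the
nearest band table entry within 10 axis units (narrower than any
inter-band gap in the tables); bands matched by several calls are flagged
ambiguous rather than arbitrated, because overlapping fingerprint bands
cannot be attributed reliably without deconvolution (out of scope).
Linearity checks regress the windowed maximum absorbance on concentration
by OLS; at water bands the slope is negative (displacement), at lactate
bands positive.

## Problem sizes and determinism

The synthetic studies used throughout tests and the acceptance script are
the full-size design: 37 samples × 501/1801/3501 channels, LOOCV over all
samples with up to 15 latent variables — small enough to run in seconds
while exercising every code path at the study's real dimensions. All
stochastic draws flow from single integer seeds; reports are
byte-identical across reruns of the same configuration.

## Known limitations

- Figures of merit from synthetic spectra characterize the pipeline, not
  any physical instrument; the generator's clean-limit exactness is
  idealized.
- RLMSC's IRLS is per-spectrum and assumes outliers are a minority of
  channels; contamination above ~50% defeats the majority safeguard.
- PRESS-based selection with LOOCV is optimistic for small N; no outer
  validation loop is provided.
- PLS1 only (single analyte); no variable selection; no prediction
  intervals.
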