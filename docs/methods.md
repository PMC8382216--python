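# Methods

This note documents the models implemented in `oxiraman`, the assumptions of
the synthetic-data generator that drives all tests, and the numerical and
design choices made where the problem left them open.

## Spectra and file format

A `Spectrum` is a strictly increasing wavenumber axis (cm⁻¹) with intensities
(arbitrary units) and provenance metadata (species, nominal oxidized fraction,
replicate, processing flags).  Files are plain two-column text with
`# key: value` header lines; CSV separators are accepted on read, rows are
sorted, and duplicate wavenumbers are an error rather than being averaged —
coincident points usually indicate an export fault, and silent averaging would
hide it.  A region tag (`fingerprint`, `thz`, `sers`) asserts axis coverage
(900–1700, below 100, and 400–1800 cm⁻¹ respectively) and a minimum of 8
points; untagged spectra only need two points, so that trivial fragments can
still be read and inspected.  No vendor binary formats and no nm↔cm⁻¹
conversion: everything is cm⁻¹ end to end.

## Synthetic-data generator

The generator encodes exactly the statistical structure the analysis assumes,
which is what makes recovery tests meaningful:

- **Bands.** Each species is a sum of Gaussians (center, σ, integrated area).
  Fingerprint σ defaults to 8 cm⁻¹ and THz σ to 25 cm⁻¹; widths and absolute
  intensities of these compounds are not available at this resolution, so
  both are free, documented parameters rather than measured constants.
- **Reference-band calibration (a construction, not a measurement).**  The
  1123 cm⁻¹ phosphate band's total area is set to 1/erf(15/(σ√2)) so that its
  integrated area inside the default ±15 cm⁻¹ normalization window is exactly
  1.  With marker areas 0.8 (1535 cm⁻¹) and 0.9 (1607 cm⁻¹) for the pure
  oxidized species, linear mixing then yields normalized calibration slopes
  of exactly 0.008 and 0.009 per % — the values the recovery tests check.
- **Mixing.** A mixture at nominal fraction *C* is
  (1−f/100)·A + (f/100)·B with f = *C* + (100−*C*)/100·c₀, where the optional
  `c0_pct` models accidental oxidized contamination of the "pure" stock; any
  fixed-window band integral is exactly affine in *C* before noise.
- **Baseline and noise.** Cubic polynomial on the [0,1]-scaled axis with
  small coefficients (default ≈5–10 % of the strongest band); additive
  homoscedastic Gaussian noise with SD expressed as a fraction of the maximum
  pure-component intensity (default 0.01), with an optional Poisson-like
  heteroscedastic mode.  Defaults follow the study design: fractions
  0–16 %, three replicates.
- **THz series.** One dominant broad Gaussian whose center follows the
  exponential shift model below; the band must satisfy center − σ ≥ 0.  The
  8-oxo band is necessarily truncated at the 10 cm⁻¹ axis edge, as at the
  instrumental low-frequency cutoff; fitting the same Gaussian family is
  unaffected by the truncation.
- **SERS.** Each spectrum is g·[(1−C/100)·dG + (C/100)·8-oxo-dG] + colloid
  band (240 cm⁻¹) + fixed background + noise, with gain
  g ~ lognormal(0, 0.05).  The 5 % gain RSD is the droplet-averaged colloid
  reproducibility scale — each acquisition averages over many aggregated
  nanoparticles, not a single hot spot — and the non-enhanced background
  (≈10 % of the strongest analyte band) models the optical-path
  contribution, which does not share the plasmonic gain.  Three acquisitions
  per mixture at C = 0, 10, …, 100 % is the default design.

What the generator deliberately does **not** emulate: Raman cross-sections
and instrument response, cosmic-ray spikes, wavenumber miscalibration, band
asymmetry (Voigt/Fano shapes), and analyte–colloid chemistry.  Passing
recovery tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to every artifact of real spectra.

## Preprocessing

Baseline subtraction fits a polynomial (default degree 3; `linear` mode for
the low-frequency range) to anchor points by least squares and subtracts it
over the full axis.  Anchors are either explicit signal-free windows or
auto-selected as the lowest-decile intensity points within each of 16 equal
axis segments (outside declared band windows); the per-segment rule spreads
anchors across the axis instead of clustering them at the global baseline
minimum.  Reference normalization divides by the trapezoidal integrated area
(±15 cm⁻¹ by default) of the 1123 cm⁻¹ band — area rather than peak height,
because area is robust to width changes; height is available via a flag.
SERS spectra are cropped to 400–1800 cm⁻¹ (closed interval on the grid) and
divided by their Euclidean norm.  Both normalizations are scale-invariant and
idempotent, which the property tests assert directly.

## Multi-Gaussian deconvolution

Bands are parameterized by (center, σ, area) — the calibration consumes
integrated intensities, so area is a parameter, not a derived quantity.  The
fit is trust-region bounded least squares (`scipy.optimize.least_squares`,
tolerances 1e-10, max 2000 evaluations, no random restarts): centers bounded
to ±20 cm⁻¹ of initialization intersected with the window, σ ∈ [1, 60] cm⁻¹,
areas ≥ 0.  Standard errors come from the local covariance
(JᵀJ)⁻¹·SSR/(n−p) via pseudo-inverse (zero-area components make JᵀJ
singular).  Hitting the evaluation limit sets `converged=False` instead of
raising.

The guanine protocol fits exactly six components in 1400–1650 cm⁻¹: the five
assigned centers (1445, 1485, 1535, 1575, 1607 cm⁻¹) plus one free
"background remnant" component initialized at 1500 cm⁻¹ — mid-window but
deliberately more than 10 cm⁻¹ from every assigned center so it cannot
collide with a marker during matching.  Band identity is resolved two ways:
the public `band_area` operation matches the unique fitted band within
10 cm⁻¹ of a target center and raises an ambiguity error on zero or multiple
matches (no silent choice); the fixed-identity pipeline instead selects each
marker by its initialization center, which stays well-defined when a
near-zero-area component's fitted center drifts under noise.  In the
noiseless degenerate case the free component may park on top of an assigned
band and share its area — a genuine likelihood degeneracy; the identity
lookup keeps the assigned component's center meaningful there.

`thz_main_band` fits one Gaussian over 10–200 cm⁻¹ (center bound ±40 cm⁻¹
around the intensity maximum, σ ∈ [3, 80]); a second component is attempted
only when the single-band residual is non-negligible and kept only if it
reduces the residual RMS by more than 20 %.  The center of the largest-area
component is reported.

## Calibration (Eq.-style linear model)

Ordinary least squares of normalized marker area on fraction, weighted by
1/err² when per-point area errors are supplied.  The contamination
correction subtracts the fitted intercept *I*⁰ from every point and reports
the line through the origin.  Algebraically the corrected slope equals the
two-parameter slope (the weighted residuals are orthogonal to *C*), so the
slope standard error is that of the full fit — the through-origin formula
would understate it by ignoring the intercept's uncertainty, which the
Monte-Carlo calibration test caught during development.  σ_res uses n−2
degrees of freedom.  Inverse prediction is C = (I − I⁰)/m with first-order
propagation of the area error, σ_res, the intercept error and the slope
error; out-of-range estimates are flagged, never clipped, because truncation
would bias validation statistics.  Dual-band averaging is
inverse-variance weighting of the two slopes with pooled σ_res, and requires
identical designs and corrected intercepts.

The detection limit is LOD = k·σ_res/m with k = 3.3 (ICH-style 3.3σ rule).
The criterion behind reported 1 % / 5 % limits is not derivable from first
principles, so k is configurable; at the illustrative scatter
σ_res = 0.0024 with m = 0.008 the rule gives 0.99 %.

## Exponential THz shift model

ν(C) = ν_oxo + (ν₀ − ν_oxo)·e^(−C/R).  This saturating-exponential form is
the package's adopted model: it matches the asymptote semantics (ν₀ at C = 0,
ν_oxo at full oxidation) and a single decay constant R (%) that differs
between deoxy- and ribonucleotides.  Defaults ν₀ = 95, ν_oxo = 60 cm⁻¹,
R = 6 % (deoxy) and 90/62 cm⁻¹, R = 12 % (ribo) are generator placeholders
consistent with the >30 cm⁻¹ pure-species contrast; they are not measured
constants.  Fitting uses `scipy.optimize.curve_fit` on band centers extracted
by `thz_main_band` (not raw argmax), initialized from the lowest- and
highest-C points with R from a log-linearized mid-point estimate; at least 4
distinct concentrations are required and an all-equal frequency input is
rejected as degenerate (R unbounded).  Inversion
C = −R·ln((ν − ν_oxo)/(ν₀ − ν_oxo)) propagates the measurement error and the
full parameter covariance; frequencies outside the asymptote interval are
rejected.  Because |dν/dC| = (ν₀ − ν_oxo)/R at C = 0 (≈5.8 cm⁻¹ per % at the
deoxy defaults), sub-percent fractions move the band by several cm⁻¹ — the
mechanism by which this observable beats the fingerprint detection limit.

## PLS1 (NIPALS)

Classical NIPALS with deflation for a single response: w = Xᵀy/‖Xᵀy‖,
t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflate and repeat; coefficients
B = W(PᵀW)⁻¹q.  Inputs are unit-vector normalized then mean-centered; no
variance scaling (all channels share units).  The algorithm is deterministic
and its coefficients agree with scikit-learn's `PLSRegression(scale=False)`
to machine precision, which the oracle test asserts at 6 significant digits;
scikit-learn is used only as that cross-check, never as the implementation.
Requesting more components than the informative rank raises (the noiseless
gain-free dataset spans exactly two components — two pure spectra — so a
third collapses).  Grid mismatches raise unless regridding is requested
explicitly (linear interpolation followed by renormalization).  Validation
is leave-one-out, reporting per-sample predictions, residuals, RMSECV and
the predicted-vs-actual slope; with the default synthetic design (33
spectra) the three-component model reaches RMSECV below 2 % with slope ≈1.

## Problem sizes and determinism

All analyses run on synthetic data generated at the defaults above: 21
spectra (7 fractions × 3 replicates) for slope recovery, single spectra for
band-location checks, 6-point series for the THz round trip, 200-draw
Monte-Carlo for trace-level inversion, and 33 spectra for PLS
cross-validation — sizes at which every estimator's sampling behavior is
visible while the whole suite completes in minutes.  Every stochastic step
takes an explicit integer seed (NumPy `default_rng`); noiseless fits are
bit-reproducible by construction.

## Known limitations

- Gaussian profiles only; real bands with Lorentzian character will bias
  fitted areas slightly.
- The six-component count is fixed, not selected; strongly non-polynomial
  baselines inside the fit window are absorbed by the free component only
  approximately.
- First-order uncertainty propagation; no bootstrap.  Coverage of the
  ±1.96u inverse-prediction interval is slightly below nominal for very
  small calibration designs (it is checked at a triplicate 18-point design).
- The THz functional form and its parameter values are a modeling choice;
  only the pure-species contrast and the existence of distinct decay rates
  are externally anchored.
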