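"""Synthetic spectrum generation with the statistical structure the analysis assumes.

Every downstream stage is exercised on data from this module, so the generator
encodes exactly the assumptions the analysis relies on: spectra are sums of
Gaussian bands at the assigned centers, mixtures mix the two pure-component
signals linearly in the oxidized fraction, baselines are smooth low-order
polynomials, noise is additive and homoscedastic (optionally Poisson-like),
THz mixtures have a single dominant broad band whose center follows the
exponential tetrad-shift model, and SERS spectra carry a per-spectrum
multiplicative enhancement gain plus the silver-colloid band near 240 cm-1.

Default conditions mirror the study design: mixture grids run from 0 to 16 %
oxidized fraction with 3 replicates, noise SD is 1 % of the maximum pure
signal, and the fingerprint axis is sampled at 0.5 cm-1 (finer than the
3 cm-1 instrumental resolution so fitting error is grid-independent).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .bands import (
    BandLibrary,
    GaussianBand,
    THZ_BAND_CENTERS,
    THZ_SIGMA,
    default_band_library,
)
from .exceptions import CoverageError, SpectrumValidationError
from .spectra import DatasetManifest, ManifestEntry, Spectrum, save_manifest, write_spectrum
from .thz import DEOXY_TETRAD_SHIFT, TetradShift

__all__ = [
    "SyntheticDatasetSpec",
    "wavenumber_axis",
    "polynomial_baseline",
    "generate_pure_spectrum",
    "generate_mixture_series",
    "generate_thz_spectrum",
    "generate_thz_series",
    "generate_sers_dataset",
    "FINGERPRINT_AXIS",
    "THZ_AXIS",
    "SERS_AXIS",
    "DEFAULT_BASELINE",
]

FINGERPRINT_AXIS = (300.0, 1800.0, 0.5)
THZ_AXIS = (10.0, 200.0, 0.25)
SERS_AXIS = (115.0, 3200.0, 1.0)
#: cubic baseline coefficients on the [0, 1]-scaled axis, small vs unit signal
DEFAULT_BASELINE = (0.05, 0.03, -0.02, 0.01)


def wavenumber_axis(start: float, stop: float, step: float) -> np.ndarray:
    """Inclusive regular grid from ``start`` to ``stop`` with ``step`` cm-1."""
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def _as_axis(axis) -> np.ndarray:
    if isinstance(axis, tuple):
        return wavenumber_axis(*axis)
    return np.asarray(axis, dtype=float)


def polynomial_baseline(axis: np.ndarray, coefficients: Sequence[float]) -> np.ndarray:
    """Polynomial in the axis scaled to [0, 1]; zero if no coefficients."""
    if coefficients is None or len(coefficients) == 0:
        return np.zeros_like(axis)
    x = (axis - axis[0]) / (axis[-1] - axis[0])
    return np.polynomial.polynomial.polyval(x, np.asarray(coefficients, dtype=float))


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Conditions for a synthetic mixture series.

    Defaults are the study conditions: fractions 0-16 %, three replicates per
    fraction, additive noise with SD equal to 1 % of the maximum pure-spectrum
    intensity, a small cubic baseline, and the standard fingerprint axis.
    ``c0_pct`` adds an accidental oxidized contamination to the nominally pure
    non-oxidized component (the C0 effect removed by the calibration).
    """

    concentrations: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0)
    replicates: int = 3
    noise_sd: float = 0.01
    baseline: tuple[float, ...] = DEFAULT_BASELINE
    axis: tuple[float, float, float] = FINGERPRINT_AXIS
    seed: int = 0
    c0_pct: float = 0.0

    def __post_init__(self) -> None:
        if len(self.concentrations) == 0:
            raise SpectrumValidationError("empty concentration list")
        for c in self.concentrations:
            if not (0.0 <= c <= 100.0):
                raise SpectrumValidationError(f"concentration {c} outside [0, 100]")
        if self.noise_sd < 0:
            raise SpectrumValidationError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise SpectrumValidationError("replicates must be >= 1")
        if not (0.0 <= self.c0_pct <= 100.0):
            raise SpectrumValidationError("c0_pct must lie in [0, 100]")


def _species_signal(
    species: str,
    library: BandLibrary,
    axis: np.ndarray,
    require_full_coverage: bool = True,
) -> np.ndarray:
    if species not in library:
        raise KeyError(f"species {species!r} not in band library")
    signal = np.zeros_like(axis)
    for band in library[species]:
        if require_full_coverage:
            if band.center - 3 * band.width < axis[0] or band.center + 3 * band.width > axis[-1]:
                raise CoverageError(
                    f"axis [{axis[0]}, {axis[-1]}] does not cover band at "
                    f"{band.center} +/- 3*{band.width} cm-1 of {species!r}"
                )
        elif not (axis[0] <= band.center <= axis[-1]):
            raise CoverageError(
                f"band center {band.center} outside axis [{axis[0]}, {axis[-1]}]"
            )
        signal += band.profile(axis)
    return signal


def _add_noise(
    signal: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    scale: float,
    heteroscedastic: bool = False,
) -> np.ndarray:
    if noise_sd == 0:
        return signal
    sd = noise_sd * scale
    if heteroscedastic:
        # Poisson-like: SD proportional to sqrt(intensity), matched at the peak
        local = sd * np.sqrt(np.clip(signal, 0.0, None) / max(scale, 1e-300))
        return signal + rng.normal(0.0, 1.0, signal.size) * local
    return signal + rng.normal(0.0, sd, signal.size)


def generate_pure_spectrum(
    species: str,
    library: BandLibrary | None = None,
    axis=FINGERPRINT_AXIS,
    baseline: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    region: str | None = "fingerprint",
    heteroscedastic: bool = False,
) -> Spectrum:
    """One pure-species spectrum: sum of library bands + baseline + noise.

    The axis must cover every band center +/- 3 sigma (for the THz region only
    the centers, since the broad band is physically truncated at the
    low-frequency cutoff).  Deterministic for a fixed ``seed``.
    """
    library = default_band_library() if library is None else library
    grid = _as_axis(axis)
    signal = _species_signal(
        species, library, grid, require_full_coverage=(region != "thz")
    )
    rng = np.random.default_rng(seed)
    scale = float(signal.max()) if signal.max() > 0 else 1.0
    inten = _add_noise(
        signal + polynomial_baseline(grid, baseline), noise_sd, rng, scale, heteroscedastic
    )
    return Spectrum(
        wavenumbers=grid, intensities=inten, species=species, fraction_pct=None,
        region=region,
    )


def generate_mixture_series(
    spec: SyntheticDatasetSpec,
    species_a: str = "dGTP",
    species_b: str = "8-oxo-dGTP",
    library: BandLibrary | None = None,
    out_dir: str | Path | None = None,
) -> tuple[DatasetManifest, list[Spectrum]]:
    """Linear-mixing series: (1 - f/100)*A + (f/100)*B + baseline + noise.

    The effective oxidized fraction f includes the accidental contamination of
    the nominally pure A component: f = C + (100 - C)/100 * c0_pct.  Marker
    band areas are therefore exactly affine in the nominal fraction C before
    noise.  When ``out_dir`` is given, spectra and a ``manifest.csv`` are
    written there.
    """
    library = default_band_library() if library is None else library
    grid = _as_axis(spec.axis)
    sig_a = _species_signal(species_a, library, grid)
    sig_b = _species_signal(species_b, library, grid)
    base = polynomial_baseline(grid, spec.baseline)
    scale = float(max(sig_a.max(), sig_b.max()))
    rng = np.random.default_rng(spec.seed)

    out = None if out_dir is None else Path(out_dir)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    spectra: list[Spectrum] = []
    entries: list[ManifestEntry] = []
    for c in spec.concentrations:
        f_eff = c + (100.0 - c) / 100.0 * spec.c0_pct
        signal = (1.0 - f_eff / 100.0) * sig_a + (f_eff / 100.0) * sig_b + base
        for rep in range(1, spec.replicates + 1):
            inten = _add_noise(signal, spec.noise_sd, rng, scale)
            s = Spectrum(
                wavenumbers=grid,
                intensities=inten,
                species="mixture",
                fraction_pct=float(c),
                region="fingerprint" if spec.axis == FINGERPRINT_AXIS else None,
                replicate=rep,
            )
            spectra.append(s)
            name = f"mix_{species_b.replace('/', '-')}_{c:06.2f}pct_r{rep}.txt"
            path = (out / name) if out is not None else Path(name)
            if out is not None:
                write_spectrum(s, path)
            entries.append(
                ManifestEntry(path=path, species="mixture", fraction_pct=float(c), replicate=rep)
            )
    manifest = DatasetManifest(entries=tuple(entries))
    if out is not None:
        save_manifest(manifest, out / "manifest.csv")
    return manifest, spectra


def generate_thz_spectrum(
    species: str | None = None,
    center: float | None = None,
    band_width: float = THZ_SIGMA,
    area: float = 1.0,
    baseline: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    axis=THZ_AXIS,
) -> Spectrum:
    """A THz spectrum with one dominant broad Gaussian.

    Give either a ``species`` (center looked up in the THz band table) or an
    explicit ``center``.  The band must not extend below 0 cm-1
    (center - sigma >= 0).
    """
    if center is None:
        if species is None or species not in THZ_BAND_CENTERS:
            raise KeyError(f"unknown THz species {species!r}; give center explicitly")
        center = THZ_BAND_CENTERS[species]
    if center - band_width < 0:
        raise CoverageError(
            f"THz band at {center} with sigma {band_width} extends below 0 cm-1"
        )
    grid = _as_axis(axis)
    band = GaussianBand(center, band_width, area, "main low-frequency band")
    signal = band.profile(grid) + polynomial_baseline(grid, baseline)
    rng = np.random.default_rng(seed)
    inten = _add_noise(signal, noise_sd, rng, float(band.amplitude))
    return Spectrum(
        wavenumbers=grid, intensities=inten, species=species, region="thz"
    )


def generate_thz_series(
    concentrations: Sequence[float],
    model: TetradShift | None = None,
    band_width: float = THZ_SIGMA,
    noise_sd: float = 0.0,
    seed: int | None = None,
    axis=THZ_AXIS,
    out_dir: str | Path | None = None,
) -> tuple[DatasetManifest, list[Spectrum]]:
    """THz mixture series whose main-band center follows the shift model."""
    if len(concentrations) == 0:
        raise SpectrumValidationError("empty concentration list")
    model = DEOXY_TETRAD_SHIFT if model is None else model
    rng = np.random.default_rng(seed)
    out = None if out_dir is None else Path(out_dir)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    spectra, entries = [], []
    for i, c in enumerate(concentrations):
        sub = int(rng.integers(0, 2**31 - 1)) if noise_sd > 0 else None
        s = generate_thz_spectrum(
            center=model.frequency(c),
            band_width=band_width,
            noise_sd=noise_sd,
            seed=sub,
            axis=axis,
        ).replace(species="mixture", fraction_pct=float(c))
        spectra.append(s)
        name = f"thz_{c:06.2f}pct.txt"
        path = (out / name) if out is not None else Path(name)
        if out is not None:
            write_spectrum(s, path)
        entries.append(
            ManifestEntry(path=path, species="mixture", fraction_pct=float(c), replicate=1)
        )
    manifest = DatasetManifest(entries=tuple(entries))
    if out is not None:
        save_manifest(manifest, out / "manifest.csv")
    return manifest, spectra


#: Three acquisitions per mixture, the usual droplet-SERS practice.
SERS_CONCENTRATIONS = tuple(c for c in range(0, 101, 10) for _ in range(3))


def generate_sers_dataset(
    concentrations: Sequence[float] = SERS_CONCENTRATIONS,
    library: BandLibrary | None = None,
    enhancement_cv: float = 0.05,
    noise_sd: float = 0.01,
    seed: int | None = None,
    axis=SERS_AXIS,
    baseline: Sequence[float] = (0.005, 0.003, -0.003),
    species_a: str = "dG",
    species_b: str = "8-oxo-dG",
) -> tuple[list[Spectrum], np.ndarray]:
    """SERS nucleoside mixtures with colloid band and enhancement variability.

    Each spectrum is g * [(1 - C/100)*dG + (C/100)*8-oxo-dG] + colloid +
    baseline + noise with a per-spectrum gain g ~ lognormal(0, enhancement_cv)
    modeling the acquisition-to-acquisition SERS enhancement scatter that
    unit-vector normalization removes downstream.  The default gain RSD of
    5 % is the droplet-averaged colloid reproducibility scale (each spectrum
    averages over many aggregated nanoparticles, not a single hot spot); the
    fixed cubic background models the small non-enhanced optical-path
    contribution, about a tenth of the strongest analyte band.
    """
    if enhancement_cv < 0:
        raise SpectrumValidationError("enhancement_cv must be >= 0")
    library = default_band_library() if library is None else library
    grid = _as_axis(axis)
    sig_a = _species_signal(species_a, library, grid)
    sig_b = _species_signal(species_b, library, grid)
    colloid = _species_signal("colloid", library, grid)
    base = polynomial_baseline(grid, baseline)
    scale = float(max(sig_a.max(), sig_b.max()))
    rng = np.random.default_rng(seed)

    spectra = []
    for c in concentrations:
        if not (0.0 <= c <= 100.0):
            raise SpectrumValidationError(f"concentration {c} outside [0, 100]")
        gain = float(rng.lognormal(0.0, enhancement_cv)) if enhancement_cv > 0 else 1.0
        mix = (1.0 - c / 100.0) * sig_a + (c / 100.0) * sig_b
        inten = _add_noise(gain * mix + colloid + base, noise_sd, rng, scale)
        spectra.append(
            Spectrum(
                wavenumbers=grid,
                intensities=inten,
                species="mixture",
                fraction_pct=float(c),
                region="sers",
            )
        )
    return spectra, np.asarray(concentrations, dtype=float)
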