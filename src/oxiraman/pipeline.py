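"""End-to-end fingerprint quantification: preprocess -> deconvolve -> calibrate.

This module wires the stages together for the standard guanine workflow:
baseline subtraction (cubic, anchored in signal-free gaps between the known
bands), normalization to the 1123 cm-1 phosphate reference, six-Gaussian
deconvolution of the 1400-1650 cm-1 window, marker-area extraction at 1535
and 1607 cm-1, and the contamination-corrected calibration with dual-band
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bands import (
    BandLibrary,
    GaussianBand,
    FINGERPRINT_SIGMA,
    MARKER_A_CENTER,
    MARKER_B_CENTER,
    PO4_CENTER,
    REF_HALF_WINDOW,
    bands_in_window,
    default_band_library,
)
from .calibration import CalibrationCurve, LinearCalibration, average_calibration
from .deconvolution import GDTP_FIT_WINDOW, MultiGaussianModel
from .preprocess import normalize_to_reference, subtract_baseline
from .spectra import Spectrum

__all__ = [
    "DEFAULT_ANCHOR_WINDOWS",
    "six_band_init",
    "preprocess_fingerprint",
    "marker_areas",
    "CalibrationSet",
    "calibrate_mixture_series",
]

#: Signal-free gaps between the default library's guanine bands.
DEFAULT_ANCHOR_WINDOWS = ((760.0, 1040.0), (1190.0, 1320.0), (1660.0, 1780.0))

#: Initialization center for the free "background remnant" component of the
#: six-Gaussian protocol; kept >10 cm-1 away from every assigned center so it
#: can never collide with a marker during band matching.
FREE_BAND_CENTER = 1500.0


def six_band_init(
    library: BandLibrary | None = None,
    species_a: str = "dGTP",
    species_b: str = "8-oxo-dGTP",
    window: tuple[float, float] = GDTP_FIT_WINDOW,
) -> tuple[GaussianBand, ...]:
    """Six-component initialization: both species' in-window bands + one free band."""
    library = default_band_library() if library is None else library
    seen: dict[float, GaussianBand] = {}
    for species in (species_a, species_b):
        for band in bands_in_window(library[species], window):
            seen.setdefault(band.center, GaussianBand(band.center, band.width, 0.2, band.assignment))
    init = [seen[c] for c in sorted(seen)]
    init.append(GaussianBand(FREE_BAND_CENTER, FINGERPRINT_SIGMA, 0.05, "background remnant"))
    return tuple(init)


def preprocess_fingerprint(
    spectrum: Spectrum,
    degree: int = 3,
    anchor_windows: Sequence[tuple[float, float]] | None = DEFAULT_ANCHOR_WINDOWS,
    ref_center: float = PO4_CENTER,
    ref_half_window: float = REF_HALF_WINDOW,
) -> Spectrum:
    """Baseline-correct and reference-normalize one fingerprint spectrum."""
    corrected = subtract_baseline(
        spectrum, mode="polynomial", degree=degree, anchor_windows=anchor_windows
    )
    normalized, _ = normalize_to_reference(corrected, ref_center, ref_half_window)
    return normalized


def marker_areas(
    spectrum: Spectrum,
    markers: Sequence[float] = (MARKER_A_CENTER, MARKER_B_CENTER),
    library: BandLibrary | None = None,
    species_a: str = "dGTP",
    species_b: str = "8-oxo-dGTP",
    window: tuple[float, float] = GDTP_FIT_WINDOW,
    tol: float = 10.0,
) -> Mapping[float, tuple[float, float]]:
    """Six-Gaussian fit of a preprocessed spectrum -> {marker: (area, se)}."""
    init = six_band_init(library, species_a, species_b, window)
    result = MultiGaussianModel(spectrum, init, window).fit()
    # fixed-identity protocol: each marker is the component initialized at
    # its assigned center, which stays well-defined even when a vanishing
    # band's fitted center drifts under noise
    out = {}
    for m in markers:
        band = result.band_for_init(m)
        out[m] = (band.area, band.area_se)
    return out


@dataclass(frozen=True)
class CalibrationSet:
    """Per-marker calibration curves plus their dual-band average."""

    curves: Mapping[float, CalibrationCurve]
    averaged: CalibrationCurve | None

    def summary(self) -> str:
        parts = [c.summary() for c in self.curves.values()]
        if self.averaged is not None:
            parts.append(self.averaged.summary())
        return "\n\n".join(parts)


def calibrate_mixture_series(
    spectra: Sequence[Spectrum],
    fractions: Sequence[float],
    markers: Sequence[float] = (MARKER_A_CENTER, MARKER_B_CENTER),
    library: BandLibrary | None = None,
    species_a: str = "dGTP",
    species_b: str = "8-oxo-dGTP",
    window: tuple[float, float] = GDTP_FIT_WINDOW,
    correct_c0: bool = True,
    anchor_windows: Sequence[tuple[float, float]] | None = DEFAULT_ANCHOR_WINDOWS,
) -> CalibrationSet:
    """Run the full fingerprint pipeline on a mixture series.

    Each spectrum is preprocessed, deconvolved and reduced to marker-band
    areas; one calibration line per marker is fitted (weighted by the fitted
    area errors, contamination-corrected by default) and the two marker curves
    are inverse-variance averaged when exactly two markers are requested.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(spectra) != fractions.size:
        raise ValueError("spectra and fractions must have equal length")

    per_marker: dict[float, list[tuple[float, float]]] = {m: [] for m in markers}
    for s in spectra:
        prepped = preprocess_fingerprint(s, anchor_windows=anchor_windows)
        areas = marker_areas(
            prepped, markers, library, species_a, species_b, window
        )
        for m in markers:
            per_marker[m].append(areas[m])

    curves: dict[float, CalibrationCurve] = {}
    for m in markers:
        vals = np.array([a for a, _ in per_marker[m]])
        errs = np.array([e for _, e in per_marker[m]])
        curves[m] = LinearCalibration(
            fractions,
            vals,
            area_errors=errs if np.all(errs > 0) else None,
            correct_c0=correct_c0,
            label=f"{m:g} cm-1",
        ).fit()

    averaged = None
    if len(markers) == 2 and correct_c0:
        a, b = (curves[m] for m in markers)
        averaged = average_calibration(a, b)
    return CalibrationSet(curves=curves, averaged=averaged)
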