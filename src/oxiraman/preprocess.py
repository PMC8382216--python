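"""Baseline subtraction and the three normalization conventions.

Fingerprint spectra are baseline-corrected with a low-order polynomial
(linear in the low-frequency range) fitted to signal-free anchor points,
then put on a common intensity scale by dividing by the integrated area of
the phosphate-backbone reference band at 1123 cm-1.  SERS spectra are
cropped to 400-1800 cm-1 and unit-vector normalized, which removes the
multiplicative enhancement gain.  Both normalizations are scale-invariant
and idempotent.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .bands import PO4_CENTER, REF_HALF_WINDOW
from .exceptions import BaselineError, CoverageError, NormalizationError
from .spectra import Spectrum

__all__ = [
    "subtract_baseline",
    "normalize_to_reference",
    "unit_vector_normalize",
]

Interval = tuple[float, float]
_AUTO_SEGMENTS = 16
_AUTO_QUANTILE = 0.10


def _window_mask(wn: np.ndarray, windows: Sequence[Interval]) -> np.ndarray:
    mask = np.zeros(wn.size, dtype=bool)
    for lo, hi in windows:
        mask |= (wn >= lo) & (wn <= hi)
    return mask


def _auto_anchor_mask(
    wn: np.ndarray, inten: np.ndarray, exclude_windows: Sequence[Interval] | None
) -> np.ndarray:
    """Lowest-decile intensity points per axis segment, outside band windows."""
    allowed = np.ones(wn.size, dtype=bool)
    if exclude_windows:
        allowed &= ~_window_mask(wn, exclude_windows)
    mask = np.zeros(wn.size, dtype=bool)
    edges = np.linspace(wn[0], wn[-1], _AUTO_SEGMENTS + 1)
    for lo, hi in zip(edges[:-1], edges[1:]):
        seg = allowed & (wn >= lo) & (wn <= hi)
        if not np.any(seg):
            continue
        cutoff = np.quantile(inten[seg], _AUTO_QUANTILE)
        mask |= seg & (inten <= cutoff)
    return mask


def subtract_baseline(
    spectrum: Spectrum,
    mode: str = "polynomial",
    degree: int = 3,
    anchor_windows: Sequence[Interval] | None = None,
    exclude_windows: Sequence[Interval] | None = None,
) -> Spectrum:
    """Fit a baseline to anchor points by least squares and subtract it.

    Parameters
    ----------
    mode : {"polynomial", "linear"}
        ``"linear"`` forces degree 1 (the low-frequency convention).
    degree : int
        Polynomial degree for ``mode="polynomial"`` (default 3).
    anchor_windows : list of (lo, hi), optional
        Wavenumber intervals assumed signal-free.  When omitted, anchors are
        auto-selected as the lowest-decile intensity points per axis segment,
        outside ``exclude_windows``.
    """
    if mode == "linear":
        degree = 1
    elif mode != "polynomial":
        raise ValueError(f"unknown baseline mode {mode!r}")
    if degree < 0:
        raise ValueError(f"degree must be >= 0, got {degree}")

    wn, inten = spectrum.wavenumbers, spectrum.intensities
    if anchor_windows is not None:
        mask = _window_mask(wn, anchor_windows)
    else:
        mask = _auto_anchor_mask(wn, inten, exclude_windows)
    if int(mask.sum()) < degree + 1:
        raise BaselineError(
            f"only {int(mask.sum())} anchor points for a degree-{degree} baseline "
            f"(need >= {degree + 1})"
        )
    poly = np.polynomial.Polynomial.fit(wn[mask], inten[mask], deg=degree)
    return spectrum.replace(
        intensities=inten - poly(wn), baseline_corrected=True
    )


def normalize_to_reference(
    spectrum: Spectrum,
    ref_center: float = PO4_CENTER,
    half_window: float = REF_HALF_WINDOW,
    use: str = "area",
) -> tuple[Spectrum, float]:
    """Divide by the reference-band intensity around ``ref_center``.

    ``use="area"`` (default) integrates the band over
    [ref_center - half_window, ref_center + half_window] by the trapezoidal
    rule; ``use="height"`` divides by the maximum in the window instead.
    Returns the normalized spectrum and the divisor.
    """
    lo, hi = ref_center - half_window, ref_center + half_window
    if not spectrum.covers(lo, hi):
        raise CoverageError(
            f"reference window [{lo}, {hi}] not covered by spectrum axis"
        )
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if use == "area":
        factor = float(
            np.trapezoid(spectrum.intensities[mask], spectrum.wavenumbers[mask])
        )
    elif use == "height":
        factor = float(spectrum.intensities[mask].max())
    else:
        raise ValueError(f"use must be 'area' or 'height', got {use!r}")
    if factor <= 0:
        raise NormalizationError(
            f"reference band {use} is {factor}; cannot normalize"
        )
    return (
        spectrum.replace(
            intensities=spectrum.intensities / factor, normalized="reference"
        ),
        factor,
    )


def unit_vector_normalize(
    spectrum: Spectrum, window: Interval = (400.0, 1800.0)
) -> Spectrum:
    """Crop to ``window`` and scale the intensity vector to Euclidean norm 1."""
    cropped = spectrum.crop(*window)
    norm = float(np.linalg.norm(cropped.intensities))
    if norm == 0:
        raise NormalizationError("all-zero window; cannot unit-normalize")
    return cropped.replace(
        intensities=cropped.intensities / norm, normalized="unit"
    )
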