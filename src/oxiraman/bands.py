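"""Vibrational band parameterization and the default band library.

A band is a Gaussian in wavenumber, parameterized by (center, sigma, integrated
area); the amplitude is derived.  The default library encodes the assigned
marker bands of the guanine/adenine (deoxy)nucleotides and nucleosides:

* 1123 cm-1 — PO4(3-) phosphate-backbone stretch, common to all triphosphates,
  used as the intensity-normalization reference;
* dGTP/GTP: 1485 (7N-8C stretch), 1575 (3N-4C stretch);
* 8-oxo-(d)GTP: 1445 (7N-H bend), 1535 (7N-8C stretch, marker "A"),
  1607 (5C-7N stretch, marker "B");
* 8-oxo-dATP: 620 (C5-N7-C8 squeeze), the adenine oxidation marker;
* dG / 8-oxo-dG nucleosides (SERS analytes, no phosphate band);
* colloid: the silver-colloid band near 240 cm-1.

Band widths and absolute intensities are not published for these compounds at
this resolution; the sigma = 8 cm-1 fingerprint default and the area table
below are free generator parameters, documented in the methods note.  The one
deliberate calibration: the reference band's total area is chosen so that its
integrated area inside the default +/-15 cm-1 normalization window equals 1,
which makes the normalized marker areas of the pure oxidized species equal to
the tabulated values (0.8 for marker A, 0.9 for marker B) exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GaussianBand",
    "BandLibrary",
    "default_band_library",
    "bands_in_window",
    "PO4_CENTER",
    "MARKER_A_CENTER",
    "MARKER_B_CENTER",
    "ADENINE_MARKER_CENTER",
    "COLLOID_CENTER",
    "FINGERPRINT_SIGMA",
    "REF_HALF_WINDOW",
    "THZ_SIGMA",
    "THZ_BAND_CENTERS",
]

PO4_CENTER = 1123.0
MARKER_A_CENTER = 1535.0
MARKER_B_CENTER = 1607.0
ADENINE_MARKER_CENTER = 620.0
COLLOID_CENTER = 240.0

FINGERPRINT_SIGMA = 8.0
REF_HALF_WINDOW = 15.0

#: Fraction of a Gaussian's total area captured by the +/-15 cm-1 window.
_REF_CAPTURE = math.erf(REF_HALF_WINDOW / (FINGERPRINT_SIGMA * math.sqrt(2.0)))
#: Reference-band area such that the windowed integral is exactly 1.
PO4_AREA = 1.0 / _REF_CAPTURE

THZ_SIGMA = 25.0
#: Main low-frequency (tetrad / intermolecular) band centers, cm-1.
THZ_BAND_CENTERS: Mapping[str, float] = {
    "dGTP": 95.0,
    "8-oxo-dGTP": 60.0,
    "GTP": 90.0,
    "8-oxo-GTP": 62.0,
}

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianBand:
    """A single Gaussian vibrational band.

    Parameters
    ----------
    center : float
        Band center in cm-1.
    width : float
        Gaussian sigma in cm-1 (> 0).
    area : float
        Integrated area in normalized intensity units (>= 0).
    assignment : str
        Free-text vibrational assignment.
    """

    center: float
    width: float
    area: float
    assignment: str = ""

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValueError(f"band width must be > 0, got {self.width}")
        if self.area < 0:
            raise ValueError(f"band area must be >= 0, got {self.area}")

    @property
    def amplitude(self) -> float:
        """Peak height implied by (area, width)."""
        return self.area / (self.width * _SQRT_2PI)

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Evaluate the band on a wavenumber grid."""
        x = np.asarray(wavenumbers, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((x - self.center) / self.width) ** 2)


#: species label -> sequence of bands
BandLibrary = Mapping[str, Sequence[GaussianBand]]


def _fp(center: float, area: float, assignment: str = "") -> GaussianBand:
    return GaussianBand(center, FINGERPRINT_SIGMA, area, assignment)


def default_band_library() -> dict[str, tuple[GaussianBand, ...]]:
    """Return the default fingerprint/SERS band library (fresh copy)."""
    dgtp = (
        _fp(681.0, 0.50, "guanine ring breathing"),
        _fp(PO4_CENTER, PO4_AREA, "PO4 backbone stretch (normalization reference)"),
        _fp(1365.0, 0.45, "ring mode"),
        _fp(1485.0, 0.90, "7N-8C stretch"),
        _fp(1575.0, 0.70, "3N-4C stretch"),
    )
    oxo_dgtp = (
        _fp(640.0, 0.50, "oxidized ring breathing"),
        _fp(PO4_CENTER, PO4_AREA, "PO4 backbone stretch (normalization reference)"),
        _fp(1445.0, 0.60, "7N-H bend"),
        _fp(MARKER_A_CENTER, 0.80, "7N-8C stretch (oxidation marker A)"),
        _fp(MARKER_B_CENTER, 0.90, "5C-7N stretch (oxidation marker B)"),
    )
    datp = (
        _fp(729.0, 1.20, "adenine ring breathing"),
        _fp(PO4_CENTER, PO4_AREA, "PO4 backbone stretch (normalization reference)"),
        _fp(1339.0, 0.90, "adenine ring mode"),
        _fp(1580.0, 0.60, "ring stretch"),
    )
    oxo_datp = (
        _fp(ADENINE_MARKER_CENTER, 0.70, "C5-N7-C8 squeeze (oxidation marker)"),
        _fp(729.0, 0.40, "adenine ring breathing"),
        _fp(PO4_CENTER, PO4_AREA, "PO4 backbone stretch (normalization reference)"),
        _fp(1339.0, 0.50, "adenine ring mode"),
        _fp(1580.0, 0.50, "ring stretch"),
    )
    # Nucleosides for SERS: no phosphate group, hence no 1123 cm-1 band.
    dg = (
        _fp(655.0, 1.00, "guanine ring breathing"),
        _fp(1326.0, 0.90, "ring mode"),
        _fp(1489.0, 0.80, "7N-8C stretch"),
        _fp(1578.0, 0.60, "3N-4C stretch"),
    )
    oxo_dg = (
        _fp(645.0, 0.80, "oxidized ring breathing"),
        _fp(1250.0, 0.60, "oxidation-sensitive mode"),
        _fp(MARKER_A_CENTER, 0.80, "7N-8C stretch (oxidation marker A)"),
        _fp(MARKER_B_CENTER, 0.90, "5C-7N stretch (oxidation marker B)"),
        _fp(1683.0, 0.40, "C8=O stretch"),
    )
    colloid = (GaussianBand(COLLOID_CENTER, 15.0, 1.50, "silver colloid band"),)
    return {
        "dGTP": dgtp,
        "8-oxo-dGTP": oxo_dgtp,
        # ribo counterparts: the sugar does not alter the fingerprint response
        "GTP": dgtp,
        "8-oxo-GTP": oxo_dgtp,
        "dATP": datp,
        "8-oxo-dATP": oxo_datp,
        "dG": dg,
        "8-oxo-dG": oxo_dg,
        "colloid": colloid,
    }


def bands_in_window(
    bands: Sequence[GaussianBand], window: tuple[float, float]
) -> tuple[GaussianBand, ...]:
    """Bands whose centers fall inside the closed ``window``."""
    lo, hi = window
    return tuple(b for b in bands if lo <= b.center <= hi)
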