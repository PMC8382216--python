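"""Linear calibration of oxidation-marker band intensity versus oxidized fraction.

The normalized integrated intensity I of an oxidation-marker band in a mixture
follows I = m * C + I0, where C is the oxidized fraction in % and I0 is the
intensity measured on the nominally pure non-oxidized sample — interpreted as
an accidental contamination C0 rather than a true blank signal.  The C0
correction subtracts the fitted I0 from every point and refits the line
through the origin, so the corrected calibration has zero intercept by
construction.  Inverse prediction C = (I - I0)/m carries first-order
propagated uncertainty from the measured area, the slope, the intercept and
the residual scatter, and the detection limit uses the ICH-style rule
LOD = k * sigma_res / m with k = 3.3 by default (the criterion behind the
reported limits is configurable, not fixed by the science).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .exceptions import DesignError

__all__ = [
    "CalibrationCurve",
    "ConcentrationEstimate",
    "LinearCalibration",
    "build_calibration",
    "average_calibration",
    "predict_concentration",
    "detection_limit",
]


@dataclass(frozen=True)
class ConcentrationEstimate:
    """An inverse-predicted oxidized fraction with standard uncertainty (%)."""

    value: float
    uncertainty: float
    curve_label: str = ""
    below_range: bool = False
    above_range: bool = False

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted marker-band calibration line I = m*C + I0.

    ``sigma_res`` is the residual scatter of the points about the line in
    normalized intensity units; after C0 correction the intercept is zero by
    construction and its nominal error at C = 0 is zero as well.
    """

    label: str
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    sigma_res: float
    concentrations: np.ndarray = field(repr=False)
    areas: np.ndarray = field(repr=False)  # after any C0 subtraction
    c0_corrected: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "areas", np.asarray(self.areas, dtype=float))
        if self.n < 3:
            raise DesignError(f"calibration needs >= 3 points, got {self.n}")
        if self.sigma_res < 0:
            raise ValueError("sigma_res must be >= 0")

    @property
    def n(self) -> int:
        return int(np.asarray(self.concentrations).size)

    @property
    def conc_range(self) -> tuple[float, float]:
        return float(self.concentrations.min()), float(self.concentrations.max())

    def predict(self, area: float, area_se: float = 0.0) -> ConcentrationEstimate:
        """Inverse prediction C = (I - I0)/m with propagated uncertainty.

        Out-of-range estimates (below the lowest or above the highest
        calibrated concentration) are flagged, never clipped.
        """
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a calibration with zero slope")
        value = (area - self.intercept) / self.slope
        var = (area_se**2 + self.sigma_res**2 + self.intercept_se**2) / self.slope**2
        var += value**2 * (self.slope_se / self.slope) ** 2
        lo, hi = self.conc_range
        return ConcentrationEstimate(
            value=float(value),
            uncertainty=float(np.sqrt(var)),
            curve_label=self.label,
            below_range=value < lo,
            above_range=value > hi,
        )

    def detection_limit(self, k: float = 3.3) -> float:
        """LOD = k * sigma_res / slope, in % oxidized fraction."""
        if self.slope <= 0:
            raise ValueError(f"detection limit requires slope > 0, got {self.slope}")
        return float(k * self.sigma_res / self.slope)

    def summary(self) -> str:
        lo, hi = self.conc_range
        lines = [
            f"Calibration curve [{self.label}]  I = m*C" + ("" if self.c0_corrected else " + I0"),
            f"  n points             : {self.n}  (C in [{lo:g}, {hi:g}] %)",
            f"  slope m              : {self.slope:.6f} +/- {self.slope_se:.6f}  per %",
            f"  intercept I0         : {self.intercept:.6f} +/- {self.intercept_se:.6f}",
            f"  residual SD          : {self.sigma_res:.6f}",
            f"  C0-corrected         : {self.c0_corrected}",
            f"  LOD (k=3.3)          : {self.detection_limit():.3f} %"
            if self.slope > 0
            else "  LOD                  : undefined (slope <= 0)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter the calibration points with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.concentrations, self.areas, "o", label="band areas")
        grid = np.linspace(*self.conc_range, 50)
        ax.plot(grid, self.slope * grid + self.intercept, "-", label="fit")
        ax.set_xlabel("oxidized fraction C [%]")
        ax.set_ylabel("normalized integrated intensity")
        ax.set_title(self.label)
        ax.legend()
        return ax


class LinearCalibration:
    """Weighted/ordinary least-squares calibration model.

    Parameters
    ----------
    concentrations, areas : sequences of float
        Oxidized fractions (%) and normalized marker-band areas; >= 3 distinct
        concentrations with nonzero spread are required.
    area_errors : sequence of float, optional
        Per-point 1-sigma area errors; when given (and all > 0) the fit is
        weighted by 1/err^2.
    correct_c0 : bool
        Apply the contamination correction: subtract the fitted intercept from
        every point and refit through the origin.
    """

    def __init__(
        self,
        concentrations: Sequence[float],
        areas: Sequence[float],
        area_errors: Sequence[float] | None = None,
        correct_c0: bool = True,
        label: str = "",
    ) -> None:
        c = np.asarray(concentrations, dtype=float)
        a = np.asarray(areas, dtype=float)
        if c.shape != a.shape or c.ndim != 1:
            raise ValueError("concentrations and areas must be equal-length 1-D")
        if np.unique(c).size < 3:
            raise DesignError(
                f"need >= 3 distinct concentrations, got {np.unique(c).size}"
            )
        if np.ptp(c) == 0:
            raise DesignError("zero concentration spread: degenerate design")
        self.concentrations = c
        self.areas = a
        self.area_errors = None
        if area_errors is not None:
            err = np.asarray(area_errors, dtype=float)
            if err.shape != c.shape:
                raise ValueError("area_errors must match points")
            if np.all(err > 0):
                self.area_errors = err
        self.correct_c0 = correct_c0
        self.label = label

    def _weights(self) -> np.ndarray | None:
        if self.area_errors is None:
            return None
        return 1.0 / self.area_errors**2

    def fit(self) -> CalibrationCurve:
        c, a = self.concentrations, self.areas
        w = self._weights()
        X = sm.add_constant(c)
        res1 = (sm.OLS(a, X) if w is None else sm.WLS(a, X, weights=w)).fit()
        intercept, slope = (float(p) for p in res1.params)
        intercept_se = float(res1.bse[0])

        if self.correct_c0:
            # subtracting the fitted I0 and refitting through the origin
            # returns the two-parameter slope unchanged (the weighted
            # residuals are orthogonal to C), so the slope and its SE are
            # those of the full fit; only the points are shifted
            a = a - intercept
            resid = a - slope * c
            dof = max(c.size - 2, 1)
            sigma_res = float(np.sqrt(np.sum(resid**2) / dof))
            slope_se = float(res1.bse[1])
            intercept, intercept_se = 0.0, 0.0
        else:
            resid = a - (slope * c + intercept)
            dof = max(c.size - 2, 1)
            sigma_res = float(np.sqrt(np.sum(resid**2) / dof))
            slope_se = float(res1.bse[1])

        return CalibrationCurve(
            label=self.label,
            slope=slope,
            slope_se=slope_se,
            intercept=intercept,
            intercept_se=intercept_se,
            sigma_res=sigma_res,
            concentrations=c,
            areas=a,
            c0_corrected=self.correct_c0,
        )


def build_calibration(
    points: Sequence[tuple],
    correct_c0: bool = True,
    label: str = "",
) -> CalibrationCurve:
    """Build a calibration from (C, area) or (C, area, area_se) tuples."""
    points = list(points)
    conc = [p[0] for p in points]
    areas = [p[1] for p in points]
    errors = [p[2] for p in points] if all(len(p) >= 3 for p in points) else None
    return LinearCalibration(
        conc, areas, area_errors=errors, correct_c0=correct_c0, label=label
    ).fit()


def average_calibration(
    curve_a: CalibrationCurve, curve_b: CalibrationCurve
) -> CalibrationCurve:
    """Inverse-variance-weighted average of two intercept-corrected curves.

    Both curves must share the same concentration design; the pooled residual
    SD is the root-mean-square of the two.
    """
    if not (curve_a.c0_corrected and curve_b.c0_corrected):
        raise DesignError("average_calibration requires both curves C0-corrected")
    ca = np.sort(curve_a.concentrations)
    cb = np.sort(curve_b.concentrations)
    if ca.size != cb.size or not np.allclose(ca, cb):
        raise DesignError("calibration designs differ; cannot average")

    if curve_a.slope_se > 0 and curve_b.slope_se > 0:
        wa, wb = 1.0 / curve_a.slope_se**2, 1.0 / curve_b.slope_se**2
        slope = (wa * curve_a.slope + wb * curve_b.slope) / (wa + wb)
        slope_se = float(np.sqrt(1.0 / (wa + wb)))
    else:  # exact fits: plain mean, zero propagated error
        slope = 0.5 * (curve_a.slope + curve_b.slope)
        slope_se = 0.0
    sigma_res = float(np.sqrt(0.5 * (curve_a.sigma_res**2 + curve_b.sigma_res**2)))

    order_a = np.argsort(curve_a.concentrations, kind="stable")
    order_b = np.argsort(curve_b.concentrations, kind="stable")
    return CalibrationCurve(
        label=f"average({curve_a.label or 'A'}, {curve_b.label or 'B'})",
        slope=float(slope),
        slope_se=slope_se,
        intercept=0.0,
        intercept_se=0.0,
        sigma_res=sigma_res,
        concentrations=ca,
        areas=0.5 * (curve_a.areas[order_a] + curve_b.areas[order_b]),
        c0_corrected=True,
    )


def predict_concentration(
    curve: CalibrationCurve, area: float, area_se: float = 0.0
) -> ConcentrationEstimate:
    """Functional form of :meth:`CalibrationCurve.predict`."""
    return curve.predict(area, area_se)


def detection_limit(curve: CalibrationCurve, k: float = 3.3) -> float:
    """Functional form of :meth:`CalibrationCurve.detection_limit`."""
    return curve.detection_limit(k)
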