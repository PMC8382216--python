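"""PLS1 (NIPALS) quantification of oxidized fraction from SERS spectra.

SERS spectra carry a large spot-to-spot multiplicative enhancement gain and a
colloid background, so single-band deconvolution is unreliable; instead the
oxidized fraction is regressed on the whole 400-1800 cm-1 window.  Spectra
are unit-vector normalized (removing the gain), mean-centered and projected
onto latent components that maximize covariance with the response — three
components by default.  The PLS1 algorithm is the classical NIPALS with
deflation; for a single response it is fully deterministic.  Predictions are
invariant to positive scaling of the input spectrum and may fall outside
[0, 100] (flagged, never clipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import GridError, RankError
from .preprocess import unit_vector_normalize
from .spectra import Spectrum

__all__ = [
    "PLSResult",
    "PLSPrediction",
    "CrossValidationResult",
    "SERSPLS",
    "fit_pls",
    "predict_pls",
    "cross_validate_pls",
]

DEFAULT_WINDOW = (400.0, 1800.0)


def _nipals_pls1(
    X: np.ndarray, y: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean-centered inputs -> (W, P, q, T); raises RankError on collapse."""
    Xc = X.copy()
    yc = y.copy()
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    x_scale = max(float(np.abs(X).max()), 1e-300)
    for k in range(n_components):
        w = Xc.T @ yc
        nw = float(np.linalg.norm(w))
        if nw <= 1e-12 * x_scale * max(float(np.abs(y).max()), 1e-300):
            raise RankError(
                f"component {k + 1} exceeds the informative rank of the data"
            )
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            raise RankError(
                f"component {k + 1} has vanishing scores; rank exhausted"
            )
        P[:, k] = Xc.T @ t / tt
        q[k] = float(yc @ t) / tt
        W[:, k] = w
        T[:, k] = t
        Xc -= np.outer(t, P[:, k])
        yc = yc - q[k] * t
    return W, P, q, T


@dataclass(frozen=True)
class PLSPrediction:
    """A predicted oxidized fraction; out-of-range values are flagged."""

    value: float
    below_range: bool = False
    above_range: bool = False


@dataclass(frozen=True)
class PLSResult:
    """A fitted PLS1 model over a fixed wavenumber grid."""

    grid: np.ndarray = field(repr=False)
    window: tuple[float, float]
    n_components: int
    x_weights: np.ndarray = field(repr=False)  # (p, k)
    x_loadings: np.ndarray = field(repr=False)  # (p, k)
    y_loadings: np.ndarray = field(repr=False)  # (k,)
    coef: np.ndarray = field(repr=False)  # (p,)
    x_mean: np.ndarray = field(repr=False)
    y_mean: float
    scores: np.ndarray = field(repr=False)  # (n, k)
    fitted: np.ndarray = field(repr=False)
    actual: np.ndarray = field(repr=False)

    @property
    def r_squared(self) -> float:
        ss_res = float(np.sum((self.actual - self.fitted) ** 2))
        ss_tot = float(np.sum((self.actual - np.mean(self.actual)) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    def _vector(self, spectrum: Spectrum, regrid: bool) -> np.ndarray:
        s = unit_vector_normalize(spectrum, self.window)
        if s.wavenumbers.shape == self.grid.shape and np.allclose(
            s.wavenumbers, self.grid
        ):
            return s.intensities
        if not regrid:
            raise GridError(
                "spectrum grid differs from training grid; pass regrid=True "
                "to interpolate explicitly"
            )
        interp = np.interp(self.grid, s.wavenumbers, s.intensities)
        norm = float(np.linalg.norm(interp))
        return interp / norm

    def predict(self, spectrum: Spectrum, regrid: bool = False) -> PLSPrediction:
        """Predict the oxidized fraction (%) of one spectrum."""
        x = self._vector(spectrum, regrid)
        value = float((x - self.x_mean) @ self.coef + self.y_mean)
        return PLSPrediction(
            value=value, below_range=value < 0.0, above_range=value > 100.0
        )

    def summary(self) -> str:
        lines = [
            f"PLS1 (NIPALS) regression, window {self.window[0]:g}-{self.window[1]:g} cm-1",
            f"  training samples : {self.actual.size}",
            f"  grid points      : {self.grid.size}",
            f"  components       : {self.n_components}",
            f"  training R^2     : {self.r_squared:.4f}",
            f"  y loadings       : {np.array2string(self.y_loadings, precision=4)}",
        ]
        return "\n".join(lines)

    def plot_predicted(self, ax=None):
        """Predicted-vs-actual scatter for the training set."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.actual, self.fitted, "o")
        lim = [min(self.actual.min(), 0), max(self.actual.max(), 1)]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("actual oxidized fraction [%]")
        ax.set_ylabel("predicted oxidized fraction [%]")
        return ax


@dataclass(frozen=True)
class CrossValidationResult:
    """Leave-one-out predictions with residuals and RMSECV."""

    table: pd.DataFrame  # columns actual, predicted, residual
    rmsecv: float

    @property
    def regression_slope(self) -> float:
        """OLS slope of predicted on actual."""
        a = self.table["actual"].to_numpy()
        p = self.table["predicted"].to_numpy()
        ac = a - a.mean()
        return float((ac @ (p - p.mean())) / (ac @ ac))


class SERSPLS:
    """PLS1 regression model of oxidized fraction on SERS spectra.

    Parameters
    ----------
    spectra : sequence of Spectrum
        Training spectra; each must cover ``window`` and all must share one
        wavenumber grid after cropping (no silent resampling).
    fractions : sequence of float
        Oxidized fractions in %.
    n_components : int
        Latent components (default 3).
    """

    def __init__(
        self,
        spectra: Sequence[Spectrum],
        fractions: Sequence[float],
        n_components: int = 3,
        window: tuple[float, float] = DEFAULT_WINDOW,
    ) -> None:
        if len(spectra) != len(fractions):
            raise ValueError("spectra and fractions must have equal length")
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if len(spectra) < n_components + 1:
            raise RankError(
                f"need >= {n_components + 1} spectra for {n_components} components"
            )
        normalized = [unit_vector_normalize(s, window) for s in spectra]
        grid = normalized[0].wavenumbers
        for s in normalized[1:]:
            if s.wavenumbers.shape != grid.shape or not np.allclose(
                s.wavenumbers, grid
            ):
                raise GridError("training spectra do not share a common grid")
        self.window = (float(window[0]), float(window[1]))
        self.grid = grid
        self.X = np.vstack([s.intensities for s in normalized])
        self.y = np.asarray(fractions, dtype=float)
        self.n_components = int(n_components)
        self._spectra = list(spectra)

    def fit(self) -> PLSResult:
        x_mean = self.X.mean(axis=0)
        y_mean = float(self.y.mean())
        Xc = self.X - x_mean
        yc = self.y - y_mean
        W, P, q, T = _nipals_pls1(Xc, yc, self.n_components)
        coef = W @ np.linalg.solve(P.T @ W, q)
        fitted = Xc @ coef + y_mean
        return PLSResult(
            grid=self.grid,
            window=self.window,
            n_components=self.n_components,
            x_weights=W,
            x_loadings=P,
            y_loadings=q,
            coef=coef,
            x_mean=x_mean,
            y_mean=y_mean,
            scores=T,
            fitted=fitted,
            actual=self.y.copy(),
        )

    def cross_validate(self) -> CrossValidationResult:
        """Leave-one-out refits; deterministic."""
        n = self.y.size
        if n < 4:
            raise ValueError(f"leave-one-out needs >= 4 samples, got {n}")
        preds = np.empty(n)
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            sub = SERSPLS(
                [self._spectra[j] for j in keep],
                self.y[keep],
                n_components=self.n_components,
                window=self.window,
            ).fit()
            preds[i] = sub.predict(self._spectra[i]).value
        table = pd.DataFrame(
            {"actual": self.y, "predicted": preds, "residual": preds - self.y}
        )
        rmsecv = float(np.sqrt(np.mean((preds - self.y) ** 2)))
        return CrossValidationResult(table=table, rmsecv=rmsecv)


def fit_pls(
    spectra: Sequence[Spectrum],
    fractions: Sequence[float],
    n_components: int = 3,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> PLSResult:
    """Fit a PLS1 model of oxidized fraction on SERS spectra."""
    return SERSPLS(spectra, fractions, n_components, window).fit()


def predict_pls(model: PLSResult, spectrum: Spectrum, regrid: bool = False) -> PLSPrediction:
    """Predict the oxidized fraction of one spectrum with a fitted model."""
    return model.predict(spectrum, regrid=regrid)


def cross_validate_pls(
    spectra: Sequence[Spectrum],
    fractions: Sequence[float],
    n_components: int = 3,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> CrossValidationResult:
    """Leave-one-out cross-validation of the PLS quantification."""
    return SERSPLS(spectra, fractions, n_components, window).cross_validate()
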