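"""Tait equation of state for the specific volume of a liquid.

    v(P, T) = v₀ [1 + α_v (T − T₀)] [1 − k ln(1 + P / (b₁ e^(−b₃ T)))]

with v in cm³/g, T in K and P in MPa.  The reference temperature T₀ is a
fixed convention, not a fitted parameter: shifting T₀ merely rescales v₀,
so the two are not jointly identifiable.  b₃ is identifiable only when at
least two isotherms are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["TaitParams", "PVTRecord", "TaitEOS", "fit_tait", "specific_volume"]


@dataclass(frozen=True)
class TaitParams:
    """Tait EOS parameters: v₀ (cm³/g), α_v (K⁻¹), T₀ (K), k, b₁ (MPa), b₃ (K⁻¹)."""

    v0: float
    alpha_v: float
    T0: float
    k: float
    b1: float
    b3: float

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.k <= 0 or self.b1 <= 0:
            raise ValueError("v0, k and b1 must be positive")


@dataclass(frozen=True)
class PVTRecord:
    """One PVT measurement: T (K), P (MPa), specific volume v (cm³/g)."""

    T: float
    P: float
    v: float

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("specific volume must be positive")


def specific_volume(tait: TaitParams, T, P) -> np.ndarray:
    """Evaluate the Tait EOS at (T, P); exact closed form.

    The EOS is calibrated on equilibrium-liquid PVT data; evaluations in
    the glass are extrapolations and should be read with caution.
    """
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    arg = 1.0 + P / (tait.b1 * np.exp(-tait.b3 * T))
    if np.any(arg <= 0):
        raise ValueError("argument of the Tait logarithm must be positive")
    v = tait.v0 * (1.0 + tait.alpha_v * (T - tait.T0)) * (1.0 - tait.k * np.log(arg))
    return v if v.ndim else float(v)


def _coerce_pvt(pvt) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(pvt, pd.DataFrame):
        return (pvt["T_K"].to_numpy(float), pvt["P_MPa"].to_numpy(float),
                pvt["v_cm3g"].to_numpy(float))
    recs = list(pvt)
    T = np.array([r.T for r in recs], dtype=float)
    P = np.array([r.P for r in recs], dtype=float)
    v = np.array([r.v for r in recs], dtype=float)
    return T, P, v


class TaitEOS(BaseEstimator, RegressorMixin):
    """Least-squares Tait EOS fit.

    ``fit(X, y)`` takes ``X`` with columns (T, P) and ``y`` the specific
    volume.  Fitted attributes: ``params_`` (:class:`TaitParams`) plus the
    individual coefficients ``v0_``, ``alpha_v_``, ``k_``, ``b1_``, ``b3_``.

    Parameters
    ----------
    T0 : float
        Fixed reference temperature of the thermal-expansion factor (K).
    """

    def __init__(self, T0: float = 300.0):
        self.T0 = T0

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        T, P = X[:, 0], X[:, 1]
        v = np.asarray(y, dtype=float).ravel()
        if np.unique(np.round(T, 6)).size < 2:
            raise ValueError(
                "at least 2 isotherms are required: with a single isotherm "
                "the temperature coefficient b3 is unidentifiable")

        T0 = self.T0

        def f(X, v0, alpha_v, k, b1, b3):
            T, P = X
            return v0 * (1.0 + alpha_v * (T - T0)) * (
                1.0 - k * np.log1p(P / (b1 * np.exp(-b3 * T))))

        v0_0 = float(np.mean(v[P <= np.percentile(P, 20)]))
        p0 = (v0_0, 7e-4, 0.09, 2.0 * P.max(), 4e-3)
        popt, pcov = optimize.curve_fit(
            f, (T, P), v, p0=p0,
            bounds=([1e-3, 1e-6, 1e-4, 1.0, 0.0],
                    [100.0, 1e-1, 1.0, 1e5, 5e-2]),
            maxfev=50000)
        self.v0_, self.alpha_v_, self.k_, self.b1_, self.b3_ = map(float, popt)
        self.params_ = TaitParams(self.v0_, self.alpha_v_, self.T0,
                                  self.k_, self.b1_, self.b3_)
        resid = f((T, P), *popt) - v
        self.rms_ = float(np.sqrt(np.mean(resid ** 2)))
        if self.rms_ > 0.005 * np.mean(v):
            warnings.warn(
                f"Tait fit residual RMS ({self.rms_:.3g}) exceeds 0.5% of mean v")
        self.stderr_ = np.sqrt(np.diag(pcov))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return specific_volume(self.params_, X[:, 0], X[:, 1])


def fit_tait(pvt, T0: float = 300.0) -> TaitParams:
    """Fit the Tait EOS to PVT records (list of :class:`PVTRecord` or a
    DataFrame with columns T_K, P_MPa, v_cm3g)."""
    T, P, v = _coerce_pvt(pvt)
    return TaitEOS(T0=T0).fit(np.column_stack([T, P]), v).params_
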