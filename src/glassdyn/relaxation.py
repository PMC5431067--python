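"""Temperature- and pressure-dependence of relaxation times.

Covers the standard toolkit for the primary (α) relaxation of a glass
former and for the Arrhenius-slope change of the Johari-Goldstein β
process at the glass transition:

* Vogel-Fulcher-Tammann fit  τ_α(T) = τ∞ exp[s·T_VF/(T − T_VF)]
* glass transition temperature Tg defined by τ_α(Tg) = 100 s
* isochronal fragility  m = d(Log τ_α)/d(Tg/T) at T = Tg
* pressure-Arrhenius fit  τ_α(P) = τ₀ exp(P·V_a/RT)  and Pg
* Andersson-Andersson Tg(P) = k₁(1 + k₂P)^k₃  (P in GPa)
* two-segment (kinked) Arrhenius fit of τ_β across Tg

Units: T in K, P in MPa (GPa only inside the Andersson fit), τ in s,
V_a in cm³/mol.  MPa·cm³ = J makes P·V_a/(R·T) dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .models import R_GAS

__all__ = [
    "TAU_GLASS",
    "VFTParams",
    "ArrheniusPParams",
    "AnderssonParams",
    "CrossoverFit",
    "VFTRegressor",
    "PressureArrheniusRegressor",
    "AnderssonRegressor",
    "CrossoverDetector",
    "fit_vft",
    "eval_vft",
    "glass_transition_temperature",
    "fragility",
    "fit_pressure_arrhenius",
    "eval_pressure_arrhenius",
    "glass_transition_pressure",
    "fit_andersson",
    "andersson_tg",
    "detect_crossover",
]

#: Conventional relaxation time at the glass transition, s.
TAU_GLASS = 100.0


@dataclass(frozen=True)
class VFTParams:
    """Vogel-Fulcher-Tammann parameters (τ∞ in s, s dimensionless, T_VF in K)."""

    tau_inf: float
    s: float
    T_VF: float

    def __post_init__(self) -> None:
        if self.tau_inf <= 0 or self.s <= 0 or self.T_VF <= 0:
            raise ValueError("VFT parameters must be positive")


@dataclass(frozen=True)
class ArrheniusPParams:
    """Pressure-Arrhenius parameters at fixed T (τ₀ in s, V_a in cm³/mol)."""

    tau_0: float
    V_a: float
    T: float

    def __post_init__(self) -> None:
        if self.tau_0 <= 0:
            raise ValueError("tau_0 must be positive")


@dataclass(frozen=True)
class AnderssonParams:
    """Andersson-Andersson Tg(P) parameters: k₁ (K), k₂ (GPa⁻¹), k₃."""

    k1: float
    k2: float
    k3: float

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")


@dataclass(frozen=True)
class CrossoverFit:
    """Two-segment Arrhenius fit of ln τ vs 1/T with continuity at T_break.

    Slopes are d ln τ / d(1/T) in K; ``slope_below`` applies on the
    low-temperature (glass) side, which is the weaker one.
    """

    T_break: float
    T_break_se: float
    slope_below: float
    slope_above: float
    p_value: float
    significant: bool


def eval_vft(vft: VFTParams, T) -> np.ndarray:
    """τ_α(T) from the VFT equation."""
    T = np.asarray(T, dtype=float)
    return vft.tau_inf * np.exp(vft.s * vft.T_VF / (T - vft.T_VF))


def eval_pressure_arrhenius(arr: ArrheniusPParams, P) -> np.ndarray:
    """τ_α(P) = τ₀ exp(P·V_a/RT) with P in MPa, V_a in cm³/mol."""
    P = np.asarray(P, dtype=float)
    return arr.tau_0 * np.exp(P * arr.V_a / (R_GAS * arr.T))


def andersson_tg(params: AnderssonParams, P_GPa) -> np.ndarray:
    """Tg(P) = k₁(1 + k₂P)^k₃ with P in GPa."""
    P_GPa = np.asarray(P_GPa, dtype=float)
    return params.k1 * (1.0 + params.k2 * P_GPa) ** params.k3


class VFTRegressor(BaseEstimator, RegressorMixin):
    """Fit Log τ_α(T) with the Vogel-Fulcher-Tammann equation.

    ``fit(T, tau)`` performs least squares on log₁₀ τ.  Fitted attributes:
    ``tau_inf_``, ``s_``, ``T_VF_`` and ``params_`` (a :class:`VFTParams`).
    """

    def __init__(self, tau_max: float | None = TAU_GLASS):
        self.tau_max = tau_max

    def fit(self, X, y):
        T = np.asarray(X, dtype=float).ravel()
        tau = np.asarray(y, dtype=float).ravel()
        if self.tau_max is not None:
            sel = tau <= self.tau_max
            T, tau = T[sel], tau[sel]
        if T.size < 5:
            raise ValueError("need at least 5 points for a VFT fit")
        lt = np.log10(tau)
        if lt.max() - lt.min() < 3.0:
            raise ValueError("VFT fit requires >= 3 decades span in tau")

        def f(T, log10_tau_inf, s, T_VF):
            return log10_tau_inf + s * T_VF / (T - T_VF) / np.log(10.0)

        Tmin = T.min()
        best = None
        # multi-start on T_VF; the VFT objective is mildly non-convex
        for frac in (0.5, 0.65, 0.8, 0.9):
            p0 = (-14.0, 10.0, frac * Tmin)
            try:
                # soft_l1 keeps occasional mis-deconvolved spectra from
                # bending the whole curve
                popt, pcov = optimize.curve_fit(
                    f, T, lt, p0=p0,
                    bounds=([-30, 1e-3, 1.0], [0.0, 1e3, Tmin - 1e-6]),
                    loss="soft_l1", f_scale=0.1, maxfev=20000)
            except RuntimeError:
                continue
            rss = float(np.sum((f(T, *popt) - lt) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt, pcov)
        if best is None:
            raise RuntimeError("VFT fit did not converge for any start point")
        rss, popt, pcov = best
        if popt[2] >= Tmin:
            raise RuntimeError(
                f"fitted T_VF = {popt[2]:.1f} K is not below the data range")
        self.tau_inf_ = float(10.0 ** popt[0])
        self.s_ = float(popt[1])
        self.T_VF_ = float(popt[2])
        self.params_ = VFTParams(self.tau_inf_, self.s_, self.T_VF_)
        self.stderr_ = np.sqrt(np.diag(pcov))
        self.rss_ = rss
        return self

    def predict(self, X):
        T = np.asarray(X, dtype=float).ravel()
        return eval_vft(self.params_, T)


def fit_vft(T, tau, tau_max: float | None = TAU_GLASS) -> VFTParams:
    """Fit the VFT equation to α relaxation times at fixed pressure.

    Only equilibrium supercooled-liquid points (τ ≤ ``tau_max``) enter the
    fit; pass ``tau_max=None`` to keep everything.
    """
    return VFTRegressor(tau_max=tau_max).fit(T, tau).params_


def glass_transition_temperature(vft: VFTParams, tau_g: float = TAU_GLASS) -> float:
    """Tg from inverting the VFT equation at τ(Tg) = tau_g (default 100 s)."""
    if tau_g <= vft.tau_inf:
        raise ValueError("tau_g must exceed the VFT prefactor tau_inf")
    return vft.T_VF * (1.0 + vft.s / np.log(tau_g / vft.tau_inf))


def fragility(vft: VFTParams, Tg: float | None = None,
              tau_g: float = TAU_GLASS) -> float:
    """Isochronal fragility m = d(Log τ_α)/d(Tg/T) evaluated at T = Tg.

    Closed form for the VFT equation:
    m = s·T_VF·Tg / [ln10 · (Tg − T_VF)²].
    """
    if Tg is None:
        Tg = glass_transition_temperature(vft, tau_g)
    if Tg <= vft.T_VF:
        raise ValueError("Tg must exceed T_VF")
    return vft.s * vft.T_VF * Tg / (np.log(10.0) * (Tg - vft.T_VF) ** 2)


class PressureArrheniusRegressor(BaseEstimator, RegressorMixin):
    """Fit ln τ_α vs P at fixed temperature (activation-volume fit).

    Fitted attributes: ``tau_0_`` (s), ``V_a_`` (cm³/mol), ``params_``.
    """

    def __init__(self, T: float = 298.15):
        self.T = T

    def fit(self, X, y):
        P = np.asarray(X, dtype=float).ravel()
        tau = np.asarray(y, dtype=float).ravel()
        if P.size < 4:
            raise ValueError("need at least 4 points")
        if P.max() - P.min() < 100.0:
            raise ValueError("pressure span must be at least 100 MPa")
        slope, intercept = np.polyfit(P, np.log(tau), 1)
        V_a = float(slope * R_GAS * self.T)
        if V_a < 0:
            import warnings
            warnings.warn("fitted activation volume is negative (unphysical)")
        self.tau_0_ = float(np.exp(intercept))
        self.V_a_ = V_a
        self.params_ = ArrheniusPParams(self.tau_0_, self.V_a_, self.T)
        return self

    def predict(self, X):
        return eval_pressure_arrhenius(self.params_, X)


def fit_pressure_arrhenius(P, tau, T: float) -> ArrheniusPParams:
    """Fit τ_α(P) = τ₀ exp(P·V_a/RT) on one isotherm (P in MPa)."""
    return PressureArrheniusRegressor(T=T).fit(P, tau).params_


def glass_transition_pressure(arr: ArrheniusPParams, T: float | None = None,
                              tau_g: float = TAU_GLASS) -> float:
    """Pg (MPa) where τ_α(Pg) = tau_g, from the pressure-Arrhenius fit."""
    if T is None:
        T = arr.T
    if tau_g <= arr.tau_0:
        raise ValueError("system is already glassy at ambient pressure")
    return R_GAS * T / arr.V_a * np.log(tau_g / arr.tau_0)


class AnderssonRegressor(BaseEstimator, RegressorMixin):
    """Fit the sublinear Tg(P) = k₁(1 + k₂P)^k₃ law (P in GPa)."""

    def fit(self, X, y):
        P = np.asarray(X, dtype=float).ravel()
        Tg = np.asarray(y, dtype=float).ravel()
        if P.size < 4:
            raise ValueError("need at least 4 (P, Tg) points")

        def f(P, k1, k2, k3):
            return k1 * (1.0 + k2 * P) ** k3

        best = None
        for k2_0 in (0.5, 2.0, 5.0, 10.0):
            try:
                popt, pcov = optimize.curve_fit(
                    f, P, Tg, p0=(Tg.min(), k2_0, 0.3),
                    bounds=([1.0, 1e-3, 1e-3], [2e3, 1e3, 2.0]), maxfev=20000)
            except RuntimeError:
                continue
            rss = float(np.sum((f(P, *popt) - Tg) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt, pcov)
        if best is None:
            raise RuntimeError(
                "Andersson fit failed from all points of the seed grid "
                "(k2 in {0.5, 2, 5, 10} GPa^-1)")
        rss, popt, pcov = best
        self.k1_, self.k2_, self.k3_ = map(float, popt)
        if not 0.0 < self.k3_ <= 1.0:
            import warnings
            warnings.warn(f"fitted k3 = {self.k3_:.3f} outside (0, 1]")
        self.params_ = AnderssonParams(self.k1_, self.k2_, self.k3_)
        self.stderr_ = np.sqrt(np.diag(pcov))
        return self

    def predict(self, X):
        return andersson_tg(self.params_, X)


def fit_andersson(P_GPa, Tg) -> AnderssonParams:
    """Fit Tg(P) = k₁(1 + k₂P)^k₃ to (P [GPa], Tg [K]) pairs."""
    return AnderssonRegressor().fit(P_GPa, Tg).params_


def _two_segment_rss(x, y, xb):
    """Continuous two-segment linear LSQ with break at xb; returns rss, coefs."""
    # y = a + s1*(x-xb) for x<=xb ; a + s2*(x-xb) for x>xb
    below = x <= xb
    A = np.column_stack([
        np.ones_like(x),
        np.where(below, x - xb, 0.0),
        np.where(~below, x - xb, 0.0),
    ])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((A @ coef - y) ** 2))
    return rss, coef


class CrossoverDetector(BaseEstimator):
    """Detect the Arrhenius-slope kink of τ_β at the glass transition.

    Fits a continuous two-segment line in (1/T, ln τ), scanning every
    admissible break point, and accepts the kink only if an F-test against
    the single-line fit is significant.  ``fit(T, tau)`` sets
    ``crossover_`` (a :class:`CrossoverFit`) or ``None``.

    Parameters
    ----------
    min_points : int
        Minimum points required on each side of the break.
    alpha : float
        F-test significance level.
    n_boot : int
        Residual-bootstrap resamples for the T_break uncertainty.
    tg_hint : float or None
        If several break candidates tie (RSS within 1%), prefer the one
        closest to this independently determined Tg.
    """

    def __init__(self, min_points: int = 4, alpha: float = 0.05,
                 n_boot: int = 200, seed: int = 0, tg_hint: float | None = None):
        self.min_points = min_points
        self.alpha = alpha
        self.n_boot = n_boot
        self.seed = seed
        self.tg_hint = tg_hint

    def _scan(self, x, y):
        candidates = []
        n = x.size
        for i in range(self.min_points - 1, n - self.min_points):
            xb = 0.5 * (x[i] + x[i + 1])
            rss, coef = _two_segment_rss(x, y, xb)
            candidates.append((rss, xb, coef))
        rss_min = min(c[0] for c in candidates)
        # tie-break: among near-optimal candidates pick closest to Tg hint
        ties = [c for c in candidates if c[0] <= rss_min * 1.01 + 1e-30]
        if self.tg_hint is not None and len(ties) > 1:
            ties.sort(key=lambda c: abs(1.0 / c[1] - self.tg_hint))
        else:
            ties.sort(key=lambda c: c[0])
        return ties[0]

    def fit(self, X, y):
        T = np.asarray(X, dtype=float).ravel()
        tau = np.asarray(y, dtype=float).ravel()
        order = np.argsort(T)
        T, tau = T[order], tau[order]
        if T.size < 2 * self.min_points:
            raise ValueError(
                f"need at least {2 * self.min_points} points for a kink fit")
        x = 1.0 / T
        yv = np.log(tau)
        idx = np.argsort(x)
        x, yv = x[idx], yv[idx]
        n = x.size

        rss2, xb, coef = self._scan(x, yv)
        # single-line fit
        A1 = np.column_stack([np.ones_like(x), x])
        c1, *_ = np.linalg.lstsq(A1, yv, rcond=None)
        rss1 = float(np.sum((A1 @ c1 - yv) ** 2))

        dof2 = n - 4
        if rss2 <= 0 or dof2 <= 0:
            p_value = 0.0
        else:
            F = ((rss1 - rss2) / 2.0) / (rss2 / dof2)
            p_value = float(stats.f.sf(F, 2, dof2))
        significant = p_value < self.alpha
        if not significant:
            self.crossover_ = None
            return self

        # residual bootstrap for T_break uncertainty
        rng = np.random.default_rng(self.seed)
        fitted = _predict_two_segment(x, xb, coef)
        resid = yv - fitted
        breaks = []
        for _ in range(self.n_boot):
            yb = fitted + rng.choice(resid, size=n, replace=True)
            _, xb_b, _ = self._scan(x, yb)
            breaks.append(1.0 / xb_b)
        T_break = 1.0 / xb
        # slopes: segment at larger 1/T (lower T) is the glass side
        slope_high_invT = coef[2]  # x > xb, i.e. T < T_break
        slope_low_invT = coef[1]   # x <= xb, i.e. T > T_break
        self.crossover_ = CrossoverFit(
            T_break=float(T_break),
            T_break_se=float(np.std(breaks)),
            slope_below=float(slope_high_invT),
            slope_above=float(slope_low_invT),
            p_value=p_value,
            significant=True,
        )
        return self


def _predict_two_segment(x, xb, coef):
    below = x <= xb
    return coef[0] + np.where(below, coef[1] * (x - xb), coef[2] * (x - xb))


def detect_crossover(T, tau, tg_hint: float | None = None, seed: int = 0,
                     n_boot: int = 200) -> CrossoverFit | None:
    """Two-segment Arrhenius fit of β relaxation times across Tg.

    Returns ``None`` when no statistically significant slope change is
    found (F-test at the 5% level).
    """
    det = CrossoverDetector(tg_hint=tg_hint, seed=seed, n_boot=n_boot)
    det.fit(T, tau)
    return det.crossover_
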