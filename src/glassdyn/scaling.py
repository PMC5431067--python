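"""Thermodynamic (density) scaling of relaxation times.

For "Roskilde-simple" glass formers the relaxation times measured along
arbitrary (T, P) paths collapse onto one master curve when plotted against
the single variable T·v^γ, with a material-specific exponent γ.  Here the
scaling variable is used in the form

    x = 1000 / (T · v^γ),        T in K, v in cm³/g,

so that Log τ is an increasing function of x (larger x = colder/denser).

Three independent estimators of γ are provided:

* ``gamma_master_curve`` — minimise the pooled residual of a single
  monotone cubic-spline master curve over a grid of candidate γ;
* ``gamma_isochronal_slope`` — γ = −slope of ln T vs ln v along isochrones
  (states of equal τ_α, computed from per-isobar VFT fits and the EOS);
* ``gamma_thermodynamic`` — closed-form estimate from static quantities
  measured across the glass transition at ambient pressure,
  γ = [ΔC_P·κ_T/(Δα_P·V_g) − α_P·Tg]⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator

from .eos import TaitParams, specific_volume
from .relaxation import TAU_GLASS, VFTParams

__all__ = [
    "ThermoQuantities",
    "ScalingResult",
    "scaling_variable",
    "MasterCurveScaler",
    "gamma_master_curve",
    "gamma_isochronal_slope",
    "gamma_thermodynamic",
]


@dataclass(frozen=True)
class ThermoQuantities:
    """Static thermodynamic quantities at the ambient-pressure glass transition.

    Units: α_P and Δα_P in K⁻¹, ΔC_P in J mol⁻¹ K⁻¹, κ_T in MPa⁻¹,
    V_g in cm³ mol⁻¹, Tg in K.  With these units ΔC_P·κ_T/(Δα_P·V_g) is
    dimensionless because MPa·cm³ = J.
    """

    alpha_P: float
    d_alpha_P: float
    d_Cp: float
    kappa_T: float
    V_g: float
    Tg: float

    def __post_init__(self) -> None:
        for name in ("alpha_P", "d_alpha_P", "d_Cp", "kappa_T", "V_g", "Tg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ScalingResult:
    """γ estimate with its provenance and collapse diagnostics."""

    gamma: float
    se: float
    method: str
    dispersion: float = 0.0
    master_curve: Callable[[np.ndarray], np.ndarray] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def scaling_variable(T, v, gamma) -> np.ndarray:
    """x = 1000/(T·v^γ) with T in K and v in cm³/g."""
    T = np.asarray(T, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(T <= 0) or np.any(v <= 0):
        raise ValueError("T and v must be positive")
    x = 1000.0 / (T * v ** gamma)
    return x if x.ndim else float(x)


def _monotone_spline(x, y, n_knots: int = 6):
    """Monotone-increasing cubic regression spline (I-spline construction).

    The curve is an intercept plus a non-negative combination of the
    antiderivatives of a clamped cubic B-spline basis, so monotonicity is
    enforced by construction.  Returns (rss, callable).
    """
    xmin, xmax = float(np.min(x)), float(np.max(x))
    if xmax - xmin <= 0:
        raise ValueError("degenerate x range for the master curve")
    knots = np.linspace(xmin, xmax, n_knots)
    t = np.r_[[xmin] * 3, knots, [xmax] * 3]
    n_basis = len(t) - 4
    bases = []
    for j in range(n_basis):
        cj = np.zeros(n_basis)
        cj[j] = 1.0
        bases.append(BSpline(t, cj, 3, extrapolate=False).antiderivative())
    A = np.empty((x.size, n_basis + 1))
    A[:, 0] = 1.0
    xc = np.clip(x, xmin, xmax)
    for j, I in enumerate(bases):
        A[:, j + 1] = I(xc) - I(xmin)
    res = optimize.lsq_linear(A, y, bounds=(np.r_[-np.inf, np.zeros(n_basis)],
                                            np.full(n_basis + 1, np.inf)))
    coef = res.x
    rss = float(np.sum((A @ coef - y) ** 2))

    def curve(xq):
        xq = np.clip(np.asarray(xq, dtype=float), xmin, xmax)
        out = np.full(xq.shape, coef[0])
        for j, I in enumerate(bases):
            out = out + coef[j + 1] * (I(xq) - I(xmin))
        return out

    return rss, curve


class MasterCurveScaler(BaseEstimator):
    """Estimate γ by collapsing Log τ onto one monotone master curve.

    ``fit(X, y)`` takes ``X`` with columns (T, v) — temperature and
    specific volume of each state point — and ``y`` = log₁₀ τ.  For each
    candidate γ a single monotone cubic spline in x = 1000/(T·v^γ) is
    fitted to the pooled points; the reported γ minimises the pooled RSS
    (coarse grid then golden-section refinement to 0.01).

    Fitted attributes: ``gamma_``, ``se_``, ``dispersion_`` (RMS residual
    at the optimum, decades), ``master_curve_``, ``profile_`` (γ grid, RSS).
    """

    def __init__(self, gamma_min: float = 0.5, gamma_max: float = 8.0,
                 gamma_step: float = 0.1, n_knots: int = 6):
        self.gamma_min = gamma_min
        self.gamma_max = gamma_max
        self.gamma_step = gamma_step
        self.n_knots = n_knots

    def _rss(self, gamma, T, v, y):
        x = scaling_variable(T, v, gamma)
        rss, _ = _monotone_spline(x, y, self.n_knots)
        return rss

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        T, v = X[:, 0], X[:, 1]
        y = np.asarray(y, dtype=float).ravel()
        if T.size < self.n_knots + 4:
            raise ValueError("too few points for a master-curve fit")

        grid = np.arange(self.gamma_min, self.gamma_max + 1e-9, self.gamma_step)
        rss_grid = np.array([self._rss(g, T, v, y) for g in grid])
        i0 = int(np.argmin(rss_grid))
        lo = grid[max(i0 - 1, 0)]
        hi = grid[min(i0 + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            self._rss, args=(T, v, y), bounds=(lo, hi), method="bounded",
            options={"xatol": 0.01})
        gamma_opt = float(res.x)
        rss_min = float(res.fun)

        x = scaling_variable(T, v, gamma_opt)
        _, curve = _monotone_spline(x, y, self.n_knots)

        # uncertainty: profile half-width where RSS <= 1.05 * min, plus a
        # curvature-based SE from the coarse grid
        thresh = max(rss_min * 1.05, rss_min + 1e-12)
        inside = grid[rss_grid <= thresh]
        half_width = 0.5 * (inside.max() - inside.min()) if inside.size > 1 else \
            self.gamma_step / 2.0
        dof = max(T.size - (self.n_knots + 3), 1)
        sigma2 = rss_min / dof
        d2 = np.gradient(np.gradient(rss_grid, grid), grid)[i0]
        se_curv = float(np.sqrt(2.0 * sigma2 / d2)) if d2 > 0 else np.inf
        self.gamma_ = gamma_opt
        self.se_ = float(max(half_width, 0.0)) if np.isfinite(half_width) else se_curv
        self.se_curvature_ = se_curv
        self.dispersion_ = float(np.sqrt(rss_min / T.size))
        self.master_curve_ = curve
        self.profile_ = (grid, rss_grid)
        return self


def _paths_check(T, P):
    if np.unique(np.round(P, 3)).size < 2 or np.unique(np.round(T, 3)).size < 2:
        raise ValueError(
            "gamma is unidentifiable from a single thermodynamic path: "
            "supply at least two distinct isobars/isotherms")


def gamma_master_curve(points: pd.DataFrame, tait: TaitParams,
                       gamma_grid: tuple[float, float, float] = (0.5, 8.0, 0.1),
                       tau_max: float = TAU_GLASS,
                       process: str | None = "alpha") -> ScalingResult:
    """Master-curve γ from a relaxation map and a fitted EOS.

    ``points`` needs columns T_K, P_MPa, tau_s (and ``process`` if a
    process filter is requested).  Only supercooled-liquid points
    (τ ≤ ``tau_max``) enter the objective.
    """
    df = points
    if process is not None and "process" in df.columns:
        df = df[df["process"] == process]
    df = df[df["tau_s"] <= tau_max]
    T = df["T_K"].to_numpy(float)
    P = df["P_MPa"].to_numpy(float)
    tau = df["tau_s"].to_numpy(float)
    _paths_check(T, P)
    v = specific_volume(tait, T, P)
    scaler = MasterCurveScaler(gamma_min=gamma_grid[0], gamma_max=gamma_grid[1],
                               gamma_step=gamma_grid[2])
    scaler.fit(np.column_stack([T, v]), np.log10(tau))
    return ScalingResult(
        gamma=scaler.gamma_, se=scaler.se_, method="master_curve",
        dispersion=scaler.dispersion_, master_curve=scaler.master_curve_,
        extra={"profile_gamma": scaler.profile_[0],
               "profile_rss": scaler.profile_[1],
               "n_points": int(T.size)})


def collapse_dispersion(points: pd.DataFrame, tait: TaitParams, gamma: float,
                        tau_max: float | None = None,
                        process: str | None = None, n_knots: int = 6) -> float:
    """RMS deviation (decades) of pooled points from their own monotone
    master spline at a *fixed* γ.

    Used to assess whether a process collapses at the exponent optimised on
    another process (e.g. the β process at the α-optimal γ), and to show
    that density-insensitive processes do not collapse at any γ.
    """
    df = points
    if process is not None and "process" in df.columns:
        df = df[df["process"] == process]
    if tau_max is not None:
        df = df[df["tau_s"] <= tau_max]
    T = df["T_K"].to_numpy(float)
    v = specific_volume(tait, T, df["P_MPa"].to_numpy(float))
    x = scaling_variable(T, v, gamma)
    rss, _ = _monotone_spline(x, np.log10(df["tau_s"].to_numpy(float)), n_knots)
    return float(np.sqrt(rss / T.size))


DEFAULT_ISOCHRONES = (1e-6, 1e-4, 1e-2, 1.0, 100.0)


def gamma_isochronal_slope(isobar_fits: list[tuple[float, VFTParams]],
                           tait: TaitParams,
                           tau_list=DEFAULT_ISOCHRONES) -> ScalingResult:
    """γ from the slope of ln T vs ln v under isochronal conditions.

    For each isochrone τ the temperature T_τ(P) follows from inverting the
    per-isobar VFT fit and v_τ(P) from the EOS; γ = −slope of the straight
    line through (ln v, ln T) across isobars.  The mean over isochrones is
    returned with the standard deviation as uncertainty.
    """
    if len(isobar_fits) < 3:
        raise ValueError("need at least 3 isobars")
    slopes = []
    used = []
    for tau in tau_list:
        lnT, lnv = [], []
        ok = True
        for P, vft in isobar_fits:
            if tau <= vft.tau_inf:
                ok = False
                break
            T_tau = vft.T_VF * (1.0 + vft.s / np.log(tau / vft.tau_inf))
            lnT.append(np.log(T_tau))
            lnv.append(np.log(specific_volume(tait, T_tau, P)))
        if not ok:
            import warnings
            warnings.warn(f"isochrone tau={tau:g} s outside VFT range; skipped")
            continue
        slope = np.polyfit(lnv, lnT, 1)[0]
        slopes.append(-slope)
        used.append(tau)
    if not slopes:
        raise ValueError("no usable isochrone")
    slopes = np.asarray(slopes)
    return ScalingResult(
        gamma=float(np.mean(slopes)),
        se=float(np.std(slopes, ddof=1)) if slopes.size > 1 else 0.0,
        method="isochronal_slope",
        extra={"tau_list": list(used), "slopes": slopes.tolist()})


def gamma_thermodynamic(tq: ThermoQuantities,
                        uncertainties: dict[str, float] | None = None
                        ) -> ScalingResult:
    """Closed-form γ from static quantities across the glass transition.

    γ = [ΔC_P·κ_T/(Δα_P·V_g) − α_P·Tg]⁻¹ — dimensionless because
    MPa·cm³ = J.  If ``uncertainties`` maps field names to 1σ errors, the
    uncertainty on γ is propagated to first order.
    """
    denom = tq.d_Cp * tq.kappa_T / (tq.d_alpha_P * tq.V_g) - tq.alpha_P * tq.Tg
    if denom <= 0:
        raise ValueError(
            f"non-positive denominator ({denom:.4g}) in the thermodynamic "
            "gamma relation; inputs are inconsistent")
    gamma = 1.0 / denom
    se = 0.0
    if uncertainties:
        # first-order propagation through the two denominator terms
        ratio = tq.d_Cp * tq.kappa_T / (tq.d_alpha_P * tq.V_g)
        var = 0.0
        for name, frac_deriv in (
            ("d_Cp", ratio / tq.d_Cp), ("kappa_T", ratio / tq.kappa_T),
            ("d_alpha_P", -ratio / tq.d_alpha_P), ("V_g", -ratio / tq.V_g),
            ("alpha_P", -tq.Tg), ("Tg", -tq.alpha_P),
        ):
            var += (frac_deriv * uncertainties.get(name, 0.0)) ** 2
        se = gamma ** 2 * np.sqrt(var)
    return ScalingResult(gamma=float(gamma), se=float(se),
                         method="thermodynamic")
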