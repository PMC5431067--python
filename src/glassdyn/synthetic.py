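"""Seeded generator of ternidazole-like synthetic datasets with ground truth.

The generator emulates a combined dielectric-spectroscopy + PVT study of an
amorphous glass former: four isobars (ambient, 0.2, 0.4, 0.6 GPa) and four
isotherms (260, 280, 300, 320 K) of loss spectra containing three
relaxation processes plus dc conductivity, and a PVT table obeying a Tait
equation of state.

Construction of the ground truth:

* the α relaxation is *exactly* thermodynamically scaling-consistent: at
  every state point Log τ_α = F(1000/(T·v^γ_true)) where F is defined by
  the ambient-pressure VFT law (τ∞ = 10⁻¹⁴ s, s = 10.62, T_VF = 180 K,
  hence Tg = 231.9 K and m = 71.5 at ambient pressure) mapped through the
  Tait EOS;
* the Johari-Goldstein β process follows the Coupling-Model relation
  τ_β = t_c^(1−β_KWW)·τ_α^(β_KWW) in the liquid, with β_KWW decreasing
  linearly in Log τ_α from 0.95 (fast) to 0.60 at τ_α = 100 s; below
  Tg(P) it continues as an Arrhenius line with a reduced slope, producing
  the characteristic kink at the glass transition;
* the γ process is an intramolecular Arrhenius relaxation with a very
  small activation volume, hence essentially density-insensitive — it
  deliberately violates the Tv^γ scaling.

Secondary amplitudes are 10% (β) and 5% (γ) of the α strength; the
spectral noise model is multiplicative log-normal on ε″ (2% default) and
relaxation-map times carry 0.02-decade log-normal noise.  Regeneration
with the same seed is bit-identical; changing the seed changes only the
noise, never the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .eos import TaitParams, specific_volume
from .models import (
    ProcessComponent,
    ProcessKind,
    R_GAS,
    SpectrumModel,
    eval_spectrum,
    shape_from_beta_kww,
)
from .relaxation import TAU_GLASS, VFTParams, eval_vft
from .scaling import ThermoQuantities, scaling_variable
from .spectral import SpectrumRecord

__all__ = [
    "GroundTruth",
    "MeasurementGrid",
    "SyntheticDataset",
    "default_tdz_config",
    "default_thermo_quantities",
    "generate_dataset",
    "generate_pvt",
]


@dataclass(frozen=True)
class MeasurementGrid:
    """Isobar/isotherm sampling plan (pressures in MPa, temperatures in K)."""

    isobars_MPa: tuple[float, ...] = (0.1, 200.0, 400.0, 600.0)
    isotherms_K: tuple[float, ...] = (260.0, 280.0, 300.0, 320.0)
    T_below_tg: float = 28.0
    T_above_tg: float = 32.0
    T_step: float = 2.0
    n_isotherm_points: int = 15
    P_beyond_pg: float = 28.0


@dataclass(frozen=True)
class GroundTruth:
    """Complete ground-truth configuration of a synthetic dataset."""

    seed: int = 42
    gamma_true: float = 2.0
    tait: TaitParams = field(default_factory=lambda: TaitParams(
        v0=0.80, alpha_v=7e-4, T0=300.0, k=0.0894, b1=800.0, b3=4.5e-3))
    vft_ambient: VFTParams = field(default_factory=lambda: VFTParams(
        tau_inf=1e-14, s=10.62, T_VF=180.0))
    t_c: float = 2e-12
    # β_KWW schedule: linear in Log τ_α, clipped to [kww_at_tg, kww_fast]
    kww_at_tg: float = 0.60
    kww_fast: float = 0.95
    kww_slope_per_decade: float = 0.35 / 12.0
    # β process in the glass: Arrhenius slope relative to the liquid side
    glass_slope_ratio: float = 0.55
    # γ (intramolecular) process: Arrhenius with tiny activation volume
    gamma_tau0: float = 3e-18
    gamma_Ea: float = 42000.0       # J/mol
    gamma_Va: float = 1.5           # cm³/mol
    # dielectric strength / conductivity schedules
    deps_alpha_K: float = 2500.0    # Δε_α = deps_alpha_K / T
    beta_amp_frac: float = 0.10
    gamma_amp_frac: float = 0.05
    cc_shape_beta: float = 0.50
    cc_shape_gamma: float = 0.55
    eps_inf: float = 3.0
    sigma_dc_coeff: float = 1e-12   # S/m · s; σ_dc = coeff / τ_α
    # noise levels
    spectrum_noise: float = 0.02    # multiplicative log-normal on ε″
    tau_log_noise: float = 0.02     # decades, on relaxation-map times

    # --- thermodynamic state helpers -------------------------------------
    def x_of(self, T, P):
        """Scaling variable 1000/(T·v^γ_true) at a state point."""
        v = specific_volume(self.tait, T, P)
        return scaling_variable(T, v, self.gamma_true)

    #: temperature window over which the ambient isobar anchors the master
    #: curve; outside it F(x) is continued linearly in x.
    _T_FLOOR_OFFSET = 0.5
    _T_CEIL = 1500.0

    def _T_ambient_of_x(self, x: float) -> float:
        """Invert x(T, P=0) for T; defines the master-curve abscissa map."""
        lo = self.vft_ambient.T_VF + self._T_FLOOR_OFFSET

        def g(T):
            return self.x_of(T, 0.0) - x

        return brentq(g, lo, self._T_CEIL, xtol=1e-10)

    def _master_log_tau_scalar(self, xi: float) -> float:
        T_floor = self.vft_ambient.T_VF + self._T_FLOOR_OFFSET
        x_hi = self.x_of(T_floor, 0.0)
        x_lo = self.x_of(self._T_CEIL, 0.0)

        def F_in_range(x):
            T_amb = self._T_ambient_of_x(x)
            vft = self.vft_ambient
            return float(np.log10(vft.tau_inf)
                         + vft.s * vft.T_VF / ((T_amb - vft.T_VF) * np.log(10.0)))

        if x_lo <= xi <= x_hi:
            return F_in_range(xi)
        # linear continuation beyond the ambient anchor range (deep-glass /
        # very hot extrapolation states; τ_α there is far outside 100 s)
        if xi > x_hi:
            x0, dx = x_hi, 1e-4 * (x_hi - x_lo)
            slope = (F_in_range(x0) - F_in_range(x0 - dx)) / dx
        else:
            x0, dx = x_lo, 1e-4 * (x_hi - x_lo)
            slope = (F_in_range(x0 + dx) - F_in_range(x0)) / dx
        return F_in_range(x0) + slope * (xi - x0)

    def master_log_tau(self, x) -> np.ndarray:
        """Master curve F(x) = Log₁₀ τ_α, anchored on the ambient VFT law."""
        xs = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.array([self._master_log_tau_scalar(xi) for xi in xs])
        return out if np.ndim(x) else float(out[0])

    def log_tau_alpha(self, T, P) -> float:
        """Log₁₀ τ_α(T, P); exactly scaling-consistent by construction."""
        return self.master_log_tau(self.x_of(T, P))

    def tg_of_pressure(self, P: float) -> float:
        """Tg(P): temperature where τ_α = 100 s on the isobar."""
        lo = self.vft_ambient.T_VF + 2.0

        def g(T):
            return self.log_tau_alpha(T, P) - np.log10(TAU_GLASS)

        return brentq(g, lo, 800.0, xtol=1e-8)

    def pg_of_temperature(self, T: float) -> float:
        """Pg(T) in MPa: pressure where τ_α = 100 s on the isotherm."""

        def g(P):
            return self.log_tau_alpha(T, P) - np.log10(TAU_GLASS)

        if g(0.0) >= 0:
            raise ValueError(f"already glassy at ambient pressure for T={T} K")
        return brentq(g, 0.0, 3000.0, xtol=1e-6)

    # --- process schedules ------------------------------------------------
    def beta_kww(self, log_tau_alpha) -> np.ndarray:
        """β_KWW schedule: linear in Log τ_α, 0.95 (fast) → 0.60 at 100 s."""
        lt = np.asarray(log_tau_alpha, dtype=float)
        beta = self.kww_at_tg + self.kww_slope_per_decade * (2.0 - lt)
        return np.clip(beta, self.kww_at_tg, self.kww_fast)

    def log_tau_beta(self, T: float, P: float) -> float:
        """Log₁₀ τ_β: Coupling Model in the liquid, kinked Arrhenius in glass."""
        Tg = self.tg_of_pressure(P)
        if T >= Tg:
            return self._log_tau_beta_liquid(T, P)
        # glass branch: Arrhenius continuation from Tg with reduced slope
        lt_g = self._log_tau_beta_liquid(Tg, P)
        dT = 0.5
        slope_liq = ((self._log_tau_beta_liquid(Tg, P)
                      - self._log_tau_beta_liquid(Tg + dT, P))
                     / (1.0 / Tg - 1.0 / (Tg + dT)))  # d Log τ / d(1/T), K
        return lt_g + self.glass_slope_ratio * slope_liq * (1.0 / T - 1.0 / Tg)

    def _log_tau_beta_liquid(self, T: float, P: float) -> float:
        lt_a = self.log_tau_alpha(T, P)
        beta = float(self.beta_kww(lt_a))
        return (1.0 - beta) * np.log10(self.t_c) + beta * lt_a

    def log_tau_gamma(self, T, P) -> np.ndarray:
        """Log₁₀ τ_γ: T-activated, nearly pressure-independent."""
        T = np.asarray(T, dtype=float)
        P = np.asarray(P, dtype=float)
        lt = (np.log10(self.gamma_tau0)
              + (self.gamma_Ea + P * self.gamma_Va) / (np.log(10.0) * R_GAS * T))
        return lt if lt.ndim else float(lt)

    # --- spectra ----------------------------------------------------------
    def spectrum_model(self, T: float, P: float,
                      include_alpha: bool | None = None) -> SpectrumModel:
        """True spectral model at a state point.

        ``include_alpha=None`` includes the α component whenever
        τ_α ≤ 10³ s (its wing is still visible near Tg).
        """
        lt_a = self.log_tau_alpha(T, P)
        deps_a = self.deps_alpha_K / T
        comps = []
        if include_alpha is None:
            include_alpha = lt_a <= 3.0
        if include_alpha:
            d = shape_from_beta_kww(float(self.beta_kww(lt_a)))
            comps.append(ProcessComponent(ProcessKind.COLE_DAVIDSON,
                                          deps_a, 10.0 ** lt_a, d))
        comps.append(ProcessComponent(
            ProcessKind.COLE_COLE, self.beta_amp_frac * deps_a,
            10.0 ** self.log_tau_beta(T, P), self.cc_shape_beta))
        comps.append(ProcessComponent(
            ProcessKind.COLE_COLE, self.gamma_amp_frac * deps_a,
            10.0 ** float(self.log_tau_gamma(T, P)), self.cc_shape_gamma))
        sigma_dc = self.sigma_dc_coeff / 10.0 ** lt_a
        return SpectrumModel(eps_inf=self.eps_inf, sigma_dc=sigma_dc,
                             components=comps)


@dataclass
class SyntheticDataset:
    """Spectra + PVT + relaxation map with full ground truth attached."""

    spectra: list[SpectrumRecord]
    spectra_truth: list[SpectrumModel]
    relaxation_map: pd.DataFrame
    pvt: pd.DataFrame
    truth: GroundTruth
    grid: MeasurementGrid


def default_tdz_config(seed: int = 42, **overrides) -> GroundTruth:
    """Frozen default configuration of the ternidazole-like fixture.

    Its ambient-pressure VFT analysis yields Tg ≈ 232 K and m ≈ 72, the
    260 K isotherm vitrifies near 0.3 GPa, and γ_true = 2.0.
    """
    return replace(GroundTruth(seed=seed), **overrides)


def default_thermo_quantities() -> ThermoQuantities:
    """Static thermodynamic quantities of ternidazole at ambient pressure.

    Literature calorimetric/volumetric values: α_P = 6.99·10⁻⁴ K⁻¹,
    Δα_P = 4.33·10⁻⁴ K⁻¹, ΔC_P = 101.6 J mol⁻¹ K⁻¹,
    κ_T = 3.90·10⁻⁴ MPa⁻¹, V_g = 138 cm³ mol⁻¹, Tg = 231.9 K.
    """
    return ThermoQuantities(alpha_P=6.99e-4, d_alpha_P=4.33e-4, d_Cp=101.6,
                            kappa_T=3.90e-4, V_g=138.0, Tg=231.9)


def _check_eos_validity(truth: GroundTruth, T: float, P: float) -> None:
    v = specific_volume(truth.tait, T, P)
    if not (0.1 < v < 10.0) or T <= truth.vft_ambient.T_VF:
        raise ValueError(
            f"state (T={T} K, P={P} MPa) outside the EOS validity window")


def _state_points(truth: GroundTruth, grid: MeasurementGrid):
    """(T, P, path) tuples of the sampling plan."""
    states = []
    for P in grid.isobars_MPa:
        Tg = truth.tg_of_pressure(P)
        T_lo = Tg - grid.T_below_tg
        n = int(np.floor((grid.T_below_tg + grid.T_above_tg) / grid.T_step)) + 1
        for i in range(n):
            T = T_lo + i * grid.T_step
            _check_eos_validity(truth, T, P)
            states.append((float(T), float(P), f"isobar_{P:g}MPa"))
    for T in grid.isotherms_K:
        Pg = truth.pg_of_temperature(T)
        Ps = np.linspace(0.1, Pg + grid.P_beyond_pg, grid.n_isotherm_points)
        for P in Ps:
            _check_eos_validity(truth, T, P)
            states.append((float(T), float(P), f"isotherm_{T:g}K"))
    return states


def _spectrum_window(path: str) -> tuple[float, float]:
    # high-frequency reflectometry channel only at ambient pressure
    if path.startswith("isobar_0"):
        return 1e-2, 1e9
    return 1e-2, 1e7


def generate_dataset(config: GroundTruth | None = None,
                     grid: MeasurementGrid | None = None,
                     include_spectra: bool = True,
                     points_per_decade: int = 8) -> SyntheticDataset:
    """Generate the full synthetic dataset for one configuration.

    The relaxation map covers every state point of the grid (α rows only
    where τ_α ≤ 100 s, i.e. in the equilibrium liquid); loss spectra are
    produced for states whose α peak lies inside the measurable frequency
    window.  All randomness derives from ``config.seed``.
    """
    truth = config or default_tdz_config()
    grid = grid or MeasurementGrid()
    rng = np.random.default_rng(truth.seed)
    states = _state_points(truth, grid)

    rows = []
    for T, P, path in states:
        lt_a = truth.log_tau_alpha(T, P)
        procs = []
        if lt_a <= np.log10(TAU_GLASS):
            beta_kww = float(truth.beta_kww(lt_a))
            procs.append(("alpha", lt_a, shape_from_beta_kww(beta_kww), beta_kww))
        procs.append(("beta", truth.log_tau_beta(T, P),
                      truth.cc_shape_beta, np.nan))
        procs.append(("gamma", float(truth.log_tau_gamma(T, P)),
                      truth.cc_shape_gamma, np.nan))
        for name, lt, shape, beta_kww in procs:
            lt_noisy = lt + truth.tau_log_noise * rng.standard_normal()
            rows.append({
                "process": name, "T_K": T, "P_MPa": P,
                "tau_s": 10.0 ** lt_noisy, "shape": shape,
                "beta_kww": beta_kww,
                "delta_eps": truth.deps_alpha_K / T, "path": path,
            })
    relaxation_map = pd.DataFrame(rows)

    pvt = generate_pvt(truth.tait, noise=1e-3, rng=rng)

    spectra: list[SpectrumRecord] = []
    spectra_truth: list[SpectrumModel] = []
    if include_spectra:
        for T, P, path in states:
            f_lo, f_hi = _spectrum_window(path)
            lt_a = truth.log_tau_alpha(T, P)
            f_peak = 1.0 / (2.0 * np.pi * 10.0 ** lt_a)
            if not (3.0 * f_lo <= f_peak <= f_hi / 10.0):
                continue
            n_f = int(np.round(np.log10(f_hi / f_lo) * points_per_decade)) + 1
            f = np.geomspace(f_lo, f_hi, n_f)
            model = truth.spectrum_model(T, P)
            eps1, eps2 = eval_spectrum(model, f)
            if truth.spectrum_noise > 0:
                eps2 = eps2 * np.exp(
                    truth.spectrum_noise * rng.standard_normal(eps2.shape))
            spectra.append(SpectrumRecord(T=T, P=P, f=f, eps2=eps2, eps1=eps1))
            spectra_truth.append(model)

    return SyntheticDataset(spectra=spectra, spectra_truth=spectra_truth,
                            relaxation_map=relaxation_map, pvt=pvt,
                            truth=truth, grid=grid)


def generate_pvt(tait: TaitParams,
                 isotherms=(303.2, 325.2, 346.2, 356.2, 368.2),
                 pressures=None, noise: float = 1e-3,
                 rng: np.random.Generator | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """PVT table from exact Tait evaluations plus relative Gaussian noise."""
    if pressures is None:
        pressures = np.linspace(0.1, 300.0, 10)
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for T in isotherms:
        for P in np.asarray(pressures, dtype=float):
            v = specific_volume(tait, T, P)
            if noise > 0:
                v = v * (1.0 + noise * rng.standard_normal())
            rows.append({"T_K": float(T), "P_MPa": float(P), "v_cm3g": float(v)})
    return pd.DataFrame(rows)
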