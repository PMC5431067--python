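"""Closed-form dielectric relaxation models.

Broadband dielectric loss spectra of molecular glass formers are commonly
decomposed into a dc-conductivity background plus a small number of
relaxation processes.  The asymmetrically broadened primary (α) relaxation
is described by the Cole-Davidson function,

    ε(f) = ε∞ + Δε / (1 + i 2π f τ)^d,        0 < d ≤ 1,

while symmetric secondary processes (β, γ) use the Cole-Cole function,

    ε(f) = ε∞ + Δε / [1 + (i 2π f τ)^c],      0 < c ≤ 1.

The dc conductivity contributes σ_dc/(ε₀ 2π f) to the imaginary part only.
Both functions reduce to the Debye function for a shape exponent of 1.

This module also carries the two frequency/time-domain bridges used in the
analysis of secondary relaxations: the Alvarez-Alegría-Colmenero conversion
between the Cole-Davidson exponent and the Kohlrausch stretched exponent,
β_KWW = d^(1/1.23), and the Coupling-Model prediction for the primitive
(Johari-Goldstein precursor) relaxation time,
τ_CM = t_c^(1-β_KWW) · τ_α^(β_KWW) with t_c ≈ 2 ps.

Units convention used package-wide: T in K, P in MPa, f in Hz, τ in s,
specific volume in cm³/g, molar (activation) volume in cm³/mol.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPS0",
    "R_GAS",
    "ProcessKind",
    "ProcessComponent",
    "SpectrumModel",
    "CMParams",
    "eval_cole_davidson",
    "eval_cole_cole",
    "eval_dc_loss",
    "eval_spectrum",
    "beta_kww_from_shape",
    "shape_from_beta_kww",
    "coupling_model_time",
]

#: Vacuum permittivity, F/m.
EPS0 = 8.854e-12
#: Molar gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314


class ProcessKind(str, enum.Enum):
    """Lineshape family of a relaxation process."""

    COLE_DAVIDSON = "cole_davidson"
    COLE_COLE = "cole_cole"


def _check_shape(shape: float, name: str = "shape") -> float:
    shape = float(shape)
    if not 0.0 < shape <= 1.0:
        raise ValueError(f"{name} must lie in (0, 1], got {shape}")
    return shape


def _check_positive(value: float, name: str) -> float:
    value = float(value)
    if not value > 0.0:
        raise ValueError(f"{name} must be positive, got {value}")
    return value


def _check_freq(f):
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0.0) or not np.all(np.isfinite(f)):
        raise ValueError("frequencies must be positive and finite")
    return f


@dataclass(frozen=True)
class ProcessComponent:
    """One relaxation process: lineshape family, strength, time, exponent."""

    kind: ProcessKind
    delta_eps: float
    tau: float
    shape: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ProcessKind(self.kind))
        _check_positive(self.delta_eps, "delta_eps")
        _check_positive(self.tau, "tau")
        _check_shape(self.shape)

    def eval(self, f) -> np.ndarray:
        """Complex permittivity contribution of this process (ε∞ excluded)."""
        if self.kind is ProcessKind.COLE_DAVIDSON:
            return eval_cole_davidson(self.delta_eps, self.tau, self.shape, 0.0, f)
        return eval_cole_cole(self.delta_eps, self.tau, self.shape, 0.0, f)


@dataclass
class SpectrumModel:
    """Full spectral model: ε∞ + dc conductivity + relaxation components.

    Components are kept sorted by descending τ (slowest first), so for the
    canonical three-process description the order is α, β, γ.
    """

    eps_inf: float = 1.0
    sigma_dc: float = 0.0
    components: list[ProcessComponent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.eps_inf < 1.0:
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.sigma_dc < 0.0:
            raise ValueError("sigma_dc must be >= 0")
        self.components = sorted(self.components, key=lambda c: -c.tau)


@dataclass(frozen=True)
class CMParams:
    """Coupling-Model cross-over time t_c (s); ≈ 2 ps for organic glasses."""

    t_c: float = 2e-12

    def __post_init__(self) -> None:
        _check_positive(self.t_c, "t_c")


def eval_cole_davidson(delta_eps, tau, d, eps_inf, f) -> np.ndarray:
    """Cole-Davidson permittivity ε∞ + Δε/(1 + i2πfτ)^d.

    Complex powers use the principal branch; since Re(1 + i2πfτ) > 0 the
    loss −Im ε is non-negative for all valid parameters.
    """
    f = _check_freq(f)
    _check_positive(tau, "tau")
    _check_positive(delta_eps, "delta_eps")
    _check_shape(d, "d")
    return eps_inf + delta_eps / (1.0 + 2j * np.pi * f * tau) ** d


def eval_cole_cole(delta_eps, tau, c, eps_inf, f) -> np.ndarray:
    """Cole-Cole permittivity ε∞ + Δε/[1 + (i2πfτ)^c].

    The loss peak is symmetric in log f about f₀ = 1/(2πτ) with peak value
    (Δε/2)·tan(πc/4).
    """
    f = _check_freq(f)
    _check_positive(tau, "tau")
    _check_positive(delta_eps, "delta_eps")
    _check_shape(c, "c")
    return eps_inf + delta_eps / (1.0 + (2j * np.pi * f * tau) ** c)


def eval_dc_loss(sigma_dc, f) -> np.ndarray:
    """dc-conductivity loss σ_dc/(ε₀·2πf); slope −1 on log-log axes."""
    f = _check_freq(f)
    sigma_dc = float(sigma_dc)
    if sigma_dc < 0.0:
        raise ValueError("sigma_dc must be >= 0")
    return sigma_dc / (EPS0 * 2.0 * np.pi * f)


def eval_spectrum(model: SpectrumModel, f_grid) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (ε′, ε″) of a SpectrumModel on a frequency grid.

    ε″ is the sum of the dc term and every component's loss; the dc term
    enters the imaginary part only, so ε′ excludes it.
    """
    f = _check_freq(f_grid)
    eps = np.full(f.shape, complex(model.eps_inf), dtype=complex)
    for comp in model.components:
        eps = eps + comp.eval(f)
    eps1 = eps.real
    eps2 = -eps.imag + eval_dc_loss(model.sigma_dc, f)
    return eps1, eps2


#: Exponent of the Alvarez-Alegría-Colmenero relation β_KWW = d^(1/1.23).
_AAC_EXPONENT = 1.23


def beta_kww_from_shape(d: float) -> float:
    """Kohlrausch stretched exponent from the Cole-Davidson exponent.

    β_KWW = d^(1/1.23); monotone increasing, β_KWW(1) = 1.
    """
    d = _check_shape(d, "d")
    return d ** (1.0 / _AAC_EXPONENT)


def shape_from_beta_kww(beta_kww: float) -> float:
    """Inverse of :func:`beta_kww_from_shape`: d = β_KWW^1.23."""
    beta_kww = _check_shape(beta_kww, "beta_kww")
    return beta_kww ** _AAC_EXPONENT


def coupling_model_time(tau_alpha: float, beta_kww: float,
                        cm: CMParams | None = None) -> float:
    """Coupling-Model primitive relaxation time τ_CM = t_c^(1−β)·τ_α^β.

    Computed in the log domain for numerical range safety.  For
    τ_α ≥ t_c the result is bracketed by t_c ≤ τ_CM ≤ τ_α.
    """
    cm = cm or CMParams()
    _check_positive(tau_alpha, "tau_alpha")
    beta_kww = _check_shape(beta_kww, "beta_kww")
    log_tau = (1.0 - beta_kww) * np.log(cm.t_c) + beta_kww * np.log(tau_alpha)
    return float(np.exp(log_tau))
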