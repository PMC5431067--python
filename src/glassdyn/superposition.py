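"""Isochronal lineshape superposition and the generalized Angell plot.

Two diagnostics of dynamic isomorphism:

* *isochronal superposition* — loss spectra measured at different (T, P)
  states that share the same α relaxation time should have identical
  lineshapes once the dc background is removed and the curves are
  normalized to the peak;
* the *generalized Angell plot* — relaxation times of all processes
  plotted against Tg(P)/T collapse for the α (and Johari-Goldstein β)
  process when the dynamics is governed solely by the distance to the
  glass transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import SpectrumModel, eval_dc_loss, eval_spectrum
from .relaxation import AnderssonParams, andersson_tg
from .spectral import SpectrumRecord

__all__ = [
    "NormalizedLineshape",
    "normalize_isochronal",
    "superposition_distance",
    "angell_rescale",
]


@dataclass
class NormalizedLineshape:
    """Peak-normalized, dc-free loss curve on a log-frequency offset axis."""

    offsets: np.ndarray        # log10(f / f_peak)
    norm_loss: np.ndarray      # ε″ / ε″_peak (dc removed)
    T: float
    P: float
    tau_alpha: float


def normalize_isochronal(spec: SpectrumRecord, model: SpectrumModel,
                         edge_margin_decades: float = 0.3) -> NormalizedLineshape:
    """Normalize a measured spectrum for isochronal shape comparison.

    The fitted σ_dc is subtracted from the measured loss (using the fit
    rather than a low-frequency extrapolation avoids double-counting
    overlapping β intensity); the curve is rescaled to unit peak height
    and the log-f axis re-centred on the α loss maximum, located on the
    model curve near 1/(2πτ_α).
    """
    if not model.components:
        raise ValueError("model must contain at least the alpha process")
    tau_alpha = model.components[0].tau
    f_alpha = 1.0 / (2.0 * np.pi * tau_alpha)
    logf_lo, logf_hi = np.log10(spec.f[0]), np.log10(spec.f[-1])
    if not (logf_lo + edge_margin_decades <= np.log10(f_alpha)
            <= logf_hi - edge_margin_decades):
        raise ValueError(
            "alpha peak lies at the edge of the frequency window; "
            "the lineshape is not measurable")

    # locate the peak of the dc-free model curve near the alpha frequency
    f_dense = np.geomspace(f_alpha / 100.0, f_alpha * 100.0, 2001)
    _, eps2_dense = eval_spectrum(model, f_dense)
    eps2_dense = eps2_dense - eval_dc_loss(model.sigma_dc, f_dense)
    i_pk = int(np.argmax(eps2_dense))
    f_peak = float(f_dense[i_pk])
    peak_val = float(eps2_dense[i_pk])

    dc = eval_dc_loss(model.sigma_dc, spec.f)
    loss = spec.eps2 - dc
    # points where the dc background dominates carry amplified subtraction
    # noise, not lineshape information
    good = (loss > 0) & (loss > 0.5 * dc)
    return NormalizedLineshape(
        offsets=np.log10(spec.f[good] / f_peak),
        norm_loss=loss[good] / peak_val,
        T=spec.T, P=spec.P, tau_alpha=tau_alpha)


def superposition_distance(a: NormalizedLineshape, b: NormalizedLineshape,
                           max_shift_decades: float = 0.2,
                           shift_step: float = 0.05,
                           grid_step: float = 0.05,
                           min_overlap_decades: float = 2.0,
                           offset_range: tuple[float, float] = (-3.0, 3.0)
                           ) -> float:
    """Shape distance between two normalized lineshapes.

    Minimum over horizontal shifts |s| ≤ ``max_shift_decades`` of the RMS
    difference of log₁₀(normalized loss) on the common offset grid.
    Symmetric in (a, b) up to floating-point grid rounding; zero iff
    the shapes coincide up to a shift.

    ``offset_range`` limits the comparison to the primary-peak region so
    that distant secondary processes (which need not be isochronal when
    the α times match) do not enter the α-shape comparison.
    """
    shifts = np.arange(-max_shift_decades, max_shift_decades + 1e-12, shift_step)
    best = np.inf
    for s in shifts:
        # the offset-range restriction applies to both curves so the
        # distance is exactly symmetric in (a, b)
        lo = max(a.offsets.min(), b.offsets.min() + s,
                 offset_range[0], offset_range[0] + s)
        hi = min(a.offsets.max(), b.offsets.max() + s,
                 offset_range[1], offset_range[1] + s)
        if hi - lo < min_overlap_decades:
            continue
        # grid aligned to absolute multiples of the step, again for symmetry
        g = np.arange(np.ceil(lo / grid_step) * grid_step, hi + 1e-12,
                      grid_step)
        ya = np.interp(g, a.offsets, np.log10(a.norm_loss))
        yb = np.interp(g - s, b.offsets, np.log10(b.norm_loss))
        rms = float(np.sqrt(np.mean((ya - yb) ** 2)))
        best = min(best, rms)
    if not np.isfinite(best):
        raise ValueError(
            f"less than {min_overlap_decades} decades of overlap between "
            "the lineshapes after any allowed shift")
    return best


def angell_rescale(points: pd.DataFrame, tg_of_p: AnderssonParams) -> pd.DataFrame:
    """Rescale a relaxation map onto the generalized Angell axes.

    Every point gets x = Tg(P)/T with Tg(P) from the Andersson-Andersson
    fit (P converted to GPa).  α points satisfy log₁₀ τ = 2 at x = 1 by
    the τ(Tg) = 100 s convention.  Returns a DataFrame with columns
    process, x, log10_tau, in the input row order.
    """
    P_GPa = points["P_MPa"].to_numpy(float) / 1000.0
    Tg = andersson_tg(tg_of_p, P_GPa)
    out = pd.DataFrame({
        "process": points["process"].to_numpy(),
        "x": Tg / points["T_K"].to_numpy(float),
        "log10_tau": np.log10(points["tau_s"].to_numpy(float)),
    })
    return out
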