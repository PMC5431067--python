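"""Decomposition of dielectric loss spectra into dc + α + β + γ components.

Each measured spectrum (one (T, P) state point) is fitted by least squares
on log₁₀ ε″ so that decade-spanning spectra are not dominated by the
low-frequency dc upturn.  The fit follows a sequential release protocol —
dc + α on the low-frequency window first, then the β process, then γ,
followed by a full joint refinement — which is robust for spectra whose
secondary relaxations are much less intense than the primary peak.

The fitted parameters of many spectra are collected into a *relaxation
map*: one row per process per state point with τ, the shape exponent and
(for the α process) the derived Kohlrausch exponent β_KWW.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter
from sklearn.base import BaseEstimator

from .models import (
    EPS0,
    ProcessComponent,
    ProcessKind,
    SpectrumModel,
    beta_kww_from_shape,
    eval_spectrum,
)

__all__ = [
    "SpectrumRecord",
    "FitResult",
    "SpectrumDecomposer",
    "initial_guess",
    "fit_spectrum",
    "extract_relaxation_map",
    "PROCESS_NAMES",
]

logger = logging.getLogger(__name__)

#: Canonical process labels by descending relaxation time.
PROCESS_NAMES = ("alpha", "beta", "gamma")

#: Loss floor below which points are treated as instrument noise.
LOSS_FLOOR = 1e-3


@dataclass
class SpectrumRecord:
    """One loss spectrum at a (T, P) state point.

    ``f`` must be strictly increasing; ``eps1`` (the real part) is optional
    and only used to seed ε∞.
    """

    T: float
    P: float
    f: np.ndarray
    eps2: np.ndarray
    eps1: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.eps2 = np.asarray(self.eps2, dtype=float)
        if self.f.ndim != 1 or self.f.shape != self.eps2.shape:
            raise ValueError("f and eps2 must be 1-d arrays of equal length")
        if np.any(np.diff(self.f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.eps1 is not None:
            self.eps1 = np.asarray(self.eps1, dtype=float)
            if self.eps1.shape != self.f.shape:
                raise ValueError("eps1 must match the frequency grid")


@dataclass
class FitResult:
    """Converged (or not) spectral fit with per-parameter standard errors."""

    model: SpectrumModel
    stderr: dict[str, float] = field(default_factory=dict)
    residual_norm: float = float("nan")
    converged: bool = False
    degenerate: bool = False
    message: str = ""


def initial_guess(spec: SpectrumRecord, n_processes: int) -> tuple[SpectrumModel, bool]:
    """Heuristic starting model for a spectrum.

    σ_dc is seeded from the low-frequency slope-(−1) region, τ values from
    local maxima of ε″ after dc subtraction (Δε = 2 × peak height, shapes
    start at 0.8).  If fewer maxima than processes are found the remaining τ
    seeds are log-equispaced and the guess is flagged degenerate.

    Returns ``(model, degenerate)``.
    """
    if n_processes not in (1, 2, 3):
        raise ValueError("n_processes must be 1, 2 or 3")
    logf = np.log10(spec.f)
    if logf[-1] - logf[0] < 3.0:
        raise ValueError("frequency grid must span at least 3 decades")
    eps2 = np.clip(spec.eps2, LOSS_FLOOR, None)

    # dc seed.  ε₀·2πf·ε″ ≥ σ_dc everywhere (all loss terms are positive),
    # with near-equality in the slope-(−1) dc-dominated region, so its
    # minimum over the first two decades is a tight upper bound on σ_dc.
    lo_sel = logf <= logf[0] + 2.0
    sigma_bound = float(np.min(EPS0 * 2.0 * np.pi * spec.f[lo_sel] * eps2[lo_sel]))
    n_lo = max(3, int(np.searchsorted(logf, logf[0] + 0.7)))
    slope = np.polyfit(logf[:n_lo], np.log10(eps2[:n_lo]), 1)[0]
    sigma_dc = 0.95 * sigma_bound if slope < -0.8 else 0.5 * sigma_bound

    # peak detection on the dc-free residual; subtract the full bound so a
    # dominant conductivity background cannot bury the loss peaks
    dc_term = sigma_bound / (EPS0 * 2.0 * np.pi * spec.f)
    resid = eps2 - dc_term
    resid = np.clip(resid, LOSS_FLOOR / 10, None)
    log_resid = np.log10(resid)
    if log_resid.size >= 9:
        log_resid = savgol_filter(log_resid, 7, 2)
    # where the spectrum is dc-dominated the subtraction residual is pure
    # noise scaled by the (large) dc term: exclude it from the peak search
    valid = resid > 0.5 * dc_term
    log_resid = np.where(valid, log_resid, np.min(log_resid) - 1.0)
    # require ~1 decade of separation so noise bumps on a peak flank are
    # not counted as extra processes
    step = float(np.median(np.diff(logf)))
    min_dist = max(1, int(np.round(1.0 / step)))
    peaks, props = find_peaks(log_resid, prominence=0.03, distance=min_dist)
    order = np.argsort(props["prominences"])[::-1][:n_processes]
    peaks = np.sort(peaks[order])  # ascending frequency = descending tau

    degenerate = len(peaks) < n_processes
    f_found = list(spec.f[peaks])
    # processes hidden as shoulders leave no local maximum: seed the largest
    # log-frequency gaps between detected peaks (and the window edges)
    while len(f_found) < n_processes:
        nodes = np.log10(np.r_[spec.f[0], np.sort(f_found), spec.f[-1]]) \
            if f_found else np.array([logf[0], logf[-1]])
        gaps = np.diff(nodes)
        i = int(np.argmax(gaps))
        f_found.append(10.0 ** (0.5 * (nodes[i] + nodes[i + 1])))
    taus, amps = [], []
    for fpk in sorted(f_found):
        taus.append(1.0 / (2.0 * np.pi * fpk))
        idx = int(np.argmin(np.abs(np.log10(spec.f) - np.log10(fpk))))
        amps.append(max(2.0 * resid[idx], 10 * LOSS_FLOOR))

    eps_inf = 2.0
    if spec.eps1 is not None:
        eps_inf = max(1.0, float(np.min(spec.eps1)))

    comps = []
    for i, (tau, amp) in enumerate(zip(taus, amps)):
        kind = ProcessKind.COLE_DAVIDSON if i == 0 else ProcessKind.COLE_COLE
        comps.append(ProcessComponent(kind=kind, delta_eps=amp, tau=tau, shape=0.8))
    model = SpectrumModel(eps_inf=eps_inf, sigma_dc=sigma_dc, components=comps)
    return model, degenerate


def _model_to_params(model: SpectrumModel,
                     tau_bounds: tuple[float, float] | None = None
                     ) -> lmfit.Parameters:
    params = lmfit.Parameters()
    # eps_inf does not enter the loss; it is carried, not fitted
    params.add("eps_inf", value=model.eps_inf, min=1.0, max=100.0, vary=False)
    # log-scale parameter for conditioning; sigma_dc == 0 handled via vary
    sig = model.sigma_dc
    params.add("log10_sigma_dc", value=np.log10(sig) if sig > 0 else -20.0,
               min=-25.0, max=2.0, vary=sig > 0)
    lt_lo, lt_hi = tau_bounds if tau_bounds else (-14.0, 6.0)
    for i, comp in enumerate(model.components):
        params.add(f"log10_deps_{i}", value=np.log10(comp.delta_eps),
                   min=-4.0, max=2.0)
        params.add(f"log10_tau_{i}",
                   value=np.clip(np.log10(comp.tau), lt_lo, lt_hi),
                   min=lt_lo, max=lt_hi)
        params.add(f"shape_{i}", value=comp.shape, min=0.05, max=1.0)
    return params


def _params_to_model(params: lmfit.Parameters, kinds: list[ProcessKind]) -> SpectrumModel:
    sig = 10.0 ** params["log10_sigma_dc"].value
    if not params["log10_sigma_dc"].vary and params["log10_sigma_dc"].value <= -19.9:
        sig = 0.0
    comps = []
    for i, kind in enumerate(kinds):
        comps.append(ProcessComponent(
            kind=kind,
            delta_eps=10.0 ** params[f"log10_deps_{i}"].value,
            tau=10.0 ** params[f"log10_tau_{i}"].value,
            shape=params[f"shape_{i}"].value,
        ))
    return SpectrumModel(eps_inf=params["eps_inf"].value, sigma_dc=sig,
                         components=comps)


def _residual(params: lmfit.Parameters, kinds, f, log_eps2) -> np.ndarray:
    model = _params_to_model(params, kinds)
    _, eps2 = eval_spectrum(model, f)
    return np.log10(np.clip(eps2, 1e-12, None)) - log_eps2


class SpectrumDecomposer(BaseEstimator):
    """Least-squares decomposition of one loss spectrum.

    Parameters
    ----------
    n_processes : int
        Number of relaxation processes (1–3).  The slowest is modelled as
        Cole-Davidson, the others as Cole-Cole.
    loss_floor : float
        ε″ points below this value are excluded from the fit.
    sequential : bool
        Use the staged dc+α → +β → +γ protocol before the joint refinement.

    Attributes
    ----------
    model_ : SpectrumModel
        Fitted spectral model (components sorted by descending τ).
    result_ : FitResult
        Fit diagnostics, standard errors and convergence flag.
    """

    def __init__(self, n_processes: int = 3, loss_floor: float = LOSS_FLOOR,
                 sequential: bool = True):
        self.n_processes = n_processes
        self.loss_floor = loss_floor
        self.sequential = sequential

    # --- internal helpers -------------------------------------------------
    def _stage_fit(self, params, kinds, f, log_eps2, window=None):
        if window is not None:
            sel = f <= window
            if sel.sum() < 8:
                sel = slice(None)
        else:
            sel = slice(None)
        mini = lmfit.minimize(_residual, params, args=(kinds, f[sel], log_eps2[sel]),
                              method="least_squares", nan_policy="raise")
        return mini

    def fit(self, X, y=None, guess: SpectrumModel | None = None,
            frozen: dict[str, bool] | None = None):
        """Fit the decomposition.

        ``X`` may be a :class:`SpectrumRecord` or a frequency array (with
        ``y`` the loss).  ``frozen`` maps internal parameter names to
        ``vary`` flags for the final joint fit.
        """
        if isinstance(X, SpectrumRecord):
            spec = X
        else:
            spec = SpectrumRecord(T=np.nan, P=np.nan, f=np.asarray(X, float).ravel(),
                                  eps2=np.asarray(y, float).ravel())
        mask = spec.eps2 >= self.loss_floor
        f = spec.f[mask]
        eps2 = spec.eps2[mask]
        if f.size < 8 * self.n_processes:
            raise ValueError("need at least 8 points per fitted process")
        log_eps2 = np.log10(eps2)

        degenerate = False
        if guess is None:
            guess, degenerate = initial_guess(spec, self.n_processes)
        kinds = [c.kind for c in guess.components]

        # relaxation times may sit at most 2 decades outside the window:
        # anything further is not constrained by the data
        lt_lo = np.log10(1.0 / (2.0 * np.pi * f[-1])) - 2.0
        lt_hi = np.log10(1.0 / (2.0 * np.pi * f[0])) + 2.0
        params = _model_to_params(guess, tau_bounds=(lt_lo, lt_hi))
        # with an explicit parameter mask the caller wants a plain joint
        # refinement from the guess, not the staged release protocol
        use_stages = self.sequential and self.n_processes > 1 and not frozen
        if use_stages:
            # stage 1: dc + alpha only, on the window up to midway between
            # the alpha and beta seed peaks
            taus = [c.tau for c in guess.components]
            for n_active in range(1, self.n_processes + 1):
                for i in range(self.n_processes):
                    active = i < n_active
                    for pname in (f"log10_deps_{i}", f"log10_tau_{i}", f"shape_{i}"):
                        params[pname].set(vary=active)
                if n_active < self.n_processes:
                    f_next = 1.0 / (2.0 * np.pi * taus[n_active])
                    f_cur = 1.0 / (2.0 * np.pi * taus[n_active - 1])
                    window = float(np.sqrt(f_next * f_cur))
                else:
                    window = None
                try:
                    mini = self._stage_fit(params, kinds[:n_active], f, log_eps2,
                                           window=window)
                except Exception as exc:  # pragma: no cover - defensive
                    logger.warning("stage %d fit failed: %s", n_active, exc)
                    continue
                for name in mini.params:
                    if params[name].vary:
                        params[name].set(value=mini.params[name].value)
            for i in range(self.n_processes):
                for pname in (f"log10_deps_{i}", f"log10_tau_{i}", f"shape_{i}"):
                    params[pname].set(vary=True)

        if frozen:
            for name, vary in frozen.items():
                params[name].set(vary=vary)

        mini = lmfit.minimize(_residual, params, args=(kinds, f, log_eps2),
                              method="least_squares", nan_policy="raise")
        if use_stages:
            # the staged protocol can lock into a local minimum when the
            # seed peaks are misassigned; a direct joint fit from the raw
            # guess is a cheap independent restart — keep the better one
            params_direct = _model_to_params(guess, tau_bounds=(lt_lo, lt_hi))
            if frozen:
                for name, vary in frozen.items():
                    params_direct[name].set(vary=vary)
            mini_direct = lmfit.minimize(_residual, params_direct,
                                         args=(kinds, f, log_eps2),
                                         method="least_squares",
                                         nan_policy="raise")
            if mini_direct.chisqr < mini.chisqr:
                mini = mini_direct
        model = _params_to_model(mini.params, kinds)
        stderr = {name: (p.stderr if p.stderr is not None else np.nan)
                  for name, p in mini.params.items() if p.vary}
        converged = bool(mini.success) and np.isfinite(mini.chisqr)
        self.model_ = model
        self.result_ = FitResult(
            model=model,
            stderr=stderr,
            residual_norm=float(np.sqrt(mini.chisqr)),
            converged=converged,
            degenerate=degenerate,
            message=str(mini.message),
        )
        self.n_features_in_ = 1
        return self

    def predict(self, f) -> np.ndarray:
        """Predicted loss ε″ on a frequency grid."""
        _, eps2 = eval_spectrum(self.model_, f)
        return eps2


def fit_spectrum(spec: SpectrumRecord, guess: SpectrumModel | None = None,
                 frozen: dict[str, bool] | None = None,
                 n_processes: int = 3) -> FitResult:
    """Functional wrapper around :class:`SpectrumDecomposer`."""
    if guess is not None:
        n_processes = len(guess.components)
    dec = SpectrumDecomposer(n_processes=n_processes)
    dec.fit(spec, guess=guess, frozen=frozen)
    return dec.result_


def extract_relaxation_map(fits: list[tuple[SpectrumRecord, FitResult]]
                           ) -> pd.DataFrame:
    """Collect fitted spectra into a relaxation map.

    One row per process per converged state point.  Processes are labelled
    alpha/beta/gamma by descending τ; β_KWW is attached to α rows via the
    Alvarez-Alegría-Colmenero conversion.  Unconverged fits are skipped
    with a warning.
    """
    rows = []
    for spec, res in fits:
        if not res.converged:
            warnings.warn(
                f"skipping unconverged fit at T={spec.T} K, P={spec.P} MPa")
            continue
        # keep only components that the data actually resolve: the loss
        # maximum must lie inside the measured window and the strength must
        # be commensurate with the observed loss (a component pinned at a
        # bound is a fit artifact of an unresolvable process)
        f_lo, f_hi = spec.f[0], spec.f[-1]
        eps2_max = float(np.max(spec.eps2))
        comps = []
        for comp in res.model.components:  # sorted by descending tau
            f_peak = 1.0 / (2.0 * np.pi * comp.tau)
            if not f_lo <= f_peak <= f_hi:
                continue
            if comp.delta_eps > 5.0 * eps2_max or comp.delta_eps >= 99.0:
                continue
            comps.append(comp)
        for name, comp in zip(PROCESS_NAMES, comps):
            beta = np.nan
            if name == "alpha" and comp.kind is ProcessKind.COLE_DAVIDSON:
                beta = beta_kww_from_shape(comp.shape)
            rows.append({
                "process": name,
                "T_K": spec.T,
                "P_MPa": spec.P,
                "tau_s": comp.tau,
                "shape": comp.shape,
                "beta_kww": beta,
                "delta_eps": comp.delta_eps,
                "tau_s_stderr": res.stderr.get("log10_tau_0", np.nan),
                "shape_stderr": res.stderr.get("shape_0", np.nan),
            })
    df = pd.DataFrame(rows, columns=["process", "T_K", "P_MPa", "tau_s", "shape",
                                     "beta_kww", "delta_eps", "tau_s_stderr",
                                     "shape_stderr"])
    if len(df):
        df = df.sort_values(["process", "P_MPa", "T_K"]).reset_index(drop=True)
    return df
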