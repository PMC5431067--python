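"""End-to-end orchestration: spectra → relaxation map → fits → scaling.

The pipeline chains the analysis stages in the order an experimentalist
would run them:

1. load (or simulate) loss spectra and PVT data;
2. decompose every spectrum into dc + relaxation components;
3. per-isobar VFT fits → Tg, fragility; Andersson-Andersson Tg(P);
   per-isotherm pressure-Arrhenius fits → V_a, Pg; β-process kink search;
4. Tait EOS fit;
5. thermodynamic-scaling exponent γ by up to three independent methods;
6. isochronal superposition distances and the generalized Angell plot;
7. a summary JSON collecting every stage's headline numbers.

Each stage writes its own output file as soon as it completes, so a
failure in a later stage preserves the partial results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .eos import TaitEOS
from .io import (
    read_pvt,
    read_spectra,
    write_json,
    write_relaxation_map,
)
from .relaxation import (
    TAU_GLASS,
    detect_crossover,
    fit_andersson,
    fit_pressure_arrhenius,
    fit_vft,
    fragility,
    glass_transition_pressure,
    glass_transition_temperature,
)
from .scaling import (
    ThermoQuantities,
    collapse_dispersion,
    gamma_isochronal_slope,
    gamma_master_curve,
    gamma_thermodynamic,
)
from .spectral import SpectrumDecomposer, extract_relaxation_map, initial_guess
from .superposition import normalize_isochronal, superposition_distance
from .superposition import angell_rescale
from .synthetic import default_tdz_config, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Either point ``spectra_path``/``pvt_path`` at CSV inputs or set
    ``simulate=True`` to analyse a freshly generated synthetic dataset.
    """

    outdir: str = "glassdyn_out"
    spectra_path: str | None = None
    pvt_path: str | None = None
    thermo: dict | None = None          # ThermoQuantities fields
    simulate: bool = False
    seed: int = 42
    n_processes: int = 3
    tau_g: float = TAU_GLASS
    gamma_grid: tuple[float, float, float] = (0.5, 8.0, 0.1)
    min_isobar_points: int = 5
    min_isotherm_points: int = 4

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _fit_all_spectra(records, n_processes):
    fits = []
    for spec in records:
        try:
            candidates = []
            for n in range(n_processes, max(n_processes - 2, 0), -1):
                try:
                    dec = SpectrumDecomposer(n_processes=n)
                    dec.fit(spec)
                    candidates.append(dec)
                except Exception:
                    continue
            if not candidates:
                raise RuntimeError("no process count converged")
            # states where two processes merge are not 3-process resolvable;
            # choose the process count by BIC
            npts = spec.f.size

            def bic(dec):
                k = 2 + 3 * len(dec.model_.components)
                chi2 = max(dec.result_.residual_norm ** 2, 1e-300)
                return npts * np.log(chi2 / npts) + k * np.log(npts)

            best = min(candidates, key=bic)
            fits.append((spec, best.result_))
        except Exception as exc:
            logger.warning("spectrum at T=%.4g K, P=%.4g MPa failed: %s",
                           spec.T, spec.P, exc)
    # quality cut: a fit whose per-point log-residual is far above the
    # ensemble median did not describe its spectrum (unresolvable state)
    rms = np.array([res.residual_norm / np.sqrt(spec.f.size)
                    for spec, res in fits])
    if rms.size:
        cut = 3.0 * np.median(rms)
        kept = []
        for (spec, res), r in zip(fits, rms):
            if r > cut:
                logger.warning("discarding poor fit at T=%.4g K, P=%.4g MPa "
                               "(residual %.3g > %.3g)", spec.T, spec.P, r, cut)
            else:
                kept.append((spec, res))
        fits = kept
    return fits


def _isobars(alpha: pd.DataFrame, min_points: int):
    for P, g in alpha.groupby("P_MPa"):
        if g["T_K"].nunique() >= min_points:
            yield float(P), g.sort_values("T_K")


def _isotherms(alpha: pd.DataFrame, min_points: int):
    for T, g in alpha.groupby("T_K"):
        g = g.sort_values("P_MPa")
        if (g["P_MPa"].nunique() >= min_points
                and g["P_MPa"].max() - g["P_MPa"].min() >= 100.0):
            yield float(T), g


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain; returns the summary dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("glassdyn %s | config %s | seed %d",
                __version__, config.config_hash(), config.seed)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config_hash": config.config_hash()}

    stage = "load-inputs"
    try:
        dataset = None
        if config.simulate:
            dataset = generate_dataset(default_tdz_config(seed=config.seed))
            spectra = dataset.spectra
            pvt = dataset.pvt
        else:
            spectra = read_spectra(config.spectra_path) \
                if config.spectra_path else None
            pvt = read_pvt(config.pvt_path) if config.pvt_path else None

        stage = "fit-spectra"
        if spectra is not None:
            fits = _fit_all_spectra(spectra, config.n_processes)
            relax_map = extract_relaxation_map(fits)
        elif dataset is not None:
            fits = []
            relax_map = dataset.relaxation_map
        else:
            raise ValueError("no spectra available (set spectra_path or simulate)")
        write_relaxation_map(relax_map, outdir / "relaxation_map.csv")
        summary["n_map_rows"] = int(len(relax_map))

        stage = "relaxation-fits"
        alpha = relax_map[relax_map["process"] == "alpha"]
        liquid = alpha[alpha["tau_s"] <= config.tau_g]
        isobar_results, isobar_fits = [], []
        for P, g in _isobars(liquid, config.min_isobar_points):
            vft = fit_vft(g["T_K"], g["tau_s"], tau_max=config.tau_g)
            Tg = glass_transition_temperature(vft, config.tau_g)
            isobar_results.append({
                "P_MPa": P, "tau_inf_s": vft.tau_inf, "s": vft.s,
                "T_VF_K": vft.T_VF, "Tg_K": Tg, "m": fragility(vft, Tg)})
            isobar_fits.append((P, vft))
        isotherm_results = []
        for T, g in _isotherms(liquid, config.min_isotherm_points):
            arr = fit_pressure_arrhenius(g["P_MPa"], g["tau_s"], T=T)
            isotherm_results.append({
                "T_K": T, "tau0_s": arr.tau_0, "Va_cm3mol": arr.V_a,
                "Pg_MPa": glass_transition_pressure(arr, T, config.tau_g)})
        andersson = None
        if len(isobar_results) >= 4:
            andersson = fit_andersson(
                [r["P_MPa"] / 1000.0 for r in isobar_results],
                [r["Tg_K"] for r in isobar_results])
        crossovers = []
        beta = relax_map[relax_map["process"] == "beta"]
        for P, g in beta.groupby("P_MPa"):
            if g["T_K"].nunique() < 8:
                continue
            tg_hint = next((r["Tg_K"] for r in isobar_results
                            if r["P_MPa"] == P), None)
            cx = detect_crossover(g["T_K"], g["tau_s"], tg_hint=tg_hint,
                                  seed=config.seed)
            if cx is not None:
                crossovers.append({"P_MPa": float(P), "T_break_K": cx.T_break,
                                   "T_break_se_K": cx.T_break_se})
        relax_report = {
            "isobars": isobar_results, "isotherms": isotherm_results,
            "beta_crossovers": crossovers}
        if andersson is not None:
            relax_report["andersson"] = {"k1_K": andersson.k1,
                                         "k2_perGPa": andersson.k2,
                                         "k3": andersson.k3}
        write_json(relax_report, outdir / "relaxation_fits.json")
        summary["relaxation"] = relax_report

        stage = "eos-fit"
        tait = None
        if pvt is not None:
            eos = TaitEOS().fit(pvt[["T_K", "P_MPa"]].to_numpy(float),
                                pvt["v_cm3g"].to_numpy(float))
            tait = eos.params_
            summary["tait"] = {"v0_cm3g": tait.v0, "alpha_v_perK": tait.alpha_v,
                               "T0_K": tait.T0, "k": tait.k, "b1_MPa": tait.b1,
                               "b3_perK": tait.b3, "rms_cm3g": eos.rms_}

        stage = "scaling"
        gammas = {}
        if tait is not None:
            mc = gamma_master_curve(relax_map, tait,
                                    gamma_grid=config.gamma_grid,
                                    tau_max=config.tau_g)
            gammas["master_curve"] = {"gamma": mc.gamma, "se": mc.se,
                                      "dispersion": mc.dispersion}
            # collapsed coordinates for all processes at the optimal gamma
            from .eos import specific_volume
            from .scaling import scaling_variable
            v = specific_volume(tait, relax_map["T_K"].to_numpy(float),
                                relax_map["P_MPa"].to_numpy(float))
            collapsed = pd.DataFrame({
                "process": relax_map["process"],
                "x": scaling_variable(relax_map["T_K"].to_numpy(float), v,
                                      mc.gamma),
                "log10_tau": np.log10(relax_map["tau_s"].to_numpy(float))})
            collapsed.to_csv(outdir / "collapsed_coordinates.csv", index=False,
                             float_format="%.9g")
            gammas["master_curve"]["beta_dispersion_at_alpha_gamma"] = \
                collapse_dispersion(relax_map, tait, mc.gamma, process="beta")
            if len(isobar_fits) >= 3:
                iso = gamma_isochronal_slope(isobar_fits, tait)
                gammas["isochronal_slope"] = {"gamma": iso.gamma, "se": iso.se}
        if config.thermo:
            tq = ThermoQuantities(**config.thermo)
            th = gamma_thermodynamic(tq)
            gammas["thermodynamic"] = {"gamma": th.gamma, "se": th.se}
        if not gammas:
            raise ValueError(
                "no gamma estimate possible: supply PVT data and/or "
                "thermodynamic quantities")
        write_json(gammas, outdir / "scaling_report.json")
        summary["gamma"] = gammas

        stage = "superposition"
        if andersson is not None:
            angell = angell_rescale(relax_map, andersson)
            angell.to_csv(outdir / "angell_plot.csv", index=False,
                          float_format="%.9g")
            summary["n_angell_points"] = int(len(angell))
        if fits:
            pairs = _isochronal_pairs(fits)
            report = []
            for (sa, ra), (sb, rb) in pairs:
                try:
                    la = normalize_isochronal(sa, ra.model)
                    lb = normalize_isochronal(sb, rb.model)
                    report.append({
                        "state_a": [sa.T, sa.P], "state_b": [sb.T, sb.P],
                        "log10_tau_alpha": np.log10(ra.model.components[0].tau),
                        "distance": superposition_distance(la, lb)})
                except ValueError:
                    continue
            write_json({"pairs": report}, outdir / "superposition_report.json")
            summary["superposition_pairs"] = report

        stage = "summary"
        write_json(summary, outdir / "summary.json")
    except Exception:
        logger.exception("pipeline failed during stage '%s'", stage)
        raise
    return summary


def _isochronal_pairs(fits, tol_decades: float = 0.15, max_pairs: int = 8):
    """Pairs of fitted spectra from different (T, P) states with matching τ_α."""
    entries = []
    for spec, res in fits:
        if res.converged and len(res.model.components) == 3:
            entries.append((np.log10(res.model.components[0].tau), spec, res))
    entries.sort(key=lambda e: e[0])
    pairs = []
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            lt_i, sa, ra = entries[i]
            lt_j, sb, rb = entries[j]
            if lt_j - lt_i > tol_decades:
                break
            if sa.P != sb.P and sa.T != sb.T:
                pairs.append(((sa, ra), (sb, rb)))
                if len(pairs) >= max_pairs:
                    return pairs
    return pairs
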