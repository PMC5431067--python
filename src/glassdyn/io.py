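"""CSV/JSON readers and writers for the pipeline's tabular dialects.

All CSV files are comma-separated, UTF-8, '.' decimal, header mandatory;
scientific notation is accepted.  Floating-point output is written with 9
significant digits so regression outputs are byte-stable.

Dialects:

* spectra:        T_K, P_MPa, f_Hz, eps1, eps2  (one row per point)
* PVT:            T_K, P_MPa, v_cm3g
* relaxation map: process, T_K, P_MPa, tau_s, shape, beta_kww, delta_eps,
                  tau_s_stderr, shape_stderr
* Angell plot:    process, x, log10_tau
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import SpectrumRecord

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_pvt",
    "write_pvt",
    "read_relaxation_map",
    "write_relaxation_map",
    "write_json",
    "FLOAT_FORMAT",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.9g"

SPECTRA_COLUMNS = ["T_K", "P_MPa", "f_Hz", "eps1", "eps2"]
PVT_COLUMNS = ["T_K", "P_MPa", "v_cm3g"]
MAP_COLUMNS = ["process", "T_K", "P_MPa", "tau_s", "shape", "beta_kww",
               "delta_eps", "tau_s_stderr", "shape_stderr"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_spectra(path) -> list[SpectrumRecord]:
    """Read a spectra CSV, grouped by (T, P) with ascending frequencies.

    Rows with non-finite loss are dropped with a logged warning naming the
    file line; duplicate (T, P, f) rows raise (ambiguous data).
    """
    df = _read_csv(path, SPECTRA_COLUMNS[:3] + ["eps2"])
    bad = ~np.isfinite(df["eps2"].to_numpy(float))
    if bad.any():
        for idx in df.index[bad]:
            logger.warning("%s: dropping row at file line %d (non-finite loss)",
                           path, idx + 2)  # +2: header + 1-based
        df = df[~bad]
    if df.duplicated(subset=["T_K", "P_MPa", "f_Hz"]).any():
        raise ValueError(f"{path}: duplicate (T, P, f) rows are ambiguous")
    records = []
    for (T, P), g in df.groupby(["T_K", "P_MPa"], sort=True):
        g = g.sort_values("f_Hz")
        eps1 = g["eps1"].to_numpy(float) if "eps1" in g.columns else None
        if eps1 is not None and not np.all(np.isfinite(eps1)):
            eps1 = None
        records.append(SpectrumRecord(T=float(T), P=float(P),
                                      f=g["f_Hz"].to_numpy(float),
                                      eps2=g["eps2"].to_numpy(float),
                                      eps1=eps1))
    return records


def write_spectra(records: list[SpectrumRecord], path) -> None:
    rows = []
    for rec in records:
        eps1 = rec.eps1 if rec.eps1 is not None else np.full_like(rec.f, np.nan)
        for f, e1, e2 in zip(rec.f, eps1, rec.eps2):
            rows.append((rec.T, rec.P, f, e1, e2))
    df = pd.DataFrame(rows, columns=SPECTRA_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_pvt(path) -> pd.DataFrame:
    return _read_csv(path, PVT_COLUMNS)


def write_pvt(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, columns=PVT_COLUMNS)


def read_relaxation_map(path) -> pd.DataFrame:
    return _read_csv(path, MAP_COLUMNS[:5])


def write_relaxation_map(df: pd.DataFrame, path) -> None:
    cols = [c for c in MAP_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, columns=cols)


def _round_sig(obj, sig: int = 9):
    if isinstance(obj, dict):
        return {k: _round_sig(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_sig(v, sig) for v in obj]
    if isinstance(obj, (float, np.floating)):
        if not np.isfinite(obj):
            return None
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_sig(obj.tolist(), sig)
    return obj


def write_json(obj: dict, path) -> None:
    """Write a JSON report with floats at 9 significant digits."""
    Path(path).write_text(json.dumps(_round_sig(obj), indent=2, sort_keys=True)
                          + "\n", encoding="utf-8")
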