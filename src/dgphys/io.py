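"""Trace-table readers/writers and structured-config loading.

The portable trace format is a UTF-8 CSV with a ``#``-prefixed metadata
header followed by the exact columns ``time_ms, V_mV, I_pA`` (``I_pA``
optional).  An HDF5 dialect (same columns as datasets, metadata as root
attributes) round-trips samples bit-exactly.  Units are fixed at the I/O
boundary: mV, pA, ms.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Any, Mapping

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .subthresh import TimeSeriesTrace

__all__ = ["read_trace", "write_trace", "load_config", "validate_config"]

_COLUMNS = ("time_ms", "V_mV", "I_pA")
_META_FIELDS = ("cell_id", "condition", "protocol", "seed")
_RTOL_TIME = 1e-9


def _trace_meta(trace: TimeSeriesTrace) -> dict[str, Any]:
    meta = {k: trace.meta[k] for k in _META_FIELDS if k in trace.meta}
    meta.update(
        dt=trace.dt, t_on=trace.t_on, t_off=trace.t_off,
        v_rmp=trace.v_rmp if trace.v_rmp is not None else "",
    )
    return meta


def write_trace(trace: TimeSeriesTrace, path: str | Path) -> Path:
    """Write a trace as CSV (default) or HDF5 (``.h5``/``.hdf5`` suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=trace.time)
            f.create_dataset("V_mV", data=trace.voltage)
            if trace.current is not None:
                f.create_dataset("I_pA", data=trace.current)
            for k, v in _trace_meta(trace).items():
                f.attrs[k] = v
        return path
    buf = _io.StringIO()
    for k, v in _trace_meta(trace).items():
        buf.write(f"# {k}: {v}\n")
    cols = {"time_ms": trace.time, "V_mV": trace.voltage}
    if trace.current is not None:
        cols["I_pA"] = trace.current
    pd.DataFrame(cols).to_csv(buf, index=False, float_format="%.9g")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def _parse_meta(lines: list[str]) -> dict[str, str]:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if ":" in body:
            k, v = body.split(":", 1)
            meta[k.strip()] = v.strip()
    return meta


def _check_time(time: np.ndarray, path: Path) -> float:
    if time.size < 2:
        raise FormatError(f"{path}: trace needs >= 2 samples")
    steps = np.diff(time)
    if np.any(steps <= 0):
        row = int(np.argmax(steps <= 0)) + 1
        raise FormatError(f"{path}: time not strictly increasing at row {row + 1}")
    dt = float(time[1] - time[0])
    bad = np.abs(steps - dt) > _RTOL_TIME * max(abs(time[-1]), 1.0)
    if np.any(bad):
        row = int(np.argmax(bad)) + 1
        raise FormatError(f"{path}: non-uniform sampling at row {row + 1}")
    return dt


def read_trace(path: str | Path) -> TimeSeriesTrace:
    """Read a trace table (CSV or HDF5), validating columns and time grid."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            missing = [c for c in ("time_ms", "V_mV") if c not in f]
            if missing:
                raise FormatError(f"{path}: missing dataset(s) {missing}")
            time = np.asarray(f["time_ms"], dtype=np.float64)
            voltage = np.asarray(f["V_mV"], dtype=np.float64)
            current = np.asarray(f["I_pA"], dtype=np.float64) if "I_pA" in f else None
            meta = {k: f.attrs[k] for k in f.attrs}
    else:
        text = path.read_text(encoding="utf-8").splitlines()
        header = [ln for ln in text if ln.startswith("#")]
        body = "\n".join(ln for ln in text if not ln.startswith("#"))
        meta = _parse_meta(header)
        df = pd.read_csv(_io.StringIO(body))
        missing = [c for c in ("time_ms", "V_mV") if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
        unknown = [c for c in df.columns if c not in _COLUMNS]
        if unknown:
            raise FormatError(f"{path}: unexpected column(s) {unknown}")
        time = df["time_ms"].to_numpy(dtype=np.float64)
        voltage = df["V_mV"].to_numpy(dtype=np.float64)
        current = df["I_pA"].to_numpy(dtype=np.float64) if "I_pA" in df.columns else None
    dt = _check_time(np.asarray(time, dtype=np.float64), path)
    v_rmp = meta.get("v_rmp", "")
    return TimeSeriesTrace(
        dt=dt,
        voltage=voltage,
        current=current,
        t_on=float(meta.get("t_on", 0.0)),
        t_off=float(meta.get("t_off", 0.0)),
        v_rmp=float(v_rmp) if str(v_rmp) not in ("", "None") else None,
        meta={k: v for k, v in meta.items() if k not in ("dt", "t_on", "t_off", "v_rmp")},
    )


#: Allowed configuration schema (key -> type or nested dict of the same).
CONFIG_SCHEMA: dict[str, Any] = {
    "seed": int,
    "n_cells": int,
    "noise_sd": float,
    "alpha": float,
    "effect_floor": float,
    "fraction_blocked": float,
    "blockades": list,
    "chirp_amplitude": float,
    "epsp_peak": float,
    "holding_voltages": list,
    "bounds": dict,
    "validity": dict,
}


def validate_config(cfg: Mapping[str, Any], schema: Mapping[str, Any] | None = None, path: str = "") -> None:
    """Fail fast on unknown keys, reporting the offending key path."""
    schema = CONFIG_SCHEMA if schema is None else schema
    for key, val in cfg.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise FormatError(f"unknown config key: {here}")
        want = schema[key]
        if want is dict and not isinstance(val, dict):
            raise FormatError(f"config key {here} must be a mapping")


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config and validate its keys against the schema."""
    with open(path, "r", encoding="utf-8") as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping at top level")
    validate_config(cfg)
    return cfg
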