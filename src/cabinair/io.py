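"""CSV/JSON/YAML readers and writers for traces, speed logs and reports.

Fixed CSV dialect: comma-separated, '.' decimal, mandatory header.
Trace files carry ``time_s, co2_ppm, temp_c, rh_pct``; speed logs carry
``time_s, speed_mph``.  The time column holds seconds from the start of
the recording; ISO-8601 timestamps are accepted and converted on read.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import SpeedLog
from .model import ParameterError, SensorTrace

logger = logging.getLogger("cabinair")

TRACE_COLUMNS = ["time_s", "co2_ppm", "temp_c", "rh_pct"]
SPEED_COLUMNS = ["time_s", "speed_mph"]

#: sampling gaps longer than this are logged as warnings [s]
GAP_WARN_S = 5.0


class ParseError(ValueError):
    """An input file violates the expected dialect or invariants."""


def _time_seconds(col: pd.Series, path: str) -> np.ndarray:
    """Numeric seconds-from-start, converting ISO-8601 timestamps if needed."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    try:
        stamps = pd.to_datetime(col, format="ISO8601")
    except (ValueError, TypeError) as err:
        bad = int(numeric.isna().idxmax())
        raise ParseError(
            f"{path}: non-numeric, non-ISO8601 time value at data line {bad + 2}"
        ) from err
    return (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy(dtype=float)


def _read_columns(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as err:
        raise ParseError(f"{path}: not parseable as CSV: {err}") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}; found {list(df.columns)}")
    for c in required[1:]:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2  # header + 1-based
            raise ParseError(f"{path}: non-numeric value in column '{c}' at line {line}")
        df[c] = vals
    return df


def _check_monotone(t: np.ndarray, path) -> None:
    d = np.diff(t)
    if np.any(d <= 0):
        line = int(np.argmax(d <= 0)) + 3  # header + 1-based + offset
        raise ParseError(f"{path}: timestamps not strictly increasing at line {line}")
    gaps = np.nonzero(d > GAP_WARN_S)[0]
    for g in gaps[:10]:
        logger.warning("%s: %.1f s sampling gap after t=%.1f s", path, d[g], t[g])


def read_sensor_trace(path) -> SensorTrace:
    """Read a trace CSV (``time_s, co2_ppm, temp_c, rh_pct``)."""
    df = _read_columns(path, TRACE_COLUMNS)
    t = _time_seconds(df["time_s"], str(path))
    _check_monotone(t, path)
    try:
        trace = SensorTrace(
            t,
            df["co2_ppm"].to_numpy(dtype=float),
            df["temp_c"].to_numpy(dtype=float),
            df["rh_pct"].to_numpy(dtype=float),
        )
    except ParameterError as err:
        raise ParseError(f"{path}: {err}") from err
    n_flagged = int(trace.out_of_calibration.sum())
    if n_flagged:
        logger.warning("%s: %d CO2 readings above the calibrated span", path, n_flagged)
    return trace


def write_sensor_trace(trace: SensorTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.timestamps,
            "co2_ppm": trace.co2,
            "temp_c": trace.temperature,
            "rh_pct": trace.relative_humidity,
        }
    ).to_csv(path, index=False)


def read_speed_log(path) -> SpeedLog:
    """Read a speed-log CSV (``time_s, speed_mph``)."""
    df = _read_columns(path, SPEED_COLUMNS)
    t = _time_seconds(df["time_s"], str(path))
    _check_monotone(t, path)
    try:
        return SpeedLog(t, df["speed_mph"].to_numpy(dtype=float))
    except ParameterError as err:
        raise ParseError(f"{path}: {err}") from err


def write_speed_log(log: SpeedLog, path) -> None:
    pd.DataFrame({"time_s": log.timestamps, "speed_mph": log.speed}).to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return None if math.isnan(x) else x  # NaN -> null: undefined statistic
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json_report(obj, path) -> None:
    """Serialize a dataclass/dict report; NaN statistics become null."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg
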