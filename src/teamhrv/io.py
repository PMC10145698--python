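"""Plain-text dialects: ECG sample CSV, beat/IBI CSV, IBI replay text,
metric CSV, and the JSONL session log."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .core_model import DataError, IBISeries
from .hrv_metrics import HRVMetrics

PathLike = Union[str, Path]

#: Allowed sample-time jitter, as a fraction of the sample period.
MAX_TIME_JITTER = 0.01


def write_ecg_csv(
    path: PathLike, samples: np.ndarray, rate: float, t0_ms: float = 0.0
) -> None:
    """ECG sample dialect: header ``time_ms,voltage_mv``, one row per sample."""
    t = t0_ms + np.arange(len(samples)) * 1000.0 / rate
    pd.DataFrame({"time_ms": t, "voltage_mv": samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_ecg_csv(path: PathLike) -> tuple[np.ndarray, float, float]:
    """Read an ECG sample CSV; returns ``(samples, rate, t0_ms)``.

    The rate is inferred from the median time step; the file is rejected
    if any step deviates from that period by more than 1%.
    """
    df = pd.read_csv(path)
    for col in ("time_ms", "voltage_mv"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    t = df["time_ms"].to_numpy(dtype=float)
    v = df["voltage_mv"].to_numpy(dtype=float)
    if len(t) < 2:
        raise DataError(f"{path}: need at least two samples to infer the rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError(f"{path}: sample times must be strictly increasing")
    period = float(np.median(dt))
    if np.max(np.abs(dt - period)) > MAX_TIME_JITTER * period:
        raise DataError(
            f"{path}: sample-time jitter exceeds {MAX_TIME_JITTER:.0%} of the "
            f"median period ({period:g} ms); not a uniform-rate recording"
        )
    return v, 1000.0 / period, float(t[0])


def write_ibi_csv(path: PathLike, series: IBISeries) -> None:
    """Beat/IBI dialect: ``beat_time_ms,ibi_ms,accepted``."""
    pd.DataFrame(
        {
            "beat_time_ms": series.beat_time_ms,
            "ibi_ms": series.ibi_ms,
            "accepted": series.accepted.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_ibi_csv(path: PathLike, stream_id: str = "") -> IBISeries:
    df = pd.read_csv(path)
    return IBISeries(
        beat_time_ms=df["beat_time_ms"].to_numpy(dtype=float),
        ibi_ms=df["ibi_ms"].to_numpy(dtype=float),
        accepted=df["accepted"].to_numpy(dtype=bool),
        stream_id=stream_id,
    )


def write_beat_times_csv(path: PathLike, beat_times_ms: np.ndarray) -> None:
    """Ground-truth beat-time dialect: single ``beat_time_ms`` column."""
    pd.DataFrame({"beat_time_ms": np.asarray(beat_times_ms, dtype=float)}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_ibi_text(path: PathLike) -> list[float]:
    """Replay dialect: one positive IBI (ms) per line.

    Blank lines and ``#`` comments are ignored.  A non-numeric or
    non-positive line raises a :class:`DataError` naming its line number.
    """
    ibis: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                value = float(line)
            except ValueError:
                raise DataError(
                    f"{path}: line {lineno}: not a number: {line!r}"
                ) from None
            if value <= 0:
                raise DataError(
                    f"{path}: line {lineno}: interval must be positive, got {value}"
                )
            ibis.append(value)
    return ibis


METRIC_COLUMNS = [
    "window_end_ms", "stream_id", "mean_hr_bpm", "sdnn_ms", "rmssd_ms",
    "lf_ms2", "hf_ms2", "lf_hf", "n_beats", "valid",
]


def write_metrics_csv(path: PathLike, metrics: Iterable[HRVMetrics]) -> None:
    rows = [
        {
            "window_end_ms": m.window_end_ms,
            "stream_id": m.stream_id,
            "mean_hr_bpm": m.mean_hr_bpm,
            "sdnn_ms": m.sdnn_ms,
            "rmssd_ms": m.rmssd_ms,
            "lf_ms2": m.lf_power_ms2,
            "hf_ms2": m.hf_power_ms2,
            "lf_hf": m.lf_hf_ratio,
            "n_beats": m.n_beats,
            "valid": int(m.valid),
        }
        for m in metrics
    ]
    pd.DataFrame(rows, columns=METRIC_COLUMNS).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_metrics_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass(frozen=True)
class LogRecord:
    """One forensic-log entry: coordinated timestamp, topic, payload."""

    time_ms: float
    topic: str
    payload: dict


def write_log(path: PathLike, records: Iterable[LogRecord]) -> None:
    """Append-style JSONL log, one record per line."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {"time_ms": rec.time_ms, "topic": rec.topic,
                     "payload": rec.payload},
                    sort_keys=True, allow_nan=True,
                )
            )
            fh.write("\n")


def read_log(path: PathLike) -> list[LogRecord]:
    """Read a JSONL log; a malformed line raises naming its line number."""
    out: list[LogRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                out.append(
                    LogRecord(
                        time_ms=float(obj["time_ms"]),
                        topic=str(obj["topic"]),
                        payload=obj["payload"],
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                raise DataError(f"{path}: malformed log line {lineno}") from None
    return out


def _jsonable(value):
    """Recursively convert numpy scalars/arrays and NaN-safe floats."""
    if isinstance(value, np.ndarray):
        return [_jsonable(v) for v in value.tolist()]
    if isinstance(value, (np.floating, np.integer)):
        value = value.item()
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value
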