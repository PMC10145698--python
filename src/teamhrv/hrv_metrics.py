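"""Ultra-short-term HRV metrics over sliding windows.

One summary per update period (default 1 s) per stream, each computed
over the trailing window (10–300 s, default 60 s) of accepted
inter-beat intervals: mean heart rate, SDNN, RMSSD, and band powers of
the IBI series in the LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) bands
with their ratio.  Spectral powers come from a least-squares (Lomb)
periodogram evaluated directly on the uneven beat-time base — no
resampling — integrated over each band on a dense grid.  The shared
0.15 Hz edge belongs to HF only, so no power is double-counted.

A window is valid only if it spans a full window length, contains at
least ``min_beats`` accepted intervals, and has HF power above a small
epsilon (the LF/HF ratio is undefined otherwise); invalid windows are
still emitted, flagged, never silently skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lombscargle

from .core_model import ConfigError, IBISeries

MIN_WINDOW_S = 10.0
MAX_WINDOW_S = 300.0
LF_BAND_HZ = (0.04, 0.15)
HF_BAND_HZ = (0.15, 0.40)
#: Below this HF power (ms^2) the LF/HF ratio is treated as undefined.
HF_EPSILON_MS2 = 1e-6


@dataclass(frozen=True)
class HRVWindowConfig:
    window_s: float = 60.0
    update_period_s: float = 1.0
    lf_band_hz: tuple[float, float] = LF_BAND_HZ
    hf_band_hz: tuple[float, float] = HF_BAND_HZ
    min_beats: int = 10

    def __post_init__(self) -> None:
        if not MIN_WINDOW_S <= self.window_s <= MAX_WINDOW_S:
            raise ConfigError(
                f"window_s must lie in [{MIN_WINDOW_S:g}, {MAX_WINDOW_S:g}] s, "
                f"got {self.window_s}"
            )
        if self.update_period_s <= 0:
            raise ConfigError("update_period_s must be positive")
        if self.min_beats < 2:
            raise ConfigError("min_beats must be at least 2")
        if not (self.lf_band_hz[0] < self.lf_band_hz[1] <= self.hf_band_hz[0]
                < self.hf_band_hz[1]):
            raise ConfigError("LF and HF bands must be ordered and disjoint")


@dataclass(frozen=True)
class HRVMetrics:
    """One windowed HRV summary; NaN marks undefined values."""

    stream_id: str
    window_end_ms: float
    window_s: float
    mean_hr_bpm: float
    sdnn_ms: float
    rmssd_ms: float
    lf_power_ms2: float
    hf_power_ms2: float
    lf_hf_ratio: float
    n_beats: int
    valid: bool


def select_window(
    series: IBISeries, end_ms: float, window_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Accepted intervals whose closing beat lies in (end - window, end].

    Returns ``(beat_times_ms, ibis_ms)``; the selection may be empty.
    """
    if not MIN_WINDOW_S <= window_s <= MAX_WINDOW_S:
        raise ConfigError(
            f"window_s must lie in [{MIN_WINDOW_S:g}, {MAX_WINDOW_S:g}] s, "
            f"got {window_s}"
        )
    lo = end_ms - window_s * 1000.0
    mask = series.accepted & (series.beat_time_ms > lo) & (series.beat_time_ms <= end_ms)
    return series.beat_time_ms[mask], series.ibi_ms[mask]


def mean_hr(ibis_ms: np.ndarray) -> float:
    """Mean heart rate in bpm: 60000 / mean(IBI). NaN for an empty window."""
    ibis_ms = np.asarray(ibis_ms, dtype=float)
    if len(ibis_ms) < 1:
        return math.nan
    return 60000.0 / float(np.mean(ibis_ms))


def sdnn(ibis_ms: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) of the intervals, ms."""
    ibis_ms = np.asarray(ibis_ms, dtype=float)
    if len(ibis_ms) < 2:
        return math.nan
    return float(np.std(ibis_ms, ddof=1))


def rmssd(ibis_ms: np.ndarray) -> float:
    """Root mean square of successive interval differences, ms."""
    ibis_ms = np.asarray(ibis_ms, dtype=float)
    if len(ibis_ms) < 2:
        return math.nan
    d = np.diff(ibis_ms)
    return float(np.sqrt(np.mean(d**2)))


def spectral_powers(
    beat_times_ms: np.ndarray,
    ibis_ms: np.ndarray,
    lf_band_hz: tuple[float, float] = LF_BAND_HZ,
    hf_band_hz: tuple[float, float] = HF_BAND_HZ,
    min_beats: int = 10,
    grid_points: int = 512,
) -> tuple[float, float]:
    """Band powers (ms^2) of the IBI series on its uneven time base.

    The mean-subtracted intervals are analysed with a least-squares
    periodogram at the beat times, scaled to a one-sided spectral density
    and integrated per band by the trapezoid rule on a ``grid_points``
    grid.  The LF grid excludes the shared 0.15 Hz edge (half-open band).
    Returns ``(nan, nan)`` with fewer than ``min_beats`` intervals.
    """
    t = np.asarray(beat_times_ms, dtype=float) / 1000.0
    y = np.asarray(ibis_ms, dtype=float)
    n = len(y)
    if n < min_beats:
        return math.nan, math.nan
    y = y - y.mean()
    if np.allclose(y, 0.0):
        return 0.0, 0.0
    span_s = t[-1] - t[0]
    # Peak of the raw Lomb periodogram for a sinusoid of amplitude A is
    # ~n A^2/4 with spectral width ~1/span; 2*span/n scales it to a
    # one-sided density whose band integral recovers the variance A^2/2.
    scale = 2.0 * span_s / n

    def band_power(band: tuple[float, float], include_upper: bool) -> float:
        f = np.linspace(band[0], band[1], grid_points, endpoint=include_upper)
        p = lombscargle(t, y, 2 * np.pi * f)
        return float(np.trapezoid(p * scale, f))

    lf = band_power(lf_band_hz, include_upper=False)
    hf = band_power(hf_band_hz, include_upper=True)
    return max(lf, 0.0), max(hf, 0.0)


def lf_hf(lf_power: float, hf_power: float, eps: float = HF_EPSILON_MS2) -> float:
    """LF/HF ratio; NaN (undefined) when HF power is below ``eps``."""
    if math.isnan(lf_power) or math.isnan(hf_power):
        return math.nan
    if lf_power < 0 or hf_power < 0:
        raise ValueError("band powers must be non-negative")
    if hf_power <= eps:
        return math.nan
    return lf_power / hf_power


def compute_window_metrics(
    series: IBISeries,
    end_ms: float,
    config: HRVWindowConfig,
    stream_id: str = "",
    full_window: bool = True,
) -> HRVMetrics:
    """All metrics for the window ending at ``end_ms``."""
    times, ibis = select_window(series, end_ms, config.window_s)
    n = len(ibis)
    lf, hf = spectral_powers(
        times, ibis, config.lf_band_hz, config.hf_band_hz, config.min_beats
    )
    ratio = lf_hf(lf, hf)
    valid = bool(full_window and n >= config.min_beats and not math.isnan(ratio))
    return HRVMetrics(
        stream_id=stream_id,
        window_end_ms=float(end_ms),
        window_s=config.window_s,
        mean_hr_bpm=mean_hr(ibis),
        sdnn_ms=sdnn(ibis),
        rmssd_ms=rmssd(ibis),
        lf_power_ms2=lf,
        hf_power_ms2=hf,
        lf_hf_ratio=ratio,
        n_beats=n,
        valid=valid,
    )


def run_metric_engine(
    series: IBISeries,
    config: HRVWindowConfig,
    stream_id: Optional[str] = None,
) -> list[HRVMetrics]:
    """Emit one metrics record per update period of stream time.

    Emission times are anchored at the stream's first beat: the k-th
    record is stamped at ``t_first + k * update_period`` for every k with
    a stamp no later than the last beat.  Records whose window has not
    yet fully elapsed are emitted with ``valid=False`` rather than
    skipped, so the cadence is exactly one per update period throughout.
    """
    sid = stream_id if stream_id is not None else series.stream_id
    if len(series) == 0:
        return []
    t_first = series.first_beat_time_ms
    t_last = float(series.beat_time_ms[-1])
    step = config.update_period_s * 1000.0
    window_ms = config.window_s * 1000.0
    out: list[HRVMetrics] = []
    k = 1
    while t_first + k * step <= t_last:
        end = t_first + k * step
        out.append(
            compute_window_metrics(
                series, end, config, stream_id=sid,
                full_window=(end - t_first) >= window_ms,
            )
        )
        k += 1
    return out
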