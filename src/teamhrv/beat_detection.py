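"""Adaptive-threshold R-peak detection and inter-beat-interval assembly.

The detector tracks the running maximum of the signal over a trailing
window (default 10 s) and sets the threshold at a fixed fraction of it
(default 0.6 — high enough to clear T waves, relative so that uniform
amplitude scaling changes nothing).  While the signal is above
threshold, the first change of the first difference from positive to
non-positive marks a beat; beats within a refractory period of the
previous one (default 250 ms, a ~240 bpm physiological ceiling) are
suppressed.  The first trailing-window span is buffered before any beat
is emitted and its maximum serves as the cold-start reference: a
max-seen-so-far reference would fire on any positive wiggle (e.g. the
P wave) before the first R peak has been observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import ConfigError, DataError, IBISeries


@dataclass(frozen=True)
class DetectorConfig:
    lookback_s: float = 10.0
    threshold_fraction: float = 0.6
    refractory_ms: float = 250.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ConfigError(
                f"threshold_fraction must lie in (0, 1), got {self.threshold_fraction}"
            )
        if self.refractory_ms <= 0:
            raise ConfigError("refractory_ms must be positive")
        if self.lookback_s <= 0:
            raise ConfigError("lookback_s must be positive")


def trailing_max(x: np.ndarray, window: int) -> np.ndarray:
    """Running maximum over the trailing ``window`` samples (van Herk).

    ``out[i] = max(x[max(i - window + 1, 0) : i + 1])`` — i.e. max-so-far
    during the cold start.  O(n) via block prefix/suffix maxima.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if window <= 1 or n == 0:
        return x.copy()
    n_blocks = -(-n // window)
    padded = np.full(n_blocks * window, -np.inf)
    padded[:n] = x
    blocks = padded.reshape(n_blocks, window)
    prefix = np.maximum.accumulate(blocks, axis=1).ravel()
    suffix = np.maximum.accumulate(blocks[:, ::-1], axis=1)[:, ::-1].ravel()
    idx = np.arange(n)
    j = idx - window + 1
    out = np.where(j >= 0, np.maximum(prefix[idx], suffix[np.maximum(j, 0)]), prefix[idx])
    return out


def detect_beats(
    ecg: np.ndarray,
    rate: float,
    config: DetectorConfig = DetectorConfig(),
    t0_ms: float = 0.0,
) -> np.ndarray:
    """Detect R-peak times (ms) in a voltage sequence.

    A stream with no super-threshold samples yields no beats.  Plateau
    maxima emit at the first sample of the plateau (deterministic
    tie-break).
    """
    x = np.asarray(ecg, dtype=float)
    if rate <= 0:
        raise ConfigError(f"rate must be positive, got {rate}")
    if len(x) < 3:
        return np.empty(0)
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite sample in detector input")
    window = max(1, int(round(config.lookback_s * rate)))
    roll = trailing_max(x, window)
    # Cold start: reference the full first window (buffered), not max-so-far.
    w_eff = min(window, len(x))
    roll[:w_eff] = np.max(x[:w_eff])
    thr = config.threshold_fraction * roll
    d = np.diff(x)
    # Candidate peaks: above threshold, rising into the sample, not rising out.
    cand = (x[1:-1] > thr[1:-1]) & (d[:-1] > 0) & (d[1:] <= 0)
    idxs = np.flatnonzero(cand) + 1
    period = 1000.0 / rate
    beats: list[float] = []
    last = -np.inf
    for i in idxs:
        t = i * period
        if t - last >= config.refractory_ms:
            beats.append(t)
            last = t
    return t0_ms + np.asarray(beats)


def ibis_from_beats(beat_times_ms: np.ndarray, stream_id: str = "") -> IBISeries:
    """Turn n beat times into n-1 inter-beat intervals.

    The sum of the intervals equals the span from first to last beat.
    """
    t = np.asarray(beat_times_ms, dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise DataError("beat times must be strictly increasing")
    if len(t) < 2:
        return IBISeries.empty(stream_id)
    ibis = np.diff(t)
    return IBISeries(
        beat_time_ms=t[1:],
        ibi_ms=ibis,
        accepted=np.ones(len(ibis), dtype=bool),
        stream_id=stream_id,
    )


def ibi_artifact_filter(
    series: IBISeries,
    min_ms: float = 300.0,
    max_ms: float = 2000.0,
    max_rel_change: float = 0.2,
) -> IBISeries:
    """Flag physiologically implausible intervals as rejected.

    An interval is rejected if it falls outside ``[min_ms, max_ms]`` or
    differs from the previous *accepted* interval by more than
    ``max_rel_change`` (relative); the relative rule is inactive until a
    first interval has been accepted.  Rejected intervals keep their slot
    with ``accepted=False`` so the time base survives.
    """
    if min_ms >= max_ms:
        raise ConfigError(f"min_ms ({min_ms}) must be below max_ms ({max_ms})")
    accepted = np.zeros(len(series), dtype=bool)
    prev: float | None = None
    for i, ibi in enumerate(series.ibi_ms):
        ok = min_ms <= ibi <= max_ms
        if ok and prev is not None and abs(ibi - prev) / prev > max_rel_change:
            ok = False
        if ok:
            prev = float(ibi)
        accepted[i] = ok
    return IBISeries(
        beat_time_ms=series.beat_time_ms.copy(),
        ibi_ms=series.ibi_ms.copy(),
        accepted=accepted,
        stream_id=series.stream_id,
    )
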