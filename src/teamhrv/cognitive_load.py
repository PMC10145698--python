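"""Cognitive-load scoring and individual/team alerting.

Each clinician's LF/HF ratio is referenced against their own calibration
distribution: the empirical terciles split it into low/medium/high load,
scored 1/2/3.  The team alarm fires when the sum of the valid members'
scores reaches ``sum_threshold`` (default 7) or when at least
``red_count_threshold`` members (default 2) sit in the high ("red")
tercile.  Members without a valid estimate are excluded from both
conditions and the alert is flagged degraded when fewer than four
members contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core_model import ConfigError, Role

#: Minimum number of valid LF/HF values before terciles are available.
MIN_CALIBRATION_VALUES = 9


class LoadLevel(Enum):
    LOW = 1
    MEDIUM = 2
    HIGH = 3


@dataclass(frozen=True)
class TercileBoundaries:
    """LF/HF values at the 1/3 and 2/3 quantiles of the reference set."""

    stream_id: str
    t1: float
    t2: float
    source: str = "calibration_window"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t1) and math.isfinite(self.t2)):
            raise ConfigError("tercile boundaries must be finite")
        if self.t1 > self.t2:
            raise ConfigError(f"t1 ({self.t1}) must not exceed t2 ({self.t2})")


@dataclass(frozen=True)
class CognitiveLoadEstimate:
    stream_id: str
    time_ms: float
    level: Optional[LoadLevel]
    score: Optional[int]
    lf_hf: float
    valid: bool


def calibrate_terciles(
    lf_hf_values: Sequence[float],
    stream_id: str = "",
    source: str = "calibration_window",
) -> Optional[TercileBoundaries]:
    """Empirical 1/3 and 2/3 quantiles (linear interpolation) of LF/HF.

    Returns ``None`` (boundaries unavailable) with fewer than
    ``MIN_CALIBRATION_VALUES`` finite values.
    """
    vals = np.asarray(
        [v for v in lf_hf_values if v is not None and math.isfinite(v)], dtype=float
    )
    if len(vals) < MIN_CALIBRATION_VALUES:
        return None
    t1, t2 = np.quantile(vals, [1.0 / 3.0, 2.0 / 3.0], method="linear")
    return TercileBoundaries(stream_id=stream_id, t1=float(t1), t2=float(t2),
                             source=source)


def rolling_terciles(
    times_ms: Sequence[float],
    lf_hf_values: Sequence[float],
    window_s: float = 600.0,
    stream_id: str = "",
) -> list[Optional[TercileBoundaries]]:
    """Sliding-window recalibration: boundaries at each estimate time.

    At each time, the terciles of the values inside the trailing
    ``window_s`` (default 10 min) are used; ``None`` until the window
    holds enough valid values.  An alternative to the fixed
    calibration-window reference for long sessions where the baseline
    drifts.
    """
    times = np.asarray(times_ms, dtype=float)
    out: list[Optional[TercileBoundaries]] = []
    for t in times:
        mask = (times >= t - window_s * 1000.0) & (times <= t)
        vals = [v for v, m in zip(lf_hf_values, mask) if m]
        out.append(calibrate_terciles(vals, stream_id=stream_id, source="rolling"))
    return out


def estimate_load(
    lf_hf: float,
    bounds: Optional[TercileBoundaries],
    time_ms: float = 0.0,
    stream_id: str = "",
) -> CognitiveLoadEstimate:
    """Map one LF/HF value to a load level and 1–3 score.

    Boundary values promote upward (a value exactly at t2 is high): the
    mapping errs toward sensitivity.  An undefined LF/HF or missing
    boundaries yield an invalid estimate with no score.
    """
    if bounds is None or lf_hf is None or not math.isfinite(lf_hf):
        return CognitiveLoadEstimate(
            stream_id=stream_id, time_ms=time_ms, level=None, score=None,
            lf_hf=math.nan if lf_hf is None else lf_hf, valid=False,
        )
    if lf_hf < bounds.t1:
        level = LoadLevel.LOW
    elif lf_hf < bounds.t2:
        level = LoadLevel.MEDIUM
    else:
        level = LoadLevel.HIGH
    return CognitiveLoadEstimate(
        stream_id=stream_id, time_ms=time_ms, level=level,
        score=level.value, lf_hf=lf_hf, valid=True,
    )


@dataclass(frozen=True)
class TeamAlert:
    time_ms: float
    active: bool
    reasons: tuple[str, ...]
    member_scores: tuple[tuple[str, Optional[int]], ...]
    sum: int
    degraded: bool
    insufficient_data: bool


def team_alert(
    member_scores: Mapping[Role, Optional[int]],
    time_ms: float = 0.0,
    sum_threshold: int = 7,
    red_count_threshold: int = 2,
) -> TeamAlert:
    """Evaluate the team alarm over the current member scores.

    ``None`` scores (invalid estimates) are excluded from the sum and the
    red count.  With no valid member the alert is inactive and flagged
    ``insufficient_data``.
    """
    valid = {r: s for r, s in member_scores.items() if s is not None}
    total = sum(valid.values())
    reds = sum(1 for s in valid.values() if s == 3)
    reasons: list[str] = []
    if valid:
        if total >= sum_threshold:
            reasons.append("sum_rule")
        if reds >= red_count_threshold:
            reasons.append("two_red")
    return TeamAlert(
        time_ms=time_ms,
        active=bool(reasons),
        reasons=tuple(reasons),
        member_scores=tuple(
            (r.value, member_scores[r]) for r in sorted(member_scores, key=lambda x: x.value)
        ),
        sum=total,
        degraded=len(valid) < 4,
        insufficient_data=not valid,
    )


@dataclass(frozen=True)
class AlertEvent:
    """One raise (active=True) or clear (active=False) transition."""

    stream_id: str
    time_ms: float
    active: bool


def individual_alerts(
    estimates: Iterable[CognitiveLoadEstimate],
    dwell_s: float = 10.0,
) -> list[AlertEvent]:
    """Dwell-based per-clinician alert with one-level hysteresis.

    Raises when the level has been HIGH continuously for ``dwell_s``
    (the event is stamped at run start + dwell); clears when the level
    has been at or below MEDIUM continuously for ``dwell_s``.  Invalid
    estimates interrupt both dwell runs.  Events strictly alternate
    raise/clear.
    """
    dwell_ms = dwell_s * 1000.0
    events: list[AlertEvent] = []
    raised = False
    high_start: Optional[float] = None
    clear_start: Optional[float] = None
    for est in estimates:
        t = est.time_ms
        if not est.valid:
            high_start = None
            clear_start = None
            continue
        if not raised:
            if est.level is LoadLevel.HIGH:
                if high_start is None:
                    high_start = t
                if t - high_start >= dwell_ms:
                    events.append(AlertEvent(est.stream_id, high_start + dwell_ms, True))
                    raised = True
                    clear_start = None
            else:
                high_start = None
        else:
            if est.level is not LoadLevel.HIGH:
                if clear_start is None:
                    clear_start = t
                if t - clear_start >= dwell_ms:
                    events.append(AlertEvent(est.stream_id, clear_start + dwell_ms, False))
                    raised = False
                    high_start = None
            else:
                clear_start = None
    return events
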