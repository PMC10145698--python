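"""Domain types and stream plumbing for the team-HRV pipeline.

ECG samples travel through the pipeline as fixed-duration packets
(default 250 ms) published on an in-process bus keyed by stream id.
All timestamps are milliseconds on a single monotonic session clock,
so packets, beats, metrics and alerts from different clinicians can be
interleaved and logged on one time base.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

import numpy as np

logger = logging.getLogger(__name__)

#: ISO 11073-10101 label for the single ECG channel carried by the pipeline.
DEFAULT_LEAD_LABEL = "MDC_ECG_Lead_II"
DEFAULT_BUNDLE_MS = 250.0
#: Minimum sampling rate accepted for beat detection; below this the
#: per-interval timing error becomes comparable to the variability measured.
DEFAULT_MIN_RATE = 500.0


class ConfigError(ValueError):
    """Invalid configuration (rejected before any data is processed)."""


class DataError(ValueError):
    """Malformed or physically impossible input data."""


def sample_period_ms(rate: float) -> float:
    """Duration covered by one sample, in milliseconds (1000 / rate)."""
    if rate <= 0:
        raise ConfigError(f"sampling rate must be positive, got {rate}")
    return 1000.0 / rate


@dataclass(frozen=True)
class StreamDescriptor:
    """Identity and sampling geometry of one ECG source."""

    stream_id: str
    rate: float
    device_id: str = ""
    lead_label: str = DEFAULT_LEAD_LABEL

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ConfigError(
                f"stream {self.stream_id!r}: rate must be positive, got {self.rate}"
            )


@dataclass(frozen=True)
class ValidationResult:
    accepted: bool
    reason: Optional[str] = None


def validate_stream(
    descriptor: StreamDescriptor,
    min_rate: float = DEFAULT_MIN_RATE,
) -> ValidationResult:
    """Accept a stream iff its sampling rate meets the pipeline minimum.

    Rejection is a value, not an exception: callers configured to warn
    instead of reject can proceed on a rejected stream at their own risk.
    """
    if descriptor.rate >= min_rate:
        return ValidationResult(True)
    return ValidationResult(
        False,
        f"stream {descriptor.stream_id!r}: rate {descriptor.rate:g} samples/s "
        f"is below the required minimum of {min_rate:g} samples/s",
    )


@dataclass(frozen=True)
class ECGPacket:
    """A timestamped bundle of consecutive voltage samples from one stream.

    Consecutive packets of a stream tile its signal: the next packet's
    ``t_start_ms`` equals this packet's ``t_end_ms``.
    """

    stream_id: str
    t_start_ms: float
    sample_period_ms: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float)
        )
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise DataError(
                f"stream {self.stream_id!r}: non-finite sample at "
                f"t={self.t_start_ms + bad * self.sample_period_ms:g} ms"
            )

    @property
    def t_end_ms(self) -> float:
        return self.t_start_ms + len(self.samples) * self.sample_period_ms


def packetize(
    samples: np.ndarray,
    rate: float,
    bundle_ms: float = DEFAULT_BUNDLE_MS,
    t0_ms: float = 0.0,
    stream_id: str = "stream",
) -> tuple[list[ECGPacket], np.ndarray]:
    """Split a sample sequence into fixed-duration packets.

    Returns ``(packets, remainder)``: the trailing partial bundle is
    withheld as ``remainder`` rather than emitted short, so a streaming
    caller can prepend it to the next chunk.  Concatenating the emitted
    packets plus the remainder reproduces the input exactly.

    Raises
    ------
    ConfigError
        If ``bundle_ms * rate / 1000`` is not a whole number of samples.
    DataError
        If any sample is non-finite.
    """
    if rate <= 0:
        raise ConfigError(f"rate must be positive, got {rate}")
    if bundle_ms <= 0:
        raise ConfigError(f"bundle_ms must be positive, got {bundle_ms}")
    n_per = bundle_ms * rate / 1000.0
    if abs(n_per - round(n_per)) > 1e-9 or round(n_per) < 1:
        raise ConfigError(
            f"bundle of {bundle_ms} ms at {rate} samples/s is not a whole "
            f"number of samples ({n_per:g})"
        )
    n_per = int(round(n_per))
    samples = np.asarray(samples, dtype=float)
    if samples.size and not np.all(np.isfinite(samples)):
        bad = int(np.flatnonzero(~np.isfinite(samples))[0])
        raise DataError(
            f"stream {stream_id!r}: non-finite sample at "
            f"t={t0_ms + bad * 1000.0 / rate:g} ms"
        )
    n_full = len(samples) // n_per
    period = 1000.0 / rate
    packets = [
        ECGPacket(
            stream_id=stream_id,
            t_start_ms=t0_ms + i * bundle_ms,
            sample_period_ms=period,
            samples=samples[i * n_per : (i + 1) * n_per],
        )
        for i in range(n_full)
    ]
    return packets, samples[n_full * n_per :].copy()


class Role(str, Enum):
    """The four monitored surgical-team roles."""

    SURGEON = "Surgeon"
    ANESTHESIOLOGIST = "Anesthesiologist"
    PERFUSIONIST = "Perfusionist"
    NURSE = "Nurse"


@dataclass(frozen=True)
class IBIRecord:
    """One inter-beat interval, stamped at the beat that closes it."""

    beat_time_ms: float
    ibi_ms: float
    accepted: bool = True

    def __post_init__(self) -> None:
        if self.ibi_ms <= 0:
            raise DataError(f"inter-beat interval must be positive, got {self.ibi_ms}")


@dataclass
class IBISeries:
    """Column-oriented sequence of inter-beat intervals for one stream.

    ``beat_time_ms[i]`` is the time of the beat *ending* interval ``i``;
    ``n`` detected beats yield ``n - 1`` intervals.  Rejected intervals
    stay in the series with ``accepted=False`` so downstream windows can
    skip them without losing the time base.
    """

    beat_time_ms: np.ndarray
    ibi_ms: np.ndarray
    accepted: np.ndarray
    stream_id: str = ""

    def __post_init__(self) -> None:
        self.beat_time_ms = np.asarray(self.beat_time_ms, dtype=float)
        self.ibi_ms = np.asarray(self.ibi_ms, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if not (len(self.beat_time_ms) == len(self.ibi_ms) == len(self.accepted)):
            raise DataError("IBISeries columns must have equal length")
        if np.any(self.ibi_ms <= 0):
            raise DataError("all inter-beat intervals must be positive")
        if len(self.beat_time_ms) > 1 and np.any(np.diff(self.beat_time_ms) <= 0):
            raise DataError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ibi_ms)

    @classmethod
    def empty(cls, stream_id: str = "") -> "IBISeries":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=bool), stream_id)

    @property
    def first_beat_time_ms(self) -> float:
        """Time of the first beat (opening the first interval)."""
        if len(self) == 0:
            raise DataError("empty IBI series has no beats")
        return float(self.beat_time_ms[0] - self.ibi_ms[0])

    def records(self) -> list[IBIRecord]:
        return [
            IBIRecord(float(t), float(v), bool(a))
            for t, v, a in zip(self.beat_time_ms, self.ibi_ms, self.accepted)
        ]


@dataclass
class SessionRoster:
    """Mapping from clinical role to stream, with a change log.

    Re-associating a role replaces the previous stream and records the
    change; each role holds at most one stream at a time.
    """

    streams: dict[str, StreamDescriptor] = field(default_factory=dict)
    assignments: dict[Role, str] = field(default_factory=dict)
    changes: list[tuple[Role, Optional[str], str]] = field(default_factory=list)

    def add_stream(self, descriptor: StreamDescriptor) -> None:
        if descriptor.stream_id in self.streams:
            raise ConfigError(f"duplicate stream id {descriptor.stream_id!r}")
        self.streams[descriptor.stream_id] = descriptor

    def associate(self, stream_id: str, role: Role) -> dict[Role, str]:
        if stream_id not in self.streams:
            raise ConfigError(f"unknown stream {stream_id!r}")
        previous = self.assignments.get(role)
        self.assignments[role] = stream_id
        if previous != stream_id:
            self.changes.append((role, previous, stream_id))
            if previous is not None:
                logger.info(
                    "role %s re-associated: %s -> %s", role.value, previous, stream_id
                )
        return dict(self.assignments)

    def stream_for(self, role: Role) -> Optional[str]:
        return self.assignments.get(role)


class Bus:
    """In-process publish/subscribe bus.

    Publications on a ``(topic, key)`` pair are delivered to subscribers
    in publication order; the latest publication is retained so a late
    subscriber immediately receives it.  ``key=None`` subscribes to every
    key of a topic (used by the session logger).
    """

    def __init__(self) -> None:
        self._subs: dict[tuple[str, Optional[str]], list[Callable]] = defaultdict(list)
        self._latest: dict[tuple[str, str], object] = {}

    def publish(self, topic: str, key: str, payload: object) -> None:
        self._latest[(topic, key)] = payload
        for cb in self._subs.get((topic, key), []):
            cb(payload)
        for cb in self._subs.get((topic, None), []):
            cb(payload)

    def subscribe(
        self, topic: str, key: Optional[str], callback: Callable[[object], None]
    ) -> None:
        self._subs[(topic, key)].append(callback)
        if key is not None and (topic, key) in self._latest:
            callback(self._latest[(topic, key)])

    def latest(self, topic: str, key: str) -> Optional[object]:
        return self._latest.get((topic, key))
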