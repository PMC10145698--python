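"""Session orchestration: wiring the six pipeline stages over the bus.

A session takes a set of stream sources (simulated, ECG CSV files, or
replayed IBI text), an optional role roster, and stage parameters; it
runs acquisition → filtering → beat detection → HRV metrics → load
estimation → alerting for every stream, publishing each stage's output
on the in-process bus and logging every publication with a coordinated
timestamp.  Replayed IBI streams enter directly at the metric stage.

Given the same config and seed, every output artifact is byte-identical
across runs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import io as thio
from .beat_detection import (
    DetectorConfig,
    detect_beats,
    ibi_artifact_filter,
    ibis_from_beats,
)
from .cognitive_load import (
    AlertEvent,
    CognitiveLoadEstimate,
    TeamAlert,
    calibrate_terciles,
    estimate_load,
    individual_alerts,
    team_alert,
)
from .core_model import (
    Bus,
    ConfigError,
    DataError,
    DEFAULT_BUNDLE_MS,
    DEFAULT_MIN_RATE,
    IBISeries,
    Role,
    SessionRoster,
    StreamDescriptor,
    packetize,
    validate_stream,
)
from .filtering import FilterChainSpec, apply_chain, preset
from .hrv_metrics import HRVMetrics, HRVWindowConfig, run_metric_engine
from .io import LogRecord
from .synthetic_ecg import (
    NoiseSpec,
    RRModulationSpec,
    add_noise,
    generate_rr_series,
    render_ecg,
)

TOPICS = (
    "ecg/raw", "ecg/filtered", "beats", "ibis", "metrics",
    "load", "alerts/individual", "alerts/team",
)

#: A member's estimate older than this is treated as stale for team scoring.
STALENESS_MS = 5000.0


@dataclass
class StreamSource:
    """Where one stream's data comes from.

    kind: ``simulate`` (synthetic ECG), ``csv`` (ECG sample file), or
    ``ibi-replay`` (IBI text file, bypassing stages 1–3).
    """

    stream_id: str
    kind: str = "simulate"
    path: Optional[str] = None
    rr: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("simulate", "csv", "ibi-replay"):
            raise ConfigError(
                f"stream {self.stream_id!r}: unknown source kind {self.kind!r}"
            )
        if self.kind in ("csv", "ibi-replay") and not self.path:
            raise ConfigError(f"stream {self.stream_id!r}: {self.kind} needs a path")


@dataclass
class SessionConfig:
    streams: list[StreamSource] = field(default_factory=list)
    roster: dict[Role, str] = field(default_factory=dict)
    bundle_ms: float = DEFAULT_BUNDLE_MS
    min_rate: float = DEFAULT_MIN_RATE
    on_low_rate: str = "reject"  # or "warn"
    filter_preset: str = "threestage"
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    window: HRVWindowConfig = field(default_factory=HRVWindowConfig)
    ibi_min_ms: float = 300.0
    ibi_max_ms: float = 2000.0
    ibi_max_rel_change: float = 0.2
    calibration_s: float = 300.0
    dwell_s: float = 10.0
    sum_threshold: int = 7
    red_count_threshold: int = 2
    duration_s: float = 120.0
    rate: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if not self.streams:
            raise ConfigError("a session needs at least one stream")
        if len(self.streams) > 8:
            raise ConfigError(
                f"at most 8 waveform streams per acquisition group, "
                f"got {len(self.streams)}"
            )
        ids = [s.stream_id for s in self.streams]
        if len(set(ids)) != len(ids):
            raise ConfigError("stream ids must be unique")
        if len(self.roster) > 4:
            raise ConfigError("at most 4 roster roles")
        for role, sid in self.roster.items():
            if sid not in ids:
                raise ConfigError(
                    f"roster role {role.value} refers to unknown stream {sid!r}"
                )
        if self.on_low_rate not in ("reject", "warn"):
            raise ConfigError("on_low_rate must be 'reject' or 'warn'")
        preset(self.filter_preset)  # raises on unknown preset

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SessionConfig":
        """Load a config from a flat YAML mapping (documented keys)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a key-value mapping")
        streams = [
            StreamSource(**s) if isinstance(s, dict) else StreamSource(stream_id=str(s))
            for s in raw.pop("streams", [])
        ]
        roster = {Role(k): v for k, v in (raw.pop("roles", {}) or {}).items()}
        det = DetectorConfig(**(raw.pop("detector", {}) or {}))
        win_kwargs = raw.pop("window", {}) or {}
        if "window_s" in raw:
            win_kwargs.setdefault("window_s", raw.pop("window_s"))
        window = HRVWindowConfig(**win_kwargs)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(streams=streams, roster=roster, detector=det, window=window, **raw)


@dataclass
class StreamResult:
    descriptor: StreamDescriptor
    series: IBISeries
    metrics: list[HRVMetrics]
    estimates: list[CognitiveLoadEstimate]
    alert_events: list[AlertEvent]
    truth_beat_times_ms: Optional[np.ndarray] = None


@dataclass
class SessionResult:
    config: SessionConfig
    roster: SessionRoster
    streams: dict[str, StreamResult]
    team_alerts: list[TeamAlert]
    log: list[LogRecord]
    out_dir: Optional[Path] = None


def replay_ibis(path: Union[str, Path], stream_id: str) -> IBISeries:
    """Load an IBI text file as a pipeline-ready series.

    Beat times are reconstructed cumulatively from t=0, so the first
    beat lands at the first interval's value.  An empty file yields an
    empty series (with a warning left to the caller's logging).
    """
    ibis = thio.read_ibi_text(path)
    if not ibis:
        return IBISeries.empty(stream_id)
    beats = np.cumsum(np.asarray(ibis, dtype=float))
    return IBISeries(
        beat_time_ms=beats,
        ibi_ms=np.asarray(ibis, dtype=float),
        accepted=np.ones(len(ibis), dtype=bool),
        stream_id=stream_id,
    )


def _acquire(
    source: StreamSource, config: SessionConfig, sub_seed: int
) -> tuple[Optional[StreamDescriptor], Optional[np.ndarray], Optional[IBISeries],
           Optional[np.ndarray]]:
    """Returns (descriptor, samples, replay_series, truth_beats)."""
    if source.kind == "ibi-replay":
        series = replay_ibis(source.path, source.stream_id)
        return None, None, series, None
    if source.kind == "csv":
        samples, rate, _t0 = thio.read_ecg_csv(source.path)
        desc = StreamDescriptor(stream_id=source.stream_id, rate=rate,
                                device_id=str(source.path))
        return desc, samples, None, None
    # simulate
    rr_kwargs = dict(source.rr)
    rr_kwargs.setdefault("mean_rr_ms", 800.0)
    rr_kwargs.setdefault("lf_amp_ms", 30.0)
    rr_kwargs.setdefault("hf_amp_ms", 30.0)
    rr_kwargs.setdefault("jitter_sd_ms", 10.0)
    rr_kwargs["seed"] = sub_seed
    spec = RRModulationSpec(**rr_kwargs)
    _rr, beats = generate_rr_series(spec, config.duration_s)
    phase = float(np.random.default_rng(sub_seed + 1).uniform(0, 1000.0 / config.rate))
    ecg = render_ecg(beats, config.rate, phase_offset_ms=phase,
                     duration_ms=config.duration_s * 1000.0)
    ecg = add_noise(ecg, config.rate, NoiseSpec(**source.noise), seed=sub_seed + 2)
    desc = StreamDescriptor(stream_id=source.stream_id, rate=config.rate,
                            device_id="simulated")
    return desc, ecg, None, beats + phase


def run_session(
    config: SessionConfig, out_dir: Optional[Union[str, Path]] = None
) -> SessionResult:
    """Run the full pipeline for every configured stream.

    Config validation happens up front; no data is touched on error.
    When ``out_dir`` is given, per-stream IBI and metric CSVs, an alert
    JSONL and the full session log are written there.
    """
    config.validate()
    bus = Bus()
    log: list[LogRecord] = []

    def _logger(topic: str):
        def cb(payload) -> None:
            log.append(
                LogRecord(
                    time_ms=float(payload.get("time_ms", 0.0)),
                    topic=topic,
                    payload=payload,
                )
            )
        return cb

    for topic in TOPICS:
        bus.subscribe(topic, None, _logger(topic))

    roster = SessionRoster()
    chain: FilterChainSpec = preset(config.filter_preset)
    sub_seeds = [
        int(c.generate_state(1)[0] % (2**31))
        for c in np.random.SeedSequence(config.seed).spawn(len(config.streams))
    ]
    results: dict[str, StreamResult] = {}

    for source, sub_seed in zip(config.streams, sub_seeds):
        sid = source.stream_id
        desc, samples, replay_series, truth = _acquire(source, config, sub_seed)
        if replay_series is not None:
            series = replay_series
            desc = StreamDescriptor(stream_id=sid, rate=config.rate,
                                    device_id=str(source.path))
            roster.add_stream(desc)
            bus.publish("ibis", sid, {
                "time_ms": float(series.beat_time_ms[-1]) if len(series) else 0.0,
                "stream_id": sid, "n_ibis": len(series),
                "ibi_ms": thio._jsonable(series.ibi_ms),
            })
        else:
            decision = validate_stream(desc, config.min_rate)
            if not decision.accepted:
                if config.on_low_rate == "reject":
                    raise ConfigError(decision.reason)
            roster.add_stream(desc)
            packets, _remainder = packetize(
                samples, desc.rate, config.bundle_ms, t0_ms=0.0, stream_id=sid
            )
            emitted = np.concatenate([p.samples for p in packets]) if packets else (
                np.empty(0)
            )
            for p in packets:
                bus.publish("ecg/raw", sid, {
                    "time_ms": p.t_start_ms, "stream_id": sid,
                    "n_samples": len(p.samples),
                    "samples_mv": [round(float(v), 4) for v in p.samples],
                })
            filtered = apply_chain(emitted, desc.rate, chain)
            fpackets, _ = packetize(filtered, desc.rate, config.bundle_ms,
                                    t0_ms=0.0, stream_id=sid)
            for p in fpackets:
                bus.publish("ecg/filtered", sid, {
                    "time_ms": p.t_start_ms, "stream_id": sid,
                    "n_samples": len(p.samples),
                    "samples_mv": [round(float(v), 4) for v in p.samples],
                })
            beats = detect_beats(filtered, desc.rate, config.detector)
            bus.publish("beats", sid, {
                "time_ms": float(beats[-1]) if len(beats) else 0.0,
                "stream_id": sid, "beat_times_ms": thio._jsonable(beats),
            })
            series = ibi_artifact_filter(
                ibis_from_beats(beats, stream_id=sid),
                config.ibi_min_ms, config.ibi_max_ms, config.ibi_max_rel_change,
            )
            bus.publish("ibis", sid, {
                "time_ms": float(series.beat_time_ms[-1]) if len(series) else 0.0,
                "stream_id": sid, "n_ibis": len(series),
                "n_rejected": int((~series.accepted).sum()),
            })

        metrics = run_metric_engine(series, config.window, stream_id=sid)
        for m in metrics:
            bus.publish("metrics", sid, {
                "time_ms": m.window_end_ms, "stream_id": sid,
                "mean_hr_bpm": thio._jsonable(m.mean_hr_bpm),
                "sdnn_ms": thio._jsonable(m.sdnn_ms),
                "rmssd_ms": thio._jsonable(m.rmssd_ms),
                "lf_ms2": thio._jsonable(m.lf_power_ms2),
                "hf_ms2": thio._jsonable(m.hf_power_ms2),
                "lf_hf": thio._jsonable(m.lf_hf_ratio),
                "n_beats": m.n_beats, "valid": m.valid,
            })

        # Stage 5: per-clinician calibration then load estimation.
        t_anchor = metrics[0].window_end_ms if metrics else 0.0
        calib_end = t_anchor + config.calibration_s * 1000.0
        calib_values = [
            m.lf_hf_ratio for m in metrics
            if m.valid and m.window_end_ms <= calib_end
        ]
        bounds = calibrate_terciles(calib_values, stream_id=sid)
        estimates = [
            estimate_load(
                m.lf_hf_ratio if m.valid else math.nan, bounds,
                time_ms=m.window_end_ms, stream_id=sid,
            )
            for m in metrics
        ]
        for est in estimates:
            bus.publish("load", sid, {
                "time_ms": est.time_ms, "stream_id": sid,
                "level": est.level.name.lower() if est.level else None,
                "score": est.score, "lf_hf": thio._jsonable(est.lf_hf),
                "valid": est.valid,
            })
        events = individual_alerts(estimates, dwell_s=config.dwell_s)
        for ev in events:
            bus.publish("alerts/individual", sid, {
                "time_ms": ev.time_ms, "stream_id": sid, "kind": "individual",
                "active": ev.active,
            })
        results[sid] = StreamResult(
            descriptor=desc, series=series, metrics=metrics,
            estimates=estimates, alert_events=events, truth_beat_times_ms=truth,
        )

    for role, sid in config.roster.items():
        roster.associate(sid, role)

    team_alerts = _evaluate_team(config, roster, results, bus)

    result = SessionResult(
        config=config, roster=roster, streams=results,
        team_alerts=team_alerts, log=log,
        out_dir=Path(out_dir) if out_dir else None,
    )
    if out_dir is not None:
        _write_outputs(result)
    return result


def _evaluate_team(
    config: SessionConfig,
    roster: SessionRoster,
    results: dict[str, StreamResult],
    bus: Bus,
) -> list[TeamAlert]:
    """Score the rostered members on a common 1 Hz session timeline."""
    if not roster.assignments:
        return []
    stamps = [
        m.window_end_ms
        for sid in roster.assignments.values()
        for m in results[sid].metrics
    ]
    if not stamps:
        return []
    step = config.window.update_period_s * 1000.0
    t0, t1 = min(stamps), max(stamps)
    alerts: list[TeamAlert] = []
    t = t0
    while t <= t1 + 1e-9:
        scores: dict[Role, Optional[int]] = {}
        for role, sid in roster.assignments.items():
            score = None
            for est in reversed(results[sid].estimates):
                if est.time_ms <= t + 1e-9:
                    if est.valid and t - est.time_ms <= STALENESS_MS:
                        score = est.score
                    break
            scores[role] = score
        alert = team_alert(
            scores, time_ms=t,
            sum_threshold=config.sum_threshold,
            red_count_threshold=config.red_count_threshold,
        )
        alerts.append(alert)
        bus.publish("alerts/team", "team", {
            "time_ms": t, "kind": "team", "active": alert.active,
            "reason": list(alert.reasons),
            "scores": {r: s for r, s in alert.member_scores},
            "sum": alert.sum, "degraded": alert.degraded,
        })
        t += step
    return alerts


def _write_outputs(result: SessionResult) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    for sid, sr in result.streams.items():
        thio.write_ibi_csv(out / f"ibis_{sid}.csv", sr.series)
        thio.write_metrics_csv(out / f"metrics_{sid}.csv", sr.metrics)
        if sr.truth_beat_times_ms is not None:
            thio.write_beat_times_csv(
                out / f"truth_beats_{sid}.csv", sr.truth_beat_times_ms
            )
    alert_records = [
        rec for rec in result.log
        if rec.topic in ("alerts/individual", "alerts/team")
    ]
    thio.write_log(out / "alerts.jsonl", alert_records)
    thio.write_log(out / "session.jsonl", result.log)
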