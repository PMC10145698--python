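"""Synthetic multi-clinician ECG with known ground truth.

The generator produces Lead-II-like waveforms whose beat times and RR
spectral content are known exactly, so the downstream detector and HRV
metrics can be scored against ground truth.  The RR model is a pair of
additive sinusoids — one in the low-frequency band (0.04–0.15 Hz, the
sympathetic/baroreflex range) and one in the high-frequency band
(0.15–0.40 Hz, respiratory sinus arrhythmia) — plus white jitter:

    RR_n = mean_rr + lf_amp·sin(2π·lf_freq·t_n)
                   + hf_amp·sin(2π·hf_freq·t_n) + ε_n,

with t_n the cumulative time of beat n and ε_n ~ N(0, jitter_sd²).
Band powers of the generated series are therefore analytically known
(a sinusoid of amplitude A contributes A²/2 of variance to its band).

Each beat is rendered as a Gaussian-sum PQRST template whose R wave is
the unique global maximum; measurement noise (baseline wander, powerline
hum, white noise, electrode dropouts) is added separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core_model import ConfigError, DataError, StreamDescriptor


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump of the beat template (amplitude mV, offsets ms)."""

    amp_mv: float
    center_ms: float
    sigma_ms: float


#: Default PQRST morphology: R is the dominant positive peak; P and T are
#: broad low bumps; Q and S are narrow negative notches flanking R.
PQRST_TEMPLATE: tuple[WaveComponent, ...] = (
    WaveComponent(0.12, -160.0, 18.0),   # P
    WaveComponent(-0.12, -22.0, 5.0),    # Q
    WaveComponent(1.10, 0.0, 9.0),       # R
    WaveComponent(-0.18, 20.0, 5.0),     # S
    WaveComponent(0.32, 155.0, 28.0),    # T
)

#: Single narrow spike, for worst-case filter tests.
SPIKE_TEMPLATE: tuple[WaveComponent, ...] = (WaveComponent(1.0, 0.0, 1.5),)


def template_support_ms(template: Sequence[WaveComponent]) -> float:
    """Half-width of the template's support (centers ± 4 sigma)."""
    return max(abs(c.center_ms) + 4.0 * c.sigma_ms for c in template)


@dataclass(frozen=True)
class RRModulationSpec:
    """Parameters of the two-sinusoid RR model for one simulated person."""

    mean_rr_ms: float = 800.0
    lf_amp_ms: float = 0.0
    lf_freq_hz: float = 0.1
    hf_amp_ms: float = 0.0
    hf_freq_hz: float = 0.25
    jitter_sd_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.04 <= self.lf_freq_hz < 0.15):
            raise ConfigError(
                f"lf_freq_hz must lie in [0.04, 0.15), got {self.lf_freq_hz}"
            )
        if not (0.15 <= self.hf_freq_hz <= 0.40):
            raise ConfigError(
                f"hf_freq_hz must lie in [0.15, 0.40], got {self.hf_freq_hz}"
            )
        if min(self.lf_amp_ms, self.hf_amp_ms, self.jitter_sd_ms) < 0:
            raise ConfigError("modulation amplitudes must be non-negative")
        # Keeps every generated interval positive (4-sigma jitter margin).
        if self.mean_rr_ms <= self.lf_amp_ms + self.hf_amp_ms + 4 * self.jitter_sd_ms:
            raise ConfigError(
                "mean_rr_ms must exceed lf_amp + hf_amp + 4*jitter_sd "
                "so intervals stay positive"
            )


def generate_rr_series(
    spec: RRModulationSpec, duration_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Generate an RR sequence and cumulative beat times (both ms).

    The modulation is evaluated at the cumulative beat time of the
    previous beat; beats are emitted until the next one would exceed
    ``duration_s``.  Deterministic for a fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    duration_ms = duration_s * 1000.0
    rr: list[float] = []
    t = 0.0
    while True:
        t_s = t / 1000.0
        rr_n = (
            spec.mean_rr_ms
            + spec.lf_amp_ms * np.sin(2 * np.pi * spec.lf_freq_hz * t_s)
            + spec.hf_amp_ms * np.sin(2 * np.pi * spec.hf_freq_hz * t_s)
            + rng.normal(0.0, spec.jitter_sd_ms)
        )
        if rr_n <= 0:
            raise DataError("generated a non-positive RR interval")
        if t + rr_n > duration_ms:
            break
        t += rr_n
        rr.append(rr_n)
    if not rr:
        raise DataError(
            f"duration {duration_s} s too short for a single beat of "
            f"~{spec.mean_rr_ms} ms"
        )
    rr_arr = np.asarray(rr)
    return rr_arr, np.cumsum(rr_arr)


def generate_uniform_rr(
    duration_s: float,
    low_ms: float = 700.0,
    high_ms: float = 1000.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """RR intervals drawn i.i.d. uniform on [low_ms, high_ms].

    A broadband alternative to the sinusoidal model, used for detector
    timing benchmarks: cumulative beat times land at arbitrary sub-sample
    phases of any sampling grid.
    """
    if high_ms <= low_ms or low_ms <= 0:
        raise ConfigError("need 0 < low_ms < high_ms")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # Draw in blocks until the cumulative time exceeds the duration.
    duration_ms = duration_s * 1000.0
    n_guess = int(duration_ms / low_ms) + 2
    rr = rng.uniform(low_ms, high_ms, size=n_guess)
    t = np.cumsum(rr)
    keep = t <= duration_ms
    if not keep.any():
        raise DataError("duration too short for a single beat")
    return rr[keep], t[keep]


def render_ecg(
    beat_times_ms: np.ndarray,
    rate: float,
    template: Sequence[WaveComponent] = PQRST_TEMPLATE,
    phase_offset_ms: float = 0.0,
    duration_ms: Optional[float] = None,
) -> np.ndarray:
    """Render beat times into a sampled voltage sequence (mV).

    One template instance is centered at each ``beat_time + phase_offset``;
    because the R component dominates, the global maximum of each beat's
    window falls within one sample of that center.

    Raises
    ------
    DataError
        If beat times are not strictly increasing, or consecutive beats
        are closer than the template support (instances would overlap).
    """
    if rate <= 0:
        raise ConfigError(f"rate must be positive, got {rate}")
    beat_times_ms = np.asarray(beat_times_ms, dtype=float)
    period = 1000.0 / rate
    half = template_support_ms(template)
    if duration_ms is None:
        duration_ms = (beat_times_ms[-1] + phase_offset_ms + half) if len(
            beat_times_ms
        ) else 0.0
    n = int(np.ceil(duration_ms * rate / 1000.0))
    x = np.zeros(n)
    if len(beat_times_ms) == 0:
        return x
    if len(beat_times_ms) > 1:
        d = np.diff(beat_times_ms)
        if np.any(d <= 0):
            raise DataError("beat times must be strictly increasing")
        if np.any(d < 2 * half):
            raise DataError(
                f"beats closer than the template support ({2 * half:g} ms): "
                "instances would overlap"
            )
    for b in beat_times_ms:
        center = b + phase_offset_ms
        lo = max(0, int(np.floor((center - half) / period)))
        hi = min(n, int(np.ceil((center + half) / period)) + 1)
        if hi <= lo:
            continue
        t = np.arange(lo, hi) * period
        for c in template:
            x[lo:hi] += c.amp_mv * np.exp(
                -0.5 * ((t - center - c.center_ms) / c.sigma_ms) ** 2
            )
    return x


@dataclass(frozen=True)
class NoiseSpec:
    """Additive measurement-noise model (all amplitudes in mV).

    ``dropout`` intervals emulate transient electrode disconnection: the
    signal is zeroed over each ``(start_ms, duration_ms)`` span.
    """

    baseline_amp_mv: float = 0.0
    baseline_freq_hz: float = 0.25
    powerline_amp_mv: float = 0.0
    powerline_freq_hz: float = 60.0
    white_sd_mv: float = 0.0
    dropout: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if min(self.baseline_amp_mv, self.powerline_amp_mv, self.white_sd_mv) < 0:
            raise ConfigError("noise amplitudes must be non-negative")


def add_noise(
    ecg: np.ndarray, rate: float, spec: NoiseSpec, seed: int = 0
) -> np.ndarray:
    """Add baseline wander, powerline hum, white noise and dropouts."""
    x = np.asarray(ecg, dtype=float).copy()
    n = len(x)
    t_s = np.arange(n) / rate
    if spec.baseline_amp_mv > 0:
        x += spec.baseline_amp_mv * np.sin(2 * np.pi * spec.baseline_freq_hz * t_s)
    if spec.powerline_amp_mv > 0:
        x += spec.powerline_amp_mv * np.sin(2 * np.pi * spec.powerline_freq_hz * t_s)
    if spec.white_sd_mv > 0:
        rng = np.random.default_rng(seed)
        x += rng.normal(0.0, spec.white_sd_mv, size=n)
    duration_ms = n * 1000.0 / rate
    for start_ms, dur_ms in spec.dropout:
        if start_ms < 0 or start_ms + dur_ms > duration_ms:
            raise DataError(
                f"dropout ({start_ms}, {dur_ms}) ms lies outside the "
                f"{duration_ms:g} ms signal"
            )
        i0 = int(np.floor(start_ms * rate / 1000.0))
        i1 = int(np.ceil((start_ms + dur_ms) * rate / 1000.0))
        x[i0:i1] = 0.0
    return x


@dataclass
class MemberStream:
    """One simulated clinician: descriptor, samples and ground truth."""

    descriptor: StreamDescriptor
    samples: np.ndarray
    beat_times_ms: np.ndarray
    rr_ms: np.ndarray
    rr_spec: RRModulationSpec
    noise_spec: NoiseSpec


@dataclass
class TeamSession:
    members: dict[str, MemberStream] = field(default_factory=dict)
    rate: float = 500.0
    duration_s: float = 120.0
    seed: int = 0


def make_team_session(
    n_members: int,
    duration_s: float = 120.0,
    rate: float = 500.0,
    seed: int = 0,
    rr_specs: Optional[Sequence[RRModulationSpec]] = None,
    noise_specs: Optional[Sequence[NoiseSpec]] = None,
    template: Sequence[WaveComponent] = PQRST_TEMPLATE,
) -> TeamSession:
    """Simulate a team of independent ECG streams with retained ground truth.

    Each member gets a distinct sub-seed spawned from ``seed``.  Default
    per-member RR specs use a resting mean of 800 ms with moderate LF and
    HF modulation (30 ms each) and 10 ms white jitter — an unremarkable
    awake adult; defaults are noise-free so detector accuracy can be read
    against ground truth, with noise opt-in per member.
    """
    if not 1 <= n_members <= 8:
        raise ConfigError(
            f"n_members must be between 1 and 8 (acquisition-group capacity), "
            f"got {n_members}"
        )
    children = np.random.SeedSequence(seed).spawn(n_members)
    session = TeamSession(rate=rate, duration_s=duration_s, seed=seed)
    for i in range(n_members):
        sub_seed = int(children[i].generate_state(1)[0] % (2**31))
        if rr_specs is not None:
            spec = replace(rr_specs[i], seed=sub_seed)
        else:
            spec = RRModulationSpec(
                mean_rr_ms=800.0,
                lf_amp_ms=30.0,
                hf_amp_ms=30.0,
                jitter_sd_ms=10.0,
                seed=sub_seed,
            )
        noise = noise_specs[i] if noise_specs is not None else NoiseSpec()
        rr, beats = generate_rr_series(spec, duration_s)
        # Sub-sample phase offset keeps true beat times off the sample grid.
        phase = float(
            np.random.default_rng(sub_seed + 1).uniform(0, 1000.0 / rate)
        )
        ecg = render_ecg(
            beats, rate, template=template, phase_offset_ms=phase,
            duration_ms=duration_s * 1000.0,
        )
        ecg = add_noise(ecg, rate, noise, seed=sub_seed + 2)
        sid = f"member-{i + 1}"
        session.members[sid] = MemberStream(
            descriptor=StreamDescriptor(stream_id=sid, rate=rate, device_id=f"sim-{i + 1}"),
            samples=ecg,
            beat_times_ms=beats + phase,
            rr_ms=rr,
            rr_spec=spec,
            noise_spec=noise,
        )
    return session
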