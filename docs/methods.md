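# Methods

## Signal model and session clock

All stages share one monotonic session clock in milliseconds. An ECG stream
is a uniform-rate sequence of Lead II voltages (mV); acquisition bundles it
into fixed-duration packets (default 250 ms; a rate/bundle combination that
is not a whole number of samples is rejected rather than padded, preserving
the exact tiling invariant: emitted packets plus the withheld remainder
reproduce the input). Streams below 500 samples/s are rejected by default
(configurable to warn-only for archival replays): the R peak is located to
within about one sample, so at lower rates the ±2-sample-period interval
error becomes comparable to the beat-to-beat variability being measured.

## Synthetic ECG generator

The generator exists to provide exact ground truth, not physiological
realism. RR intervals follow an additive two-sinusoid model

    RR_n = mean_rr + lf_amp·sin(2π f_LF t_n) + hf_amp·sin(2π f_HF t_n) + ε_n

evaluated at the cumulative beat time t_n of the previous beat, with
ε_n ~ N(0, jitter_sd²). An additive model was chosen over integral-pulse
frequency modulation because the band powers of the generated series are
analytically known (a sinusoid of amplitude A carries A²/2 of variance into
its band), which makes spectral recovery testable without a second
estimator. Defaults for a simulated team member are mean_rr = 800 ms
(75 bpm, resting adult), 30 ms LF and HF amplitudes at 0.1 / 0.25 Hz and
10 ms jitter — mid-range resting values; the spec invariant
mean_rr > lf_amp + hf_amp + 4·jitter_sd keeps intervals positive.

Beats are rendered as a five-Gaussian PQRST template whose R component
(1.1 mV, σ = 9 ms) dominates, so the global maximum of each beat window is
within one sample of the true beat time; a single-spike template is provided
for worst-case filter tests. Rendering extends (by default) one template
support past the final beat so every true peak is actually in the signal.
Measurement noise is additive and separately seeded: baseline wander and
powerline sinusoids, white noise, and zeroed dropout intervals.

What the generator does **not** emulate: ectopy and arrhythmia, respiratory
amplitude modulation, electrode-motion transients with realistic spectra,
inter-lead differences. Tests passing on this model therefore demonstrate
the pipeline's numerical correctness and its noise robustness to the modeled
disturbances — not clinical validity of the load estimates, which would
require annotated OR recordings.

## Filtering

Three interchangeable ECG→ECG stages, each length- and rate-preserving so
they can be chained in any order (presets `threestage` and `none`):

- **Wavelet denoising** — db4, level 4, soft universal threshold
  σ̂·√(2 ln N) with σ̂ = MAD(finest detail)/0.6745. On a clean signal σ̂ ≈ 0
  and the stage is near-identity.
- **High-pass** — causal second-order Butterworth at 0.5 Hz (DC and baseline
  wander). Causality keeps the stage streaming-capable; its group delay in
  the QRS band is far below one sample period, and any constant delay
  cancels when intervals are differenced, so no beat-time correction is
  applied.
- **Non-linear low-pass** — running median, kernel 5 samples at 500 Hz
  (scaled with rate, kept odd). Boundaries use edge replication, the padding
  under which a monotone signal passes unchanged for every kernel width;
  reflective padding fails that identity at kernel ≥ 5.

Filters are applied per record (batch) inside the session runner rather than
in overlapping streaming blocks; the stages themselves are causal or
symmetric, so a streaming deployment only adds a fixed warm-up, not
different numbers.

## Beat detection

The detector thresholds at `threshold_fraction` (default 0.6) of the rolling
maximum over the trailing `lookback_s` (default 10 s; O(n) block prefix/
suffix maxima). The fraction 0.6 clears the largest non-R wave of the
default template (T, 0.32/1.10 ≈ 0.29) with margin, and a purely relative
threshold makes detection invariant to amplitude scaling. While above
threshold, the first sign change of the first difference (plateaus: first
sample) marks the beat; a 250 ms refractory period (~240 bpm ceiling)
suppresses double fires.

Cold start: the first lookback window is buffered and its maximum used as
the threshold reference. A max-seen-so-far reference cannot work — before
the first R peak, any positive local maximum (the P wave, filter ringing)
exceeds 0.6 of its own running maximum and fires, and the refractory period
then masks the true first beat.

The IBI plausibility filter rejects intervals outside 300–2000 ms or
differing from the last accepted interval by more than 20 %; rejects are
flagged, never deleted, so the time base and downstream window selection
survive artifact bursts.

## HRV metrics

Windows are right-aligned and half-open on the left, stamped at the window
end, emitted every update period (default 1 s) on a grid anchored at the
stream's first beat; emissions whose window has not fully elapsed, has fewer
than `min_beats` (default 10) accepted intervals, or has HF power below
1e−6 ms² are flagged invalid rather than skipped, so the cadence is exactly
one record per second. Anchoring at the first beat makes metric values
invariant to a constant time shift, which is what lets a replayed IBI file
(beat times rebuilt cumulatively from zero) reproduce the original metric
values exactly.

Definitions: mean HR = 60000/mean(IBI) (the mean-interval convention);
SDNN with the sample (n−1) denominator; RMSSD over successive differences.
Spectral powers use a least-squares (Lomb) periodogram of the mean-subtracted
intervals at their actual beat times — uneven-base analysis avoids the
interpolation bias of resample-and-FFT on ultra-short windows — scaled to a
one-sided density (factor 2·span/n, under which an amplitude-A sinusoid's
band integral recovers its variance A²/2) and integrated by the trapezoid
rule on 512-point grids per band. The LF grid is half-open at 0.15 Hz so the
shared band edge is counted once, in HF.

## Cognitive load and alerts

Tercile boundaries are the empirical 1/3 and 2/3 quantiles (linear
interpolation) of at least nine valid LF/HF values. The default reference is
per-clinician calibration over the first five minutes of valid metrics —
within-subject referencing matches the personalized-workload framing, and a
population reference is deliberately not claimed; the boundaries object also
accepts a rolling source. Boundary ties promote upward (a value exactly at a
boundary takes the higher tercile): deterministic, and alerts err toward
sensitivity. Levels map to scores 1/2/3.

Individual alerts raise after the level has been high for a continuous dwell
(default 10 s, stamped at run start + dwell) and clear after an equally long
run at or below medium; invalid estimates interrupt both runs. Team alarms
are evaluated on the shared 1 Hz timeline using each rostered member's most
recent estimate (stale after 5 s): active iff the valid scores sum to ≥ 7 or
at least two members score 3. Members with invalid estimates are excluded
from both conditions — not imputed — and the alert is flagged degraded when
fewer than four members contribute. With four valid members the two-red
condition is mathematically implied by the sum rule at the default
thresholds (two 3s force a sum ≥ 8); both reasons are still recorded.

## Numerical and design notes

- All randomness flows through `numpy.random.SeedSequence` spawns of a
  single session seed; identical config + seed yields byte-identical output
  files (fixed float formatting in CSV/JSONL writers).
- Degenerate inputs: empty packetizer input → no packets; an all-zero signal
  → no beats; a constant IBI window → zero SDNN/RMSSD and ≈0 band powers;
  zero HF power → LF/HF undefined and the window invalid.
- The window length is fixed per session run; changing it mid-session is not
  supported (restart the session instead).
- A mid-session sampling-rate change is treated as a new stream epoch
  (re-validate, re-packetize); the detector state does not carry over.
- Benchmark problem sizes: the beat-timing benchmark uses 100 records ×
  120 s at 500 samples/s (≈14,000 intervals), spectral recovery uses 20
  seeds × 300 s windows, and oracle-equivalence checks use 1000 random
  windows — large enough that the measured maxima are stable across seeds
  while keeping the whole suite fast.

## Known limitations

- The cognitive-load mapping is a monotone transform of LF/HF with
  within-subject terciles; its clinical validity against annotated
  operating-room data is untested here and cannot be established with
  synthetic inputs.
- The detector assumes a zero-baseline, positive-R signal after the
  high-pass stage; inverted leads would need a polarity check upstream.
- The in-process bus preserves the publish/subscribe contract (per-key
  ordering, latest-value delivery to late subscribers) but is not a network
  transport; distribution, discovery and QoS are out of scope.
- The IBI artifact filter is a range/step heuristic, not beat-morphology
  classification; sustained artifact runs can re-anchor its reference.
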