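import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from teamhrv import (
    ConfigError,
    HRVWindowConfig,
    IBISeries,
    RRModulationSpec,
    generate_rr_series,
    lf_hf,
    mean_hr,
    rmssd,
    run_metric_engine,
    sdnn,
    select_window,
    spectral_powers,
)


def make_series(ibis, t0=0.0):
    ibis = np.asarray(ibis, dtype=float)
    return IBISeries(t0 + np.cumsum(ibis), ibis, np.ones(len(ibis), dtype=bool))


class TestWindowSelection:
    def test_only_final_window_selected(self):
        series = make_series([1000.0] * 120)  # beats spanning 120 s
        times, ibis = select_window(series, end_ms=120_000.0, window_s=60.0)
        assert len(ibis) == 60
        assert times.min() > 60_000.0 and times.max() == 120_000.0

    @pytest.mark.parametrize("window_s", [5.0, 9.99, 300.1, 400.0])
    def test_window_outside_allowed_range_is_error(self, window_s):
        series = make_series([1000.0] * 20)
        with pytest.raises(ConfigError):
            select_window(series, 20_000.0, window_s)
        with pytest.raises(ConfigError):
            HRVWindowConfig(window_s=window_s)

    @pytest.mark.parametrize("window_s", [10.0, 60.0, 300.0])
    def test_allowed_range_boundaries_accepted(self, window_s):
        HRVWindowConfig(window_s=window_s)
        series = make_series([1000.0] * 20)
        select_window(series, 20_000.0, window_s)

    def test_empty_series_gives_empty_selection(self):
        times, ibis = select_window(IBISeries.empty(), 60_000.0, 60.0)
        assert len(ibis) == 0

    def test_rejected_intervals_excluded(self):
        series = make_series([800.0] * 20)
        series.accepted[5] = False
        _, ibis = select_window(series, series.beat_time_ms[-1], 60.0)
        assert len(ibis) == 19

    @given(
        end_s=st.floats(20.0, 120.0),
        w1=st.floats(10.0, 300.0),
        w2=st.floats(10.0, 300.0),
    )
    def test_enlarging_window_never_removes_beats(self, end_s, w1, w2):
        series = make_series([750.0] * 150)
        small, large = sorted([w1, w2])
        _, ibis_small = select_window(series, end_s * 1000, small)
        _, ibis_large = select_window(series, end_s * 1000, large)
        assert set(ibis_small).issubset(set(ibis_large))
        assert len(ibis_large) >= len(ibis_small)


class TestTimeDomainMetrics:
    @pytest.mark.parametrize(
        "ibis,expected",
        [([800.0] * 4, 75.0), ([1000.0] * 3, 60.0), ([800.0, 1200.0], 60.0)],
    )
    def test_mean_hr(self, ibis, expected):
        assert mean_hr(ibis) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ibis,expected",
        [
            ([800.0] * 5, 0.0),
            ([800.0, 820.0, 780.0, 800.0], math.sqrt(800.0 / 3.0)),
            ([800.0, 820.0], math.sqrt(200.0)),
        ],
    )
    def test_sdnn(self, ibis, expected):
        assert sdnn(ibis) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "ibis,expected",
        [
            ([800.0] * 5, 0.0),
            ([800.0, 810.0, 790.0], math.sqrt((10**2 + 20**2) / 2.0)),
        ],
    )
    def test_rmssd(self, ibis, expected):
        assert rmssd(ibis) == pytest.approx(expected, abs=1e-9)

    def test_undefined_below_minimum_counts(self):
        assert math.isnan(mean_hr([]))
        assert math.isnan(sdnn([800.0]))
        assert math.isnan(rmssd([800.0]))

    @given(st.lists(st.floats(300.0, 2000.0), min_size=2, max_size=50))
    def test_rmssd_symmetric_under_reversal(self, ibis):
        assert rmssd(ibis) == pytest.approx(rmssd(ibis[::-1]), rel=1e-12)

    def test_agreement_with_brute_force_oracle(self):
        # direct-formula oracle evaluated with plain Python arithmetic
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(2, 120))
            ibis = rng.uniform(400.0, 1500.0, size=n)
            mean_oracle = 60000.0 / (sum(ibis) / n)
            mu = sum(ibis) / n
            sd_oracle = math.sqrt(sum((v - mu) ** 2 for v in ibis) / (n - 1))
            dif = [b - a for a, b in zip(ibis, ibis[1:])]
            rms_oracle = math.sqrt(sum(d * d for d in dif) / len(dif))
            assert mean_hr(ibis) == pytest.approx(mean_oracle, rel=1e-9)
            assert sdnn(ibis) == pytest.approx(sd_oracle, rel=1e-9)
            assert rmssd(ibis) == pytest.approx(rms_oracle, rel=1e-9)


class TestSpectralPowers:
    def test_constant_series_has_no_power(self):
        series = make_series([800.0] * 100)
        lf, hf = spectral_powers(series.beat_time_ms, series.ibi_ms)
        assert lf <= 1e-9 and hf <= 1e-9

    def test_lf_only_modulation_dominates(self):
        spec = RRModulationSpec(mean_rr_ms=800.0, lf_amp_ms=50.0, seed=2)
        rr, beats = generate_rr_series(spec, 300.0)
        lf, hf = spectral_powers(beats, rr)
        assert lf / hf > 10.0
        # a sinusoid of amplitude A carries A^2/2 = 1250 ms^2 of variance
        assert lf == pytest.approx(1250.0, rel=0.15)

    def test_balanced_modulation_gives_unit_ratio(self):
        spec = RRModulationSpec(
            mean_rr_ms=800.0, lf_amp_ms=30.0, hf_amp_ms=30.0, seed=2
        )
        rr, beats = generate_rr_series(spec, 300.0)
        lf, hf = spectral_powers(beats, rr)
        assert 0.8 <= lf / hf <= 1.25

    def test_too_few_beats_is_undefined(self):
        series = make_series([800.0] * 5)
        lf, hf = spectral_powers(series.beat_time_ms, series.ibi_ms, min_beats=10)
        assert math.isnan(lf) and math.isnan(hf)

    def test_single_band_recovery_across_seeds(self):
        for seed in range(10):
            spec = RRModulationSpec(mean_rr_ms=800.0, lf_amp_ms=40.0,
                                    jitter_sd_ms=5.0, seed=seed)
            rr, beats = generate_rr_series(spec, 300.0)
            lf, hf = spectral_powers(beats, rr)
            assert lf > 10.0 * hf


class TestLFHF:
    def test_simple_ratio(self):
        assert lf_hf(4.0, 2.0) == 2.0

    @pytest.mark.parametrize("lf,hf", [(0.0, 0.0), (5.0, 0.0), (5.0, 1e-9)])
    def test_degenerate_hf_is_undefined(self, lf, hf):
        assert math.isnan(lf_hf(lf, hf))

    def test_negative_power_is_internal_error(self):
        with pytest.raises(ValueError):
            lf_hf(-1.0, 2.0)


class TestMetricEngine:
    def test_one_metric_per_second_after_first_full_window(self):
        spec = RRModulationSpec(mean_rr_ms=800.0, lf_amp_ms=30.0,
                                hf_amp_ms=30.0, jitter_sd_ms=10.0, seed=9)
        rr, beats = generate_rr_series(spec, 120.0)
        series = make_series(rr, t0=beats[0] - rr[0])
        config = HRVWindowConfig(window_s=60.0, update_period_s=1.0)
        metrics = run_metric_engine(series, config)
        stamps = np.array([m.window_end_ms for m in metrics])
        np.testing.assert_allclose(np.diff(stamps), 1000.0)
        full = [m for m in metrics if m.valid]
        assert len(full) >= 55  # everything past the 60 s warm-up
        # warm-up windows are emitted but flagged invalid
        assert all(not m.valid for m in metrics[:59])

    def test_short_stream_emits_only_invalid_metrics(self):
        series = make_series([800.0] * 6)  # < min_beats of data
        metrics = run_metric_engine(series, HRVWindowConfig(window_s=10.0))
        assert metrics and all(not m.valid for m in metrics)

    def test_identical_input_gives_identical_metrics(self):
        rr, beats = generate_rr_series(
            RRModulationSpec(mean_rr_ms=800.0, jitter_sd_ms=15.0, seed=4), 90.0
        )
        series = make_series(rr)
        config = HRVWindowConfig(window_s=30.0)
        assert run_metric_engine(series, config) == run_metric_engine(series, config)

    def test_empty_series_emits_nothing(self):
        assert run_metric_engine(IBISeries.empty(), HRVWindowConfig()) == []
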