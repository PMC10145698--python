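import filecmp

import numpy as np
import pytest
from click.testing import CliRunner

from teamhrv import ConfigError, DataError, Role
from teamhrv import io as thio
from teamhrv.cli import main
from teamhrv.hrv_metrics import HRVWindowConfig, run_metric_engine
from teamhrv.io import LogRecord
from teamhrv.session import SessionConfig, StreamSource, replay_ibis, run_session


@pytest.fixture(scope="module")
def team_config():
    return SessionConfig(
        streams=[StreamSource(stream_id=f"m{i}") for i in range(1, 5)],
        roster={
            Role.SURGEON: "m1",
            Role.ANESTHESIOLOGIST: "m2",
            Role.PERFUSIONIST: "m3",
            Role.NURSE: "m4",
        },
        duration_s=120.0,
        seed=7,
    )


@pytest.fixture(scope="module")
def team_result(team_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("session")
    return run_session(team_config, out_dir=out)


class TestRunSession:
    def test_every_stage_output_is_logged(self, team_result):
        topics = {rec.topic for rec in team_result.log}
        assert {"ecg/raw", "ecg/filtered", "beats", "ibis", "metrics",
                "load", "alerts/team"} <= topics

    def test_at_least_sixty_metric_records_per_member(self, team_result):
        for sid, sr in team_result.streams.items():
            assert len(sr.metrics) >= 60
            assert sum(m.valid for m in sr.metrics) >= 50

    def test_log_times_non_decreasing_per_topic(self, team_result):
        by_topic = {}
        for rec in team_result.log:
            by_topic.setdefault(rec.topic, []).append(rec.time_ms)
        for topic, times in by_topic.items():
            if topic.startswith("alerts") or topic == "metrics":
                continue  # interleaved per-stream publications
            per_stream = {}
            for rec in team_result.log:
                if rec.topic == topic:
                    sid = rec.payload.get("stream_id", "")
                    per_stream.setdefault(sid, []).append(rec.time_ms)
            for seq in per_stream.values():
                assert all(a <= b for a, b in zip(seq, seq[1:]))

    def test_team_alerts_evaluated_on_session_timeline(self, team_result):
        assert len(team_result.team_alerts) >= 60
        sums = [a.sum for a in team_result.team_alerts if not a.degraded]
        assert sums and all(4 <= s <= 12 for s in sums)

    def test_zero_streams_is_validation_error(self):
        with pytest.raises(ConfigError):
            run_session(SessionConfig(streams=[]))

    def test_nine_streams_is_validation_error(self):
        cfg = SessionConfig(
            streams=[StreamSource(stream_id=f"m{i}") for i in range(9)]
        )
        with pytest.raises(ConfigError):
            run_session(cfg)

    def test_roster_with_unknown_stream_is_validation_error(self):
        cfg = SessionConfig(
            streams=[StreamSource(stream_id="m1")],
            roster={Role.SURGEON: "ghost"},
        )
        with pytest.raises(ConfigError):
            run_session(cfg)

    def test_identical_config_and_seed_give_byte_identical_outputs(
        self, team_config, team_result, tmp_path
    ):
        rerun = run_session(team_config, out_dir=tmp_path)
        for sid in team_result.streams:
            assert filecmp.cmp(
                team_result.out_dir / f"metrics_{sid}.csv",
                tmp_path / f"metrics_{sid}.csv",
                shallow=False,
            )
        assert filecmp.cmp(
            team_result.out_dir / "session.jsonl",
            tmp_path / "session.jsonl",
            shallow=False,
        )


class TestReplay:
    def test_cumulative_beat_times(self, tmp_path):
        path = tmp_path / "ibi.txt"
        path.write_text("800\n810\n790\n")
        series = replay_ibis(path, "s1")
        np.testing.assert_allclose(series.beat_time_ms, [800.0, 1610.0, 2400.0])
        np.testing.assert_allclose(series.ibi_ms, [800.0, 810.0, 790.0])

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        path = tmp_path / "ibi.txt"
        path.write_text("# recorded intervals\n800\n\n810\n")
        assert len(replay_ibis(path, "s1")) == 2

    def test_empty_file_gives_empty_stream(self, tmp_path):
        path = tmp_path / "ibi.txt"
        path.write_text("")
        assert len(replay_ibis(path, "s1")) == 0

    def test_negative_line_is_parse_error_naming_line(self, tmp_path):
        path = tmp_path / "ibi.txt"
        path.write_text("-5\n")
        with pytest.raises(DataError, match="line 1"):
            replay_ibis(path, "s1")

    def test_non_numeric_line_is_parse_error_naming_line(self, tmp_path):
        path = tmp_path / "ibi.txt"
        path.write_text("800\nabc\n")
        with pytest.raises(DataError, match="line 2"):
            replay_ibis(path, "s1")

    def test_replay_reproduces_original_metric_values(self, team_result, tmp_path):
        sr = team_result.streams["m1"]
        path = tmp_path / "ibi.txt"
        path.write_text(
            "".join(f"{float(v)!r}\n" for v in sr.series.ibi_ms[sr.series.accepted])
        )
        replayed = replay_ibis(path, "m1")
        config = team_result.config.window
        original = sr.metrics
        rerun = run_metric_engine(replayed, config, stream_id="m1")
        assert len(original) == len(rerun)
        for a, b in zip(original, rerun):
            np.testing.assert_allclose(
                [a.mean_hr_bpm, a.sdnn_ms, a.rmssd_ms, a.lf_power_ms2,
                 a.hf_power_ms2],
                [b.mean_hr_bpm, b.sdnn_ms, b.rmssd_ms, b.lf_power_ms2,
                 b.hf_power_ms2],
                rtol=1e-9, atol=1e-12,
            )


class TestLogRoundTrip:
    def test_round_trip_equality(self, tmp_path):
        records = [
            LogRecord(float(i), "metrics" if i % 2 else "beats",
                      {"stream_id": "s1", "value": i / 3.0})
            for i in range(1000)
        ]
        path = tmp_path / "log.jsonl"
        thio.write_log(path, records)
        assert thio.read_log(path) == records

    def test_empty_log(self, tmp_path):
        path = tmp_path / "log.jsonl"
        thio.write_log(path, [])
        assert thio.read_log(path) == []

    def test_truncated_line_is_error_naming_line(self, tmp_path):
        path = tmp_path / "log.jsonl"
        thio.write_log(path, [LogRecord(1.0, "beats", {})])
        with open(path, "a") as fh:
            fh.write('{"time_ms": 2.0, "topic": "bea')
        with pytest.raises(DataError, match="line 2"):
            thio.read_log(path)


class TestECGCsv:
    def test_round_trip_preserves_rate_and_samples(self, tmp_path):
        rng = np.random.default_rng(0)
        samples = rng.normal(size=400)
        path = tmp_path / "ecg.csv"
        thio.write_ecg_csv(path, samples, rate=500.0)
        got, rate, t0 = thio.read_ecg_csv(path)
        assert rate == pytest.approx(500.0)
        assert t0 == 0.0
        np.testing.assert_allclose(got, samples, atol=1e-6)

    def test_jittered_times_are_rejected(self, tmp_path):
        path = tmp_path / "ecg.csv"
        t = np.arange(100) * 2.0
        t[50] += 0.5  # 25% of the period
        with open(path, "w") as fh:
            fh.write("time_ms,voltage_mv\n")
            for ti in t:
                fh.write(f"{ti},0.0\n")
        with pytest.raises(DataError, match="jitter"):
            thio.read_ecg_csv(path)


class TestCLI:
    def test_simulate_run_replay_report_round_trip(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        result = runner.invoke(main, [
            "simulate", "--members", "2", "--duration", "90",
            "--seed", "3", "--out", str(sim_dir),
        ])
        assert result.exit_code == 0, result.output
        assert (sim_dir / "session.yaml").exists()

        run_dir = tmp_path / "run"
        result = runner.invoke(main, [
            "run", "--config", str(sim_dir / "session.yaml"),
            "--out", str(run_dir),
        ])
        assert result.exit_code == 0, result.output
        assert (run_dir / "session.jsonl").exists()

        ibi_path = tmp_path / "ibi.txt"
        ibi_path.write_text("".join(f"{800 + (i % 7)}\n" for i in range(100)))
        result = runner.invoke(main, [
            "replay", "--ibi", str(ibi_path), "--window", "30",
            "--out", str(tmp_path / "replay"),
        ])
        assert result.exit_code == 0, result.output

        result = runner.invoke(main, ["report", "--log",
                                      str(run_dir / "session.jsonl")])
        assert result.exit_code == 0, result.output
        assert "metrics" in result.output

    def test_config_error_exits_2(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("streams: []\n")
        runner = CliRunner()
        result = runner.invoke(main, [
            "run", "--config", str(bad), "--out", str(tmp_path / "out"),
        ])
        assert result.exit_code == 2

    def test_data_error_exits_3(self, tmp_path):
        ibi = tmp_path / "ibi.txt"
        ibi.write_text("-5\n")
        runner = CliRunner()
        result = runner.invoke(main, [
            "replay", "--ibi", str(ibi), "--out", str(tmp_path / "out"),
        ])
        assert result.exit_code == 3
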