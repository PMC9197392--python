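"""Domain-type validation and tabular round-trip fidelity."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerebellopipe import io as cio
from cerebellopipe.gait import GaitMetrics
from cerebellopipe.responses import ResponseSummary
from cerebellopipe.types import (
    BehaviorScoreSeries,
    FormatError,
    SpikeTrain,
    StimProtocol,
    Trajectory,
)


class TestSpikeTrainValidation:
    def test_accepts_valid_train(self):
        tr = SpikeTrain("u1", "VAL", [0.1, 0.5, 2.0], 0.0, 10.0)
        assert tr.n_spikes == 3 and tr.duration == 10.0

    @pytest.mark.parametrize("times,t0,t1", [
        ([0.5, 0.4], 0.0, 1.0),        # decreasing
        ([0.5, 0.5], 0.0, 1.0),        # duplicate
        ([np.nan], 0.0, 1.0),          # non-finite
        ([-0.1], 0.0, 1.0),            # before start
        ([1.0], 0.0, 1.0),             # at/after end (half-open)
    ])
    def test_rejects_invalid_times(self, times, t0, t1):
        with pytest.raises(ValueError):
            SpikeTrain("u1", "VAL", times, t0, t1)

    def test_rejects_unknown_region(self):
        with pytest.raises(ValueError, match="region"):
            SpikeTrain("u1", "CTX", [0.5], 0.0, 1.0)

    @given(st.lists(st.floats(min_value=0.0, max_value=9.99,
                              allow_nan=False), min_size=0, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_random_times_accepted_iff_strictly_increasing(self, times):
        arr = np.asarray(times)
        ok = arr.size == 0 or np.all(np.diff(np.sort(arr)) > 0)
        if ok:
            tr = SpikeTrain("u", "M1", np.sort(arr), 0.0, 10.0)
            assert tr.n_spikes == arr.size
        else:
            with pytest.raises(ValueError):
                SpikeTrain("u", "M1", np.sort(arr), 0.0, 10.0)


class TestStimProtocolValidation:
    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimProtocol([0.0, 0.05], 0.1, "low_freq")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            StimProtocol([0.0, 4.0], 0.1, "tetanus")


class TestRecordingSession:
    def test_session_invariants(self):
        from cerebellopipe.types import RecordingSession
        tr1 = SpikeTrain("a", "VAL", [1.0, 5.0], 0.0, 100.0)
        tr2 = SpikeTrain("b", "M1", [2.0], 0.0, 100.0)
        proto = StimProtocol([10.0, 14.0], 0.1, "low_freq")
        sess = RecordingSession("s1", "WT", "naive_saline", "pre_burst",
                                [tr1, tr2], proto)
        assert sess.genotype == "WT"
        tr3 = SpikeTrain("c", "M1", [2.0], 0.0, 50.0)  # mismatched interval
        with pytest.raises(ValueError, match="share"):
            RecordingSession("s2", "WT", "oxo", "pre_burst", [tr1, tr3],
                             proto)
        late = StimProtocol([99.0, 103.0], 0.1, "low_freq")
        with pytest.raises(ValueError, match="outside"):
            RecordingSession("s3", "GNAL", "oxo", "post_burst", [tr1], late)


class TestSpikeTrainsIO:
    def test_two_units_counted(self, tmp_path):
        p = tmp_path / "spikes.csv"
        p.write_text("unit_id,region,spike_time_s\n"
                     "a,VAL,0.1\na,VAL,0.2\na,VAL,0.9\n"
                     "b,M1,0.3\nb,M1,0.6\n")
        trains = cio.read_spike_trains(p)
        assert [tr.n_spikes for tr in trains] == [3, 2]
        assert {tr.region for tr in trains} == {"VAL", "M1"}

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "spikes.csv"
        p.write_text("unit_id,region,spike_time_s\n")
        assert cio.read_spike_trains(p) == []

    def test_unknown_region_names_offending_row(self, tmp_path):
        p = tmp_path / "spikes.csv"
        p.write_text("unit_id,region,spike_time_s\na,VAL,0.1\nb,CTX,0.2\n")
        with pytest.raises(FormatError, match="CTX"):
            cio.read_spike_trains(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "spikes.csv"
        p.write_text("unit_id,spike_time_s\na,0.1\n")
        with pytest.raises(FormatError, match="region"):
            cio.read_spike_trains(p)

    def test_duplicate_timestamps_deduplicated_with_warning(self, tmp_path):
        p = tmp_path / "spikes.csv"
        p.write_text("unit_id,region,spike_time_s\na,VAL,0.1\na,VAL,0.1\n"
                     "a,VAL,0.4\n")
        with pytest.warns(UserWarning, match="duplicate"):
            trains = cio.read_spike_trains(p)
        assert trains[0].n_spikes == 2

    def test_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 100, 50))
        tr = SpikeTrain("u0", "DN", times, 0.0, 100.0)
        cio.write_spike_trains([tr], tmp_path / "s.csv")
        back = cio.read_spike_trains(tmp_path / "s.csv", t_start=0.0,
                                     t_end=100.0)
        np.testing.assert_array_equal(back[0].spike_times, times)


class TestEventsIO:
    def test_low_freq_schedule(self, tmp_path):
        p = tmp_path / "events.csv"
        lines = ["onset_s,pulse_duration_s,kind"] + [
            f"{4 * i},0.1,low_freq" for i in range(10)]
        p.write_text("\n".join(lines) + "\n")
        proto = cio.read_events(p)
        assert proto.n_pulses == 10 and proto.kind == "low_freq"

    def test_out_of_order_onsets_resorted_with_warning(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text("onset_s,pulse_duration_s,kind\n8,0.1,low_freq\n"
                     "0,0.1,low_freq\n4,0.1,low_freq\n")
        with pytest.warns(UserWarning, match="re-sorting"):
            proto = cio.read_events(p)
        np.testing.assert_array_equal(proto.onsets, [0.0, 4.0, 8.0])

    def test_two_durations_rejected(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text("onset_s,pulse_duration_s,kind\n0,0.1,low_freq\n"
                     "4,0.02,low_freq\n")
        with pytest.raises(FormatError, match="duration"):
            cio.read_events(p)


class TestFrameStackIO:
    def test_raw_stack_roundtrip(self, tmp_path):
        frames = [np.full((64, 64), i % 256, dtype=np.uint8)
                  for i in range(100)]
        cio.write_frame_stack(frames, tmp_path / "fr", fps=25, px_per_cm=8)
        out = list(cio.read_frame_stack(tmp_path / "fr"))
        assert len(out) == 100
        for (i, f), orig in zip(out, frames):
            assert f.shape == (64, 64)
            np.testing.assert_array_equal(f, orig)

    def test_zero_frames_is_empty_iterator(self, tmp_path):
        cio.write_frame_stack([], tmp_path / "fr", fps=25, px_per_cm=8)
        assert list(cio.read_frame_stack(tmp_path / "fr")) == []

    def test_size_mismatch_raises_at_index(self, tmp_path):
        import json
        from PIL import Image
        d = tmp_path / "fr"
        d.mkdir()
        for i, shape in enumerate([(64, 64), (64, 63), (64, 64)]):
            Image.fromarray(np.zeros(shape, np.uint8)).save(
                d / f"{i:04d}.png")
        (d / "manifest.json").write_text(json.dumps(
            {"width": 64, "height": 64, "n_frames": 3, "fps": 25,
             "px_per_cm": 8}))
        it = cio.read_frame_stack(d)
        next(it)
        with pytest.raises(FormatError, match="frame 1"):
            next(it)


class TestWriteReport:
    def test_response_summaries_one_row_per_unit(self, tmp_path):
        summaries = [
            ResponseSummary(f"u{i}", "VAL", True, 1.5, 0.5, 10.0, 2.0,
                            11.0, 0.9)
            for i in range(3)
        ]
        cio.write_report(summaries, tmp_path / "resp")
        import pandas as pd
        df = pd.read_csv(tmp_path / "resp.csv")
        assert len(df) == 3 and "delta_rate" in df.columns

    def test_gait_metrics_json_has_named_fields(self, tmp_path):
        import json
        m = GaitMetrics(5.0, 0.1, 3.0, 0.02, 1.5, 10.0, 5.83)
        cio.write_report(m, tmp_path / "gait")
        rec = json.loads((tmp_path / "gait.json").read_text())[0]
        assert set(rec) == set(dataclasses.asdict(m))

    def test_empty_result_list_writes_header_only_csv(self, tmp_path):
        cio.write_report([], tmp_path / "empty")
        assert (tmp_path / "empty.csv").read_text().strip() == ""

    def test_float_roundtrip_full_precision(self, tmp_path):
        import pandas as pd  # round-trip parser needed for bit-exactness
        vals = [np.pi, 1 / 3, 1e-17, 123456.789012345]
        rows = [{"x": v} for v in vals]
        cio.write_report(rows, tmp_path / "f")
        back = pd.read_csv(tmp_path / "f.csv",
                           float_precision="round_trip")["x"].to_list()
        np.testing.assert_array_equal(back, vals)


class TestTrajectoryAndScores:
    def test_trajectory_roundtrip(self, tmp_path):
        ts = np.arange(100) / 25.0
        pos = np.column_stack([np.cos(ts), np.sin(ts)]) * 5
        traj = Trajectory(ts, pos)
        cio.write_trajectory(traj, tmp_path / "t.csv")
        back = cio.read_trajectory(tmp_path / "t.csv")
        np.testing.assert_array_equal(back.positions, pos)

    def test_nonuniform_timestamps_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            Trajectory([0.0, 0.1, 0.3], np.zeros((3, 2)))

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError, match="0,1,2,3,4"):
            BehaviorScoreSeries(np.array([[0, 5]]), ("r1",))

    def test_scores_roundtrip(self, tmp_path):
        series = BehaviorScoreSeries(np.array([[0, 2, 4], [1, 2, 3]]),
                                     ("a", "b"))
        cio.write_scores(series, tmp_path / "sc.csv")
        back = cio.read_scores(tmp_path / "sc.csv")
        np.testing.assert_array_equal(back.block_scores, series.block_scores)
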