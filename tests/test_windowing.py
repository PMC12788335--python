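"""Scaling, slicing and overlap-average reassembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprintgc.errors import ValidationError
from sprintgc.study_io import ImuStream, LabelStream
from sprintgc.windowing import (
    build_dataset,
    reassemble,
    scale_minmax,
    slice_windows,
    window_starts,
)


class TestScaleMinmax:
    def test_endpoints_and_midpoint(self):
        s = scale_minmax(np.array([[0.0, 5.0, 10.0]]))
        np.testing.assert_allclose(s.channels[0], [-1.5, 0.0, 1.5])

    def test_degenerate_channel_maps_to_zero(self):
        s = scale_minmax(np.array([[4.0, 4.0, 4.0]]))
        np.testing.assert_array_equal(s.channels[0], [0.0, 0.0, 0.0])

    def test_matches_two_point_affine_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(2, 50, size=200)
        s = scale_minmax(x[None, :])
        # independent oracle: solve y = a x + b from the min/max constraints
        a = 3.0 / (x.max() - x.min())
        b = -1.5 - a * x.min()
        np.testing.assert_allclose(s.channels[0], a * x + b, rtol=1e-6)

    def test_channels_scaled_independently(self):
        s = scale_minmax(np.array([[0.0, 10.0], [100.0, 300.0]]))
        np.testing.assert_allclose(s.channels, [[-1.5, 1.5], [-1.5, 1.5]])

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(6)
        once = scale_minmax(rng.uniform(0, 9, size=(2, 100)))
        twice = scale_minmax(once.channels)
        np.testing.assert_allclose(twice.channels, once.channels, atol=1e-6)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            scale_minmax(np.array([[1.0, np.nan]]))

    def test_range_recorded(self, run_record):
        s = scale_minmax(run_record.imu)
        assert s.channels.min() >= -1.5 and s.channels.max() <= 1.5
        assert s.scale_params[0] == (run_record.imu.a_res.min(), run_record.imu.a_res.max())


def _stream(L, seed=0):
    rng = np.random.default_rng(seed)
    feats = scale_minmax(rng.uniform(0, 1, size=(2, L)))
    labels = LabelStream((rng.random(L) > 0.5).astype(int), fs=250)
    return feats, labels


class TestSliceWindows:
    def test_window_count_and_last_start(self):
        feats, labels = _stream(1000)
        ws = slice_windows(feats, labels, T=100, stride=15)
        assert ws.n_windows == 61
        assert ws.starts[-1] == 900
        np.testing.assert_array_equal(ws.starts, np.arange(0, 901, 15))

    def test_exactly_one_window(self):
        feats, labels = _stream(100)
        ws = slice_windows(feats, labels, T=100, stride=15)
        assert ws.n_windows == 1

    def test_incomplete_tail_discarded(self):
        feats, labels = _stream(109)
        ws = slice_windows(feats, labels, T=100, stride=15)
        assert ws.n_windows == 1  # frames 100..108 fall in no window

    def test_window_contents(self):
        feats, labels = _stream(300, seed=1)
        ws = slice_windows(feats, labels, T=50, stride=20)
        for i, st_ in enumerate(ws.starts):
            np.testing.assert_array_equal(ws.X[i], feats.channels[:, st_ : st_ + 50])
            np.testing.assert_array_equal(ws.Y[i], labels.values[st_ : st_ + 50])

    def test_stride_ge_window_rejected(self):
        feats, labels = _stream(500)
        with pytest.raises(ValidationError):
            slice_windows(feats, labels, T=25, stride=25)

    def test_stream_shorter_than_window_warns_empty(self):
        feats, labels = _stream(50)
        with pytest.warns(UserWarning, match="shorter"):
            ws = slice_windows(feats, labels, T=100, stride=15)
        assert ws.n_windows == 0


class TestReassemble:
    def test_constant_windows_and_uncovered_tail(self):
        starts = np.arange(0, 91, 15)
        probs = np.full((starts.size, 100), 0.8)
        out = reassemble(probs, starts, source_length=200)
        np.testing.assert_allclose(out[:190], 0.8)
        np.testing.assert_array_equal(out[190:], 0.0)

    def test_mean_of_two_overlapping_windows(self):
        probs = np.array([[0.2, 0.2], [0.6, 0.6]])
        out = reassemble(probs, np.array([0, 1]), source_length=3)
        np.testing.assert_allclose(out, [0.2, 0.4, 0.6])

    def test_matches_sum_count_loop_oracle(self):
        rng = np.random.default_rng(12)
        starts = window_starts(400, 60, 17)
        probs = rng.random((starts.size, 60))
        out = reassemble(probs, starts, 400)
        acc = np.zeros(400)
        cnt = np.zeros(400)
        for i, st_ in enumerate(starts):
            for j in range(60):
                acc[st_ + j] += probs[i, j]
                cnt[st_ + j] += 1
        expect = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
        np.testing.assert_allclose(out, expect)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        L=st.integers(60, 400),
        T=st.integers(20, 60),
        stride=st.integers(1, 19),
        seed=st.integers(0, 10_000),
    )
    def test_labels_survive_slice_reassemble_round_trip(self, L, T, stride, seed):
        """Pushing the label tensor through slice->reassemble reproduces the
        labels exactly on every covered frame."""
        feats, labels = _stream(L, seed=seed)
        ws = slice_windows(feats, labels, T=T, stride=stride)
        out = reassemble(ws.Y, ws.starts, L)
        covered = np.zeros(L, dtype=bool)
        for st_ in ws.starts:
            covered[st_ : st_ + T] = True
        np.testing.assert_array_equal(out[covered], labels.values[covered])
        np.testing.assert_array_equal(out[~covered], 0)

    def test_output_stays_in_unit_interval(self):
        rng = np.random.default_rng(1)
        starts = window_starts(300, 40, 13)
        out = reassemble(rng.random((starts.size, 40)), starts, 300)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestBuildDataset:
    def test_concatenated_window_count(self, tiny_study):
        runs = list(tiny_study.runs.values())
        L = len(runs[0].imu)
        from sprintgc.windowing import window_starts as wstarts

        expect = sum(wstarts(len(r.imu), 100, 15).size for r in runs)
        ds = build_dataset(runs, 100, 15)
        assert ds.n_windows == expect

    def test_two_equal_streams_double_windows(self):
        rng = np.random.default_rng(0)
        from sprintgc.synthetic_gait import GaitSimConfig, generate_run

        cfg = GaitSimConfig(seed=2)
        runs = [generate_run(cfg, "a01", "r1", "left"), generate_run(cfg, "a01", "r1", "right")]
        ds = build_dataset(runs, 100, 15)
        n1 = window_starts(len(runs[0].imu), 100, 15).size
        n2 = window_starts(len(runs[1].imu), 100, 15).size
        assert ds.n_windows == n1 + n2

    def test_empty_run_list(self):
        ds = build_dataset([], 100, 15)
        assert ds.n_windows == 0

    def test_provenance_round_trip_touches_each_stream_once(self, tiny_study):
        runs = list(tiny_study.runs.values())
        ds = build_dataset(runs, 100, 15)
        seen = 0
        for r in runs:
            idx = ds.stream_index(r.stream_id)
            seen += idx.size
            out = ds.reassemble_stream(ds.Y, r.stream_id)
            covered = np.zeros(len(r.imu), dtype=bool)
            for st_ in ds.windows.starts[idx]:
                covered[st_ : st_ + 100] = True
            np.testing.assert_array_equal(out[covered], r.labels.values[covered])
        assert seen == ds.n_windows

    def test_export_import_round_trip(self, tiny_study, tmp_path):
        from sprintgc.windowing import export_dataset, import_dataset

        ds = build_dataset(list(tiny_study.runs.values()), 100, 15)
        path = tmp_path / "ds.npz"
        export_dataset(ds, path)
        back = import_dataset(path)
        np.testing.assert_array_equal(back.X, ds.X)
        np.testing.assert_array_equal(back.Y, ds.Y)
        np.testing.assert_array_equal(back.windows.starts, ds.windows.starts)
        assert back.source_lengths == ds.source_lengths
        assert (back.windows.T, back.windows.stride) == (100, 15)

    def test_mixed_sampling_rates_rejected(self, tiny_study):
        from dataclasses import replace

        runs = list(tiny_study.runs.values())
        bad = replace(
            runs[0],
            imu=ImuStream(
                runs[0].imu.a_res, runs[0].imu.w_res, fs=500,
                athlete_id="zz", run_id="r9", leg="left",
            ),
            labels=LabelStream(runs[0].labels.values, fs=500),
        )
        with pytest.raises(ValidationError, match="sampling"):
            build_dataset(runs + [bad], 100, 15)
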