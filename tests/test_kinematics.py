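"""Displacement, differentiation and per-beat metric oracles."""

import numpy as np
import pytest

from cardiokin.kinematics import (
    BeatSegment,
    KinematicsParams,
    VideoSummary,
    analyze_signal,
    analyze_trajectory_set,
    beat_metrics,
    detect_beats,
    displacement,
    smooth_and_differentiate,
    summarize_syncytium,
    summarize_video,
)
from cardiokin.synthgen import (
    BeatWaveformParams,
    ConditionParams,
    make_beat_waveform,
    synth_trajectories,
)
from cardiokin.kinematics import DisplacementSignal, KinematicRecord
from cardiokin.trajectories import MarkerTrajectory, TimeBase

from conftest import farthest_marker


class TestDisplacement:
    def test_constant_trajectory_gives_zero(self):
        tr = MarkerTrajectory(0, np.full(100, 5.0), np.full(100, 7.0))
        assert displacement(tr).d.max() == 0.0

    def test_pure_x_motion_recovers_waveform_exactly(self, clean_pulse_params,
                                                     tb_25hz):
        s, _, _, _ = make_beat_waveform(clean_pulse_params, tb_25hz, seed=0)
        a = 10.0
        tr = MarkerTrajectory(0, 100.0 - a * s, np.full(tb_25hz.n_frames, 50.0))
        np.testing.assert_allclose(displacement(tr).d, a * s, atol=1e-12)

    def test_unknown_policy_rejected(self):
        tr = MarkerTrajectory(0, np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError, match="ref_policy"):
            displacement(tr, "median")


class TestSmoothAndDifferentiate:
    def test_constant_signal_zero_derivatives(self, tb_25hz):
        d_s, v, a = smooth_and_differentiate(np.full(500, 3.0), tb_25hz)
        np.testing.assert_allclose(v, 0.0, atol=1e-9)
        np.testing.assert_allclose(a, 0.0, atol=1e-8)
        np.testing.assert_allclose(d_s, 3.0, atol=1e-9)

    def test_sinusoid_derivative_maxima(self, tb_25hz):
        """10 px, 1 Hz sinusoid: v_max = 2 pi f A, a_max = (2 pi f)^2 A."""
        t = tb_25hz.times
        d = 10.0 * np.sin(2 * np.pi * t)
        _, v, a = smooth_and_differentiate(d, tb_25hz)
        assert v.max() == pytest.approx(2 * np.pi * 10.0, rel=0.02)
        assert a.max() == pytest.approx((2 * np.pi) ** 2 * 10.0, rel=0.05)

    def test_window_too_long_errors(self, tb_25hz):
        with pytest.raises(ValueError, match="admissible"):
            smooth_and_differentiate(np.zeros(10), tb_25hz, window_s=10.0)


class TestDetectBeats:
    def test_flat_signal_has_no_beats(self):
        assert detect_beats(np.zeros(500), fs=25.0) == []

    def test_one_hz_pulse_train_count(self, clean_pulse_params, tb_25hz):
        s, _, _, beats = make_beat_waveform(clean_pulse_params, tb_25hz, seed=0)
        segs = detect_beats(10 * s, fs=25.0)
        assert abs(len(segs) - len(beats)) <= 1

    def test_close_pulses_merge_under_min_period(self):
        fs = 100.0
        t = np.arange(int(fs)) / fs
        d = np.exp(-0.5 * ((t - 0.40) / 0.02) ** 2) \
            + np.exp(-0.5 * ((t - 0.50) / 0.02) ** 2)
        segs = detect_beats(d, fs=fs, min_prominence=0.3, min_period_s=0.25)
        assert len(segs) == 1

    def test_segments_are_disjoint_and_ordered(self, tb_25hz):
        p = BeatWaveformParams()
        s, _, _, _ = make_beat_waveform(p, tb_25hz, seed=3)
        rng = np.random.default_rng(0)
        segs = detect_beats(10 * s + rng.normal(0, 0.05, s.size), fs=25.0)
        assert len(segs) > 5
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.onset
            assert a.onset <= a.peak <= a.end


class TestBeatMetrics:
    def test_raised_cosine_beat_recovery_fs100(self, clean_pulse_params):
        """A=10 px, tau_c=0.2 s at 100 Hz: D ~ 10, V ~ 78.54, Acc ~ 1233.7."""
        tb = TimeBase(100.0, 2000)
        s, _, _, _ = make_beat_waveform(clean_pulse_params, tb, seed=0)
        d = 10.0 * s
        records = analyze_signal(DisplacementSignal(0, d, (0.0, 0.0)), tb)
        assert len(records) >= 18
        D = np.mean([r.D for r in records])
        V = np.mean([r.V for r in records])
        Acc = np.mean([r.Acc for r in records])
        assert D == pytest.approx(10.0, rel=0.01)
        assert V == pytest.approx(78.5398, rel=0.02)
        assert Acc == pytest.approx(1233.70, rel=0.05)

    def test_metrics_scale_linearly_with_amplitude(self, clean_pulse_params):
        tb = TimeBase(100.0, 1000)
        s, _, _, _ = make_beat_waveform(clean_pulse_params, tb, seed=0)
        rec1 = analyze_signal(DisplacementSignal(0, 10 * s, (0, 0)), tb)
        rec2 = analyze_signal(DisplacementSignal(0, 20 * s, (0, 0)), tb)
        for a, b in zip(rec1, rec2):
            assert b.D == pytest.approx(2 * a.D, rel=1e-6)
            assert b.V == pytest.approx(2 * a.V, rel=1e-6)
            assert b.Acc == pytest.approx(2 * a.Acc, rel=1e-6)

    def test_degenerate_segment_yields_zero_record(self):
        seg = BeatSegment(5, 5, 7, 1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            rec = beat_metrics(np.zeros(10), np.zeros(10), np.zeros(10), seg,
                               fs=25.0)
        assert (rec.D, rec.V, rec.Acc) == (0.0, 0.0, 0.0)

    def test_sampling_rate_invariance_of_displacement(self, clean_pulse_params):
        """The same continuous motion gives the same D at 25 and 100 Hz."""
        Ds = []
        for fs in (25.0, 100.0):
            tb = TimeBase(fs, int(20 * fs))
            s, _, _, _ = make_beat_waveform(clean_pulse_params, tb, seed=0)
            recs = analyze_signal(DisplacementSignal(0, 10 * s, (0, 0)), tb)
            Ds.append(np.mean([r.D for r in recs]))
        assert Ds[0] == pytest.approx(Ds[1], rel=0.02)


class TestAggregation:
    def test_video_summary_marker_then_mean(self):
        recs = [KinematicRecord(0, 0, 2.0, 1.0, 1.0),
                KinematicRecord(0, 1, 4.0, 1.0, 1.0),
                KinematicRecord(1, 0, 6.0, 1.0, 1.0)]
        v = summarize_video(recs)
        assert v.D == pytest.approx(4.5)
        assert v.n_markers == 2 and v.n_beats == 3

    def test_video_summary_empty_errors(self):
        with pytest.raises(ValueError, match="no beats"):
            summarize_video([])

    def test_syncytium_mean_over_videos(self):
        vids = [VideoSummary(d, 0.0, 0.0, 1, 1) for d in (1, 2, 3, 4, 5)]
        s = summarize_syncytium(vids, 3, "ISO")
        assert s.D_mean == pytest.approx(3.0)
        assert s.n_videos == 5

    def test_syncytium_empty_window_errors(self):
        with pytest.raises(ValueError):
            summarize_syncytium([])


class TestEndToEndProperties:
    def test_amplitude_monotonicity_paired_seeds(self, grid_640x480,
                                                 frame_center, tb_25hz):
        """Raising amp_mult raises recovered mean D (paired seeds)."""
        base = BeatWaveformParams()
        wins = 0
        for seed in range(5):
            Ds = []
            for mult in (0.9, 1.2):
                cp = ConditionParams("CTRL", amp_mult=mult, between_cv=0.0)
                ts, _ = synth_trajectories(cp, base, grid_640x480.positions,
                                           frame_center, tb_25hz, seed=seed)
                recs = analyze_trajectory_set(ts)
                Ds.append(summarize_video(recs).D)
            wins += Ds[1] > Ds[0]
        assert wins == 5

    def test_noise_only_records_rarely_beat(self, grid_640x480, frame_center,
                                            tb_25hz, ctrl_condition):
        """False-positive control: zero amplitude, 0.1 px noise."""
        p = BeatWaveformParams(A0=0.0, noise_sigma=0.1)
        false_pos = 0
        for seed in range(20):
            ts, _ = synth_trajectories(ctrl_condition, p,
                                       grid_640x480.positions[:3],
                                       frame_center, tb_25hz, seed=seed)
            d = displacement(ts.trajectories[0])
            false_pos += bool(analyze_signal(d, tb_25hz))
        assert false_pos <= 1
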