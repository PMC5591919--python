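"""Generator oracles: closed-form pulse maxima, determinism, scaling laws."""

import numpy as np
import pytest

from cardiokin.synthgen import (
    BeatWaveformParams,
    ConditionParams,
    StudyDesign,
    generate_study,
    make_beat_waveform,
    pulse_maxima,
    render_frames,
    synth_trajectories,
)
from cardiokin.trajectories import TimeBase

from conftest import farthest_marker


class TestBeatWaveform:
    def test_jitter_free_beat_times_and_normalization(self, clean_pulse_params):
        """1 Hz, 20 s, no jitter: 20 onsets at 0.5 + k s and unit peak."""
        tb = TimeBase(1000.0, 20000)
        s, s_dot, s_ddot, beats = make_beat_waveform(clean_pulse_params, tb, seed=0)
        assert len(beats) == 20
        np.testing.assert_allclose(beats, 0.5 + np.arange(20), atol=1e-12)
        assert s.max() == pytest.approx(1.0, abs=1e-5)
        assert s.min() == 0.0

    def test_derivative_maxima_match_closed_forms(self, clean_pulse_params):
        """Densely sampled s_dot and s_ddot reach the analytic pulse maxima."""
        tb = TimeBase(100_000.0, 2_000_000)
        s, s_dot, s_ddot, _ = make_beat_waveform(clean_pulse_params, tb, seed=0)
        smax, vmax, amax = pulse_maxima(clean_pulse_params)
        assert vmax == pytest.approx(np.pi / 0.4)
        assert amax == pytest.approx(np.pi ** 2 / 0.08)
        assert s_dot.max() == pytest.approx(vmax, rel=5e-3)
        assert s_ddot.max() == pytest.approx(amax, rel=5e-3)

    @pytest.mark.parametrize("fs", [100.0, 250.0])
    def test_sampled_maxima_within_half_percent(self, clean_pulse_params, fs):
        """At fs >= 100 Hz the sampled maxima agree with the closed forms."""
        tb = TimeBase(fs, int(20 * fs))
        s, s_dot, s_ddot, _ = make_beat_waveform(clean_pulse_params, tb, seed=0)
        _, vmax, amax = pulse_maxima(clean_pulse_params)
        assert s.max() == pytest.approx(1.0, rel=5e-3)
        assert s_dot.max() == pytest.approx(vmax, rel=5e-3)
        assert s_ddot.max() == pytest.approx(amax, rel=5e-3)

    @pytest.mark.parametrize("jitter", [0.0, 0.1, 0.2])
    @pytest.mark.parametrize("duration", [10.0, 20.0])
    def test_beat_count_tracks_duration(self, jitter, duration):
        p = BeatWaveformParams(f_beat=1.0, tau_c=0.2, tau_r=0.3,
                               jitter_cv=jitter, noise_sigma=0.0)
        tb = TimeBase(50.0, int(50 * duration))
        for seed in range(5):
            _, _, _, beats = make_beat_waveform(p, tb, seed=seed)
            assert abs(len(beats) - int(duration * p.f_beat)) <= 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="exceeds the beat period"):
            BeatWaveformParams(f_beat=2.0, tau_c=0.3, tau_r=0.3)
        with pytest.raises(ValueError):
            BeatWaveformParams(jitter_cv=0.9)


class TestSynthTrajectories:
    def test_zero_amplitude_is_rest_plus_noise(self, grid_640x480, frame_center,
                                               tb_25hz, ctrl_condition):
        p = BeatWaveformParams(A0=0.0, noise_sigma=0.05)
        ts, gt = synth_trajectories(ctrl_condition, p, grid_640x480.positions,
                                    frame_center, tb_25hz, seed=0)
        assert gt.D_true == 0.0
        xs, ys = ts.positions()
        assert np.abs(xs - grid_640x480.positions[:, [0]]).max() < 0.3
        assert np.abs(ys - grid_640x480.positions[:, [1]]).max() < 0.3

    def test_farthest_marker_ground_truth_velocity(self, grid_640x480,
                                                   frame_center, tb_25hz,
                                                   ctrl_condition):
        """A = 10 px, tau_c = 0.2 s: peak velocity 10 pi / 0.4 = 78.54 px/s."""
        p = BeatWaveformParams(A0=10.0, f_beat=1.0, tau_c=0.2, tau_r=0.3,
                               jitter_cv=0.0, noise_sigma=0.0)
        _, gt = synth_trajectories(ctrl_condition, p, grid_640x480.positions,
                                   frame_center, tb_25hz, seed=0)
        assert gt.V_true == pytest.approx(78.539816, rel=1e-6)
        assert gt.D_true == pytest.approx(10.0)

    def test_seed_determinism_bit_identical(self, grid_640x480, frame_center,
                                            tb_25hz):
        cp = ConditionParams("CTRL")
        p = BeatWaveformParams()
        a, _ = synth_trajectories(cp, p, grid_640x480.positions, frame_center,
                                  tb_25hz, seed=42)
        b, _ = synth_trajectories(cp, p, grid_640x480.positions, frame_center,
                                  tb_25hz, seed=42)
        xa, ya = a.positions()
        xb, yb = b.positions()
        assert np.array_equal(xa, xb) and np.array_equal(ya, yb)

    def test_amplitude_scaling_doubles_ground_truth(self, grid_640x480,
                                                    frame_center, tb_25hz,
                                                    ctrl_condition):
        p1 = BeatWaveformParams(A0=5.0, noise_sigma=0.0)
        p2 = BeatWaveformParams(A0=10.0, noise_sigma=0.0)
        _, g1 = synth_trajectories(ctrl_condition, p1, grid_640x480.positions,
                                   frame_center, tb_25hz, seed=7)
        _, g2 = synth_trajectories(ctrl_condition, p2, grid_640x480.positions,
                                   frame_center, tb_25hz, seed=7)
        assert g2.D_true == pytest.approx(2 * g1.D_true)
        assert g2.V_true == pytest.approx(2 * g1.V_true)
        assert g2.Acc_true == pytest.approx(2 * g1.Acc_true)

    def test_marker_motion_is_radial_toward_center(self, grid_640x480,
                                                   frame_center, tb_25hz,
                                                   ctrl_condition):
        p = BeatWaveformParams(A0=10.0, jitter_cv=0.0, noise_sigma=0.0)
        ts, _ = synth_trajectories(ctrl_condition, p, grid_640x480.positions,
                                   frame_center, tb_25hz, seed=0)
        far = farthest_marker(grid_640x480, frame_center)
        tr = ts.trajectories[far]
        rest = grid_640x480.positions[far]
        disp = np.column_stack([tr.x - rest[0], tr.y - rest[1]])
        toward = np.asarray(frame_center) - rest
        toward = toward / np.linalg.norm(toward)
        along = disp @ toward
        assert along.min() >= -1e-9  # never moves away from the center
        perp = disp - np.outer(along, toward)
        assert np.abs(perp).max() < 1e-9

    def test_empty_grid_rejected(self, frame_center, tb_25hz, ctrl_condition):
        with pytest.raises(ValueError, match="empty grid"):
            synth_trajectories(ctrl_condition, BeatWaveformParams(),
                               np.empty((0, 2)), frame_center, tb_25hz, seed=0)


class TestRenderFrames:
    def test_static_marker_frames_identical(self):
        from cardiokin.trajectories import MarkerTrajectory, TrajectorySet
        tb = TimeBase(25.0, 10)
        tr = MarkerTrajectory(0, np.full(10, 50.0), np.full(10, 40.0))
        stack = render_frames(TrajectorySet(tb, [tr]), shape=(80, 100),
                              noise="none")
        assert np.array_equal(stack.frames[0], stack.frames[5])
        peak = np.unravel_index(np.argmax(stack.frames[0]),
                                stack.frames[0].shape)
        assert peak == (40, 50)

    def test_frame_count_matches_timebase(self, grid_640x480, frame_center,
                                          ctrl_condition):
        tb = TimeBase(25.0, 500)
        p = BeatWaveformParams(noise_sigma=0.0)
        ts, _ = synth_trajectories(ctrl_condition, p, grid_640x480.positions,
                                   frame_center, tb, seed=0)
        stack = render_frames(ts, shape=(480, 640))
        assert stack.frames.shape == (500, 480, 640)

    def test_gaussian_blob_mass(self):
        """Background-subtracted blob integrates to amplitude * 2 pi sigma^2."""
        from cardiokin.trajectories import MarkerTrajectory, TrajectorySet
        tb = TimeBase(25.0, 2)
        tr = MarkerTrajectory(0, np.full(2, 60.0), np.full(2, 60.0))
        sigma, amp, bg = 3.0, 5000.0, 100.0
        stack = render_frames(TrajectorySet(tb, [tr]), shape=(120, 120),
                              spot_sigma=sigma, spot_amplitude=amp,
                              background=bg, noise="none")
        mass = (stack.frames[0].astype(float) - bg).sum()
        assert mass == pytest.approx(amp * 2 * np.pi * sigma ** 2, rel=0.01)

    def test_marker_leaving_frame_is_an_error(self):
        from cardiokin.trajectories import MarkerTrajectory, TrajectorySet
        tb = TimeBase(25.0, 3)
        tr = MarkerTrajectory(0, np.array([50.0, 5.0, 50.0]), np.full(3, 40.0))
        with pytest.raises(ValueError, match="marker 0 .*frame 1"):
            render_frames(TrajectorySet(tb, [tr]), shape=(80, 100))


class TestGenerateStudy:
    def test_file_counts_and_manifest(self, tmp_path):
        design = StudyDesign(n_syncytia=2, minutes=(27,), fs=25.0, duration=4.0)
        manifest = generate_study(design, seed=0, outdir=tmp_path / "out")
        assert len(manifest) == 4 * 2 * 1
        assert len(list((tmp_path / "out").glob("*_s*_m*.csv"))) == 8
        assert set(manifest.arm) == {"CTRL", "ISO", "EMF", "ISO+EMF"}
        assert (manifest.D_true > 0).all()

    def test_refuses_nonempty_outdir(self, tmp_path):
        design = StudyDesign(n_syncytia=2, minutes=(27,), duration=4.0)
        out = tmp_path / "out"
        out.mkdir()
        (out / "stale.txt").write_text("x")
        with pytest.raises(FileExistsError):
            generate_study(design, seed=0, outdir=out)
        generate_study(design, seed=0, outdir=out, overwrite=True)

    def test_default_design_matches_study_schedule(self):
        d = StudyDesign()
        assert d.n_syncytia == 20
        assert d.minutes == (27, 30, 33, 36, 39)
        assert d.grid_rows * d.grid_cols == 30
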