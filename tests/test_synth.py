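"""Synthetic generator: waveform, traces, trajectories, scenarios, renderer."""

from dataclasses import replace

import numpy as np
import pytest

from pulsefuse.evaluate import agreement, reference_series, windowed_hr
from pulsefuse.ppg import rppg_from_traces
from pulsefuse.bcg import rbcg_from_trajectories
from pulsefuse.signal_core import dominant_hr, power_spectrum, snr
from pulsefuse.synth import (
    SimConfig,
    pulse_waveform,
    random_hr_trajectory,
    render_clip,
    scenario,
    simulate_rgb,
    simulate_trajectories,
)


class TestSimConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(duration=10.0)
        with pytest.raises(ValueError):
            SimConfig(fps=5.0)
        with pytest.raises(ValueError):
            SimConfig(hr_bpm=40.0)
        with pytest.raises(ValueError):
            SimConfig(expression_fraction=1.5)

    def test_hr_trajectory_interpolation(self):
        cfg = SimConfig(hr_bpm=((0.0, 60.0), (60.0, 90.0)))
        np.testing.assert_allclose(
            cfg.hr_values(np.array([0.0, 30.0, 60.0])), [60.0, 75.0, 90.0]
        )


class TestPulseWaveform:
    def test_constant_rate_dominant_hr(self):
        w = pulse_waveform(SimConfig(hr_bpm=72.0))
        assert dominant_hr(w).bpm == pytest.approx(72.0, abs=0.5)

    def test_unit_amplitude(self):
        w = pulse_waveform(SimConfig(hr_bpm=65.0))
        assert np.max(np.abs(w.samples)) == pytest.approx(1.0)

    def test_amplitude_invariance_of_hr(self):
        w = pulse_waveform(SimConfig(hr_bpm=80.0))
        scaled = w.with_samples(10.0 * w.samples)
        assert dominant_hr(scaled).bpm == dominant_hr(w).bpm

    def test_ramp_frequency_increases(self):
        cfg = SimConfig(duration=120.0, hr_bpm=((0.0, 60.0), (120.0, 90.0)))
        w = pulse_waveform(cfg)
        hrs = windowed_hr(w, window_s=30.0, stride_s=10.0).bpm
        # window-mean dominant frequency climbs monotonically along the ramp
        assert np.all(np.diff(hrs) > 0)
        assert hrs[0] < 70 < hrs[-1]


class TestSimulateRgb:
    def test_channel_means_near_baseline(self):
        traces, _ = simulate_rgb(SimConfig(seed=3, illum_amp=0.5))
        for t in traces:
            assert abs(t.r.mean() - 140.0) < 0.5
            assert abs(t.g.mean() - 110.0) < 0.5
            assert abs(t.b.mean() - 90.0) < 0.5

    def test_clean_input_recovers_hr(self):
        cfg = SimConfig(hr_bpm=70.0, illum_amp=0.0, rgb_noise=0.0,
                        pulse_amp_mod=0.0, seed=1)
        traces, _ = simulate_rgb(cfg)
        out = rppg_from_traces(traces)
        assert dominant_hr(out).bpm == pytest.approx(70.0, abs=0.5)

    def test_no_pulse_means_low_snr(self):
        """Without a cardiac component the selected rPPG component has
        SNR < 1 in >= 18/20 seeds (no spurious narrowband structure)."""
        wins = 0
        for seed in range(20):
            cfg = SimConfig(pulse_amp_rgb=0.0, seed=seed)
            traces, _ = simulate_rgb(cfg)
            out = rppg_from_traces(traces, seed=seed)
            wins += snr(power_spectrum(out)) < 1.0
        assert wins >= 18

    def test_ground_truth_matches_configuration(self):
        cfg = SimConfig(hr_bpm=((0.0, 60.0), (60.0, 80.0)), seed=0)
        _, gt = simulate_rgb(cfg)
        np.testing.assert_allclose(gt.bpm, cfg.hr_values(gt.times))


class TestSimulateTrajectories:
    def test_always_80_rows(self):
        traj, _ = simulate_trajectories(SimConfig(seed=2))
        assert traj.n_points == 80

    def test_clean_recovery(self):
        cfg = SimConfig(hr_bpm=80.0, bcg_amp=0.5, jitter_px=0.0,
                        pulse_amp_mod=0.0, seed=1)
        traj, _ = simulate_trajectories(cfg)
        out = rbcg_from_trajectories(traj)
        assert dominant_hr(out).bpm == pytest.approx(80.0, abs=0.5)

    def test_motion_event_gets_clamped(self):
        from pulsefuse.bcg import condition_bank, y_signal_bank
        from pulsefuse.signal_core import Signal1D, bandpass

        cfg = SimConfig(motion_rate=4.0, motion_amp=30.0, seed=7)
        traj, _ = simulate_trajectories(cfg)
        bank = y_signal_bank(traj)
        conditioned = condition_bank(bank)
        row = bandpass(Signal1D(bank.channels[0], bank.fs)).samples
        replaced = np.mean(conditioned.channels[0] != row)
        assert replaced > 0.0


class TestScenarios:
    def test_presets(self):
        assert scenario("normal").motion_rate == 0.0
        assert scenario("normal").expression_fraction == 0.0
        assert scenario("hci").illum_amp > scenario("normal").illum_amp
        assert scenario("expressions").expression_fraction == pytest.approx(0.4)

    def test_deterministic_presets(self):
        assert scenario("hci") == scenario("hci")

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError):
            scenario("outdoors")

    def test_same_seed_bit_identical(self):
        cfg = replace(scenario("hci"), seed=11)
        t1, g1 = simulate_rgb(cfg)
        t2, g2 = simulate_rgb(cfg)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.g, b.g)
        np.testing.assert_array_equal(g1.bpm, g2.bpm)
        tr1, _ = simulate_trajectories(cfg)
        tr2, _ = simulate_trajectories(cfg)
        np.testing.assert_array_equal(tr1.ys, tr2.ys)

    def test_random_hr_trajectory_in_range(self):
        traj = random_hr_trajectory(5, 60.0)
        bpm = np.array([b for _, b in traj])
        assert np.all((bpm >= 45.0) & (bpm <= 150.0))
        assert random_hr_trajectory(5, 60.0) == traj


class TestNoiseMonotonicity:
    def test_illumination_degrades_rppg(self):
        """Seed-mean rPPG MAE is non-decreasing in illumination amplitude."""
        maes = []
        for amp in (0.0, 1.0, 2.0, 4.0):
            errs = []
            for seed in range(20):
                cfg = SimConfig(
                    illum_amp=amp, seed=seed,
                    hr_bpm=random_hr_trajectory(seed + 1000, 60.0),
                )
                traces, gt = simulate_rgb(cfg)
                est = windowed_hr(rppg_from_traces(traces, seed=seed),
                                  method="RPPG")
                errs.append(agreement(est, reference_series(gt)).mae)
            maes.append(float(np.mean(errs)))
        assert all(b >= a for a, b in zip(maes, maes[1:]))
        assert maes[-1] > maes[0]

    def test_motion_degrades_rbcg(self):
        """Seed-mean rBCG MAE is non-decreasing in motion amplitude."""
        maes = []
        for amp in (0.0, 5.0, 10.0, 20.0):
            errs = []
            for seed in range(20):
                cfg = SimConfig(
                    motion_rate=6.0, motion_amp=amp, seed=seed,
                    hr_bpm=random_hr_trajectory(seed + 1000, 60.0),
                )
                traj, gt = simulate_trajectories(cfg)
                est = windowed_hr(rbcg_from_trajectories(traj), method="RBCG")
                errs.append(agreement(est, reference_series(gt)).mae)
            maes.append(float(np.mean(errs)))
        assert all(b >= a for a, b in zip(maes, maes[1:]))
        assert maes[-1] > maes[0]


@pytest.fixture(scope="module")
def clip():
    cfg = SimConfig(duration=20.0, hr_bpm=72.0, seed=5, illum_amp=0.2)
    return cfg, render_clip(cfg)


class TestRenderClip:
    def test_shapes_and_boxes(self, clip):
        cfg, rc = clip
        assert rc.frames.shape == (cfg.n_frames, 240, 320, 3)
        assert rc.frames.dtype == np.uint8
        assert len(rc.face_boxes) == cfg.n_frames

    def test_roi_traces_match_driving_signal(self, clip):
        """Extracting mean RGB from the rendered ROIs reproduces the
        simulated traces within 1 8-bit unit RMS."""
        from pulsefuse.geometry import FaceBox, compute_rois
        from pulsefuse.ppg import extract_rgb_traces

        cfg, rc = clip
        rois_by_frame = []
        for i in range(cfg.n_frames):
            b = rc.face_boxes[i]
            rois_by_frame.append({r.name: r for r in compute_rois(b)})
        traces = extract_rgb_traces(rc.frames, rois_by_frame, cfg.fps)
        driving = {t.roi: t for t in rc.traces}
        for t in traces:
            for ch in ("r", "g", "b"):
                err = getattr(t, ch) - getattr(driving[t.roi], ch)
                assert np.sqrt(np.mean(err**2)) <= 1.0

    def test_static_clip_zero_displacement(self):
        from pulsefuse.geometry import track_video

        cfg = SimConfig(duration=20.0, fps=10.0, hr_bpm=72.0, seed=6,
                        bcg_amp=0.0, illum_amp=0.0, motion_rate=0.0,
                        pulse_amp_rgb=0.0, rgb_noise=0.0)
        rc = render_clip(cfg)
        res = track_video(rc.frames, rc.face_boxes, cfg.fps)
        assert np.abs(np.diff(res.trajectories.ys, axis=1)).max() < 0.1

    def test_jump_triggers_redetection(self):
        from pulsefuse.geometry import track_video

        cfg = SimConfig(duration=20.0, fps=10.0, hr_bpm=72.0, seed=6,
                        illum_amp=0.0)
        rc = render_clip(cfg, motion_jump_px=12.0, jump_frame=100)
        res = track_video(rc.frames, rc.face_boxes, cfg.fps)
        assert 100 in res.reset_frames
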