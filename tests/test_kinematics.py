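"""Filtering, local frames, heel-point estimation, deformation track."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heelstrike.errors import (
    EventNotFoundError,
    GeometryError,
    InputError,
    SynchronizationError,
)
from heelstrike.forceplate import GRFSeries, detect_contact_onset, detect_impact_peak, reduce_channels
from heelstrike.kinematics import (
    FrameSeries,
    HeelTrack,
    LocalCOP,
    MarkerSeries,
    build_local_frames,
    detect_deformation_end,
    estimate_heel_point,
    localize_cop,
    reconstruct_heel_track,
    zero_phase_lowpass,
)

RATE = 1295.0


class TestZeroPhaseLowpass:
    def test_dc_gain_is_unity(self):
        out = zero_phase_lowpass(np.full(500, 5.0), 100.0, RATE)
        np.testing.assert_allclose(out, 5.0, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(0, 1.0, 1 / RATE)
        out = zero_phase_lowpass(np.sin(2 * np.pi * 10 * t), 100.0, RATE)
        assert np.max(np.abs(out[200:-200])) >= 0.999

    def test_stopband_attenuation_matches_closed_form(self):
        # forward-backward 2nd-order Butterworth: |H(f)|^2 with the
        # bilinear-transform frequency warping
        f = 300.0
        t = np.arange(0, 2.0, 1 / RATE)
        out = zero_phase_lowpass(np.sin(2 * np.pi * f * t), 100.0, RATE)
        expected = 1.0 / (1.0 + (np.tan(np.pi * f / RATE) / np.tan(np.pi * 100.0 / RATE)) ** 4)
        measured = np.max(np.abs(out[500:-500]))
        assert measured == pytest.approx(expected, rel=0.01)

    def test_zero_phase_keeps_pulse_peak(self):
        t = np.arange(0, 1.0, 1 / RATE)
        pulse = np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2)
        out = zero_phase_lowpass(pulse, 100.0, RATE)
        assert abs(t[np.argmax(out)] - 0.5) <= 1 / RATE + 1e-12

    def test_too_short_series_rejected(self):
        with pytest.raises(InputError, match="short"):
            zero_phase_lowpass(np.zeros(5), 100.0, RATE)

    def test_undersampled_rejected(self):
        with pytest.raises(InputError, match="cutoff"):
            zero_phase_lowpass(np.zeros(100), 100.0, 150.0)


def _static_markers(led1, led2, n=50):
    t = np.arange(n) / RATE
    return MarkerSeries(time=t, led1=np.tile(led1, (n, 1)), led2=np.tile(led2, (n, 1)))


class TestBuildLocalFrames:
    def test_vertical_leds_give_identity(self):
        frames = build_local_frames(_static_markers([0, 0, 0], [0, 0, 0.16]))
        np.testing.assert_allclose(frames.rotation[0], np.eye(3), atol=1e-12)

    def test_tilt_about_x_is_recovered(self):
        th = np.deg2rad(10.0)
        led2 = [0.0, -0.16 * np.sin(th), 0.16 * np.cos(th)]
        frames = build_local_frames(_static_markers([0, 0, 0], led2))
        Rx = np.array([[1, 0, 0],
                       [0, np.cos(th), -np.sin(th)],
                       [0, np.sin(th), np.cos(th)]])
        np.testing.assert_allclose(frames.rotation[0], Rx, atol=1e-12)
        np.testing.assert_allclose(frames.rotation[0][:, 0], [1, 0, 0], atol=1e-12)

    def test_simulator_constant_tilt_recovered(self):
        from heelstrike.synthetic import SimConfig, render_markers, simulate_heel_impact

        cfg = SimConfig(tilt_deg=5.0, tilt_ramp=0.0, noise_marker_sd=0.0)
        sol, _ = simulate_heel_impact(cfg)
        markers = render_markers(sol, cfg)
        frames = build_local_frames(markers)
        th = np.deg2rad(5.0)
        Rx = np.array([[1, 0, 0],
                       [0, np.cos(th), -np.sin(th)],
                       [0, np.sin(th), np.cos(th)]])
        np.testing.assert_allclose(frames.rotation, np.broadcast_to(Rx, frames.rotation.shape),
                                   atol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-80, 80), st.floats(-80, 80), st.floats(-0.05, 0.05))
    def test_frames_orthonormal_with_y_in_progression_plane(self, tilt_x, tilt_y, dx):
        """Orthonormality, det +1, and zero global-X component of local y."""
        thx, thy = np.deg2rad(tilt_x), np.deg2rad(tilt_y)
        direction = np.array([
            np.sin(thy), -np.cos(thy) * np.sin(thx), np.cos(thy) * np.cos(thx)
        ])
        led1 = np.array([dx, 0.0, 0.0])
        frames = build_local_frames(_static_markers(led1, led1 + 0.16 * direction, n=12))
        R = frames.rotation[0]
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)
        assert R[0, 1] == pytest.approx(0.0, abs=1e-12)   # y has no global-X part
        assert R[1, 1] >= 0                                # anterior-positive y
        np.testing.assert_allclose(R[:, 2], direction, atol=1e-10)

    def test_coincident_leds_rejected(self):
        with pytest.raises(GeometryError, match="sample index"):
            build_local_frames(_static_markers([0, 0, 0], [0, 0, 0]))

    def test_z_parallel_to_global_x_rejected(self):
        with pytest.raises(GeometryError, match="y undefined"):
            build_local_frames(_static_markers([0, 0, 0], [0.16, 0, 0]))


def _grf_const_cop(t, cop, fz=100.0):
    n = t.size
    return GRFSeries(time=t, F_X=np.zeros(n), F_Y=np.zeros(n), F_Z=np.full(n, fz),
                     cop_X=np.full(n, cop[0]), cop_Y=np.full(n, cop[1]),
                     cop_valid=np.ones(n, bool))


class TestLocalizeCop:
    def test_static_identity_frames(self):
        mk = _static_markers([0, 0, 0.1], [0, 0, 0.26])
        frames = build_local_frames(mk)
        grf = _grf_const_cop(mk.time, (0.3, 0.5))
        local = localize_cop(frames, grf)
        expected = np.array([0.3, 0.5, -0.1])
        np.testing.assert_allclose(local.xyz[local.valid] - expected, 0.0, atol=1e-12)

    def test_pure_translation(self):
        mk = _static_markers([0.1, 0, 0.1], [0.1, 0, 0.26])
        frames = build_local_frames(mk)
        local = localize_cop(frames, _grf_const_cop(mk.time, (0.3, 0.5)))
        expected = np.array([0.2, 0.5, -0.1])
        np.testing.assert_allclose(local.xyz[local.valid] - expected, 0.0, atol=1e-12)

    def test_no_overlap_raises(self):
        mk = _static_markers([0, 0, 0.1], [0, 0, 0.26])
        frames = build_local_frames(mk)
        t_late = mk.time + 10.0
        with pytest.raises(SynchronizationError):
            localize_cop(frames, _grf_const_cop(t_late, (0.3, 0.5)))


class TestEstimateHeelPoint:
    def _window_setup(self, local_xyz_value=(0.01, -0.03, -0.06)):
        tf = np.arange(0, 0.1, 1 / 3000.0)
        fz = np.interp(tf, [0, 0.02, 0.05, 0.1], [0, 0, 400, 0])
        grf = GRFSeries(time=tf, F_X=0 * tf, F_Y=0 * tf, F_Z=fz,
                        cop_X=0 * tf, cop_Y=0 * tf, cop_valid=fz > 10)
        tk = np.arange(0, 0.1, 1 / RATE)
        xyz = np.tile(local_xyz_value, (tk.size, 1))
        local = LocalCOP(time=tk, xyz=xyz, valid=np.ones(tk.size, bool))
        return local, grf

    def test_constant_cloud_recovered(self):
        local, grf = self._window_setup()
        r_H = estimate_heel_point(local, grf, t_p=0.05)
        np.testing.assert_allclose(r_H, [0.01, -0.03, -0.06], atol=1e-12)

    def test_median_robust_to_outlier(self):
        local, grf = self._window_setup()
        r_clean = estimate_heel_point(local, grf, t_p=0.05)
        local.xyz[60] = [5.0, 5.0, 5.0]  # wild outlier inside the window
        r_dirty = estimate_heel_point(local, grf, t_p=0.05)
        np.testing.assert_allclose(r_dirty, r_clean, atol=1e-9)

    def test_simulator_pure_translation_recovery(self):
        """Noiseless zero-tilt trial: x, y exact; z biased by the median
        penetration over the window (the heel point moves through the
        ground while the COP stays on it)."""
        from heelstrike.synthetic import SimConfig, render_trial

        cfg = SimConfig(tilt_deg=0.0, tilt_ramp=0.0, noise_marker_sd=0.0,
                        noise_channel_sd=0.0)
        rec, markers, truth = render_trial(cfg)
        grf = reduce_channels(rec, cfg.plate)
        t0 = detect_contact_onset(grf)
        t_p = detect_impact_peak(grf, t0)
        frames = build_local_frames(markers)
        local = localize_cop(frames, grf)
        r_H = estimate_heel_point(local, grf, t_p)
        true_r = np.asarray(cfg.cop_local)
        np.testing.assert_allclose(r_H[:2], true_r[:2], atol=1e-4)
        max_pen = float(truth.deformation.max())
        assert true_r[2] - 1e-6 <= r_H[2] <= true_r[2] + max_pen

    def test_noisy_recovery_within_half_mm(self):
        """Pure translation with study-level noise: x, y within 0.5 mm."""
        from heelstrike.kinematics import filter_markers
        from heelstrike.synthetic import SimConfig, render_trial

        cfg = SimConfig(tilt_deg=0.0, noise_marker_sd=1e-4,
                        noise_channel_sd=0.25, sync_jitter=8e-4, seed=42)
        rec, markers, _ = render_trial(cfg)
        grf = reduce_channels(rec, cfg.plate)
        t0 = detect_contact_onset(grf)
        t_p = detect_impact_peak(grf, t0)
        frames = build_local_frames(filter_markers(markers))
        local = localize_cop(frames, grf)
        r_H = estimate_heel_point(local, grf, t_p)
        np.testing.assert_allclose(r_H[:2], np.asarray(cfg.cop_local)[:2], atol=5e-4)


class TestHeelTrack:
    def test_static_frames_zero_deformation(self):
        mk = _static_markers([0, 0, 0.1], [0, 0, 0.26], n=100)
        frames = build_local_frames(mk)
        track = reconstruct_heel_track(frames, np.array([0.0, -0.05, -0.1]), t0=0.01)
        np.testing.assert_allclose(track.S, 0.0, atol=1e-12)
        np.testing.assert_allclose(track.Zdot_H, 0.0, atol=1e-12)

    def test_constant_descent_velocity_exact(self):
        t = np.arange(200) / RATE
        led1 = np.column_stack([0 * t, 0 * t, 0.3 - 0.5 * t])
        led2 = led1 + [0, 0, 0.16]
        frames = build_local_frames(MarkerSeries(time=t, led1=led1, led2=led2))
        track = reconstruct_heel_track(frames, np.zeros(3), t0=0.02)
        np.testing.assert_allclose(track.Zdot_H[1:-1], -0.5, atol=1e-9)
        # S at t0 vanishes by construction
        assert abs(np.interp(0.02, track.time, track.S[:, 2])) < 1e-12

    def test_simulator_touchdown_velocity(self, clean_result):
        result, inter = clean_result
        assert result.Zdot_t0 == pytest.approx(-0.57, abs=0.02)

    def test_t0_outside_range_rejected(self):
        mk = _static_markers([0, 0, 0.1], [0, 0, 0.26])
        frames = build_local_frames(mk)
        with pytest.raises(SynchronizationError):
            reconstruct_heel_track(frames, np.zeros(3), t0=5.0)


class TestDeformationEnd:
    def test_analytic_sinusoid(self):
        t = np.arange(0, 0.12, 1 / RATE)
        z = -0.01 * np.sin(np.pi * t / 0.06)
        track = HeelTrack(time=t, r_H=np.zeros(3),
                          R_H=np.column_stack([0 * t, 0 * t, z]),
                          S=np.column_stack([0 * t, 0 * t, z]),
                          Zdot_H=np.gradient(z, t), t0=0.0)
        t_e = detect_deformation_end(track, t0=0.0)
        assert t_e == pytest.approx(0.03, abs=1.5 / RATE)

    def test_damped_trial_matches_truth(self, clean_result, clean_trial):
        result, _ = clean_result
        truth = clean_trial[2]
        assert abs(result.t_e - truth.t_e_true) <= 1 / RATE + 1e-9

    def test_undamped_te_equals_tp(self, undamped_trial):
        rec, markers, truth, cfg = undamped_trial
        from heelstrike import process_records

        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = process_records(rec, markers)
        assert abs(result.t_e - result.t_p) <= 1 / cfg.force_rate + 1e-9

    def test_no_crossing_raises(self):
        t = np.arange(0, 0.3, 1 / RATE)
        z = -0.5 * t  # monotone descent, never stops
        track = HeelTrack(time=t, r_H=np.zeros(3),
                          R_H=np.column_stack([0 * t, 0 * t, z]),
                          S=np.column_stack([0 * t, 0 * t, z]),
                          Zdot_H=np.gradient(z, t), t0=0.0)
        with pytest.raises(EventNotFoundError):
            detect_deformation_end(track, t0=0.0)


def test_inter_marker_distance_warning():
    t = np.arange(50) / RATE
    led1 = np.zeros((50, 3))
    led2 = np.tile([0, 0, 0.16], (50, 1))
    led2[25, 2] += 0.005  # 5 mm excursion
    with pytest.warns(UserWarning, match="inter-marker"):
        MarkerSeries(time=t, led1=led1, led2=led2)
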