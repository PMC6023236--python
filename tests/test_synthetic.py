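"""Simulator physics, rendering fidelity, fixture-study generation."""

import warnings

import numpy as np
import pytest

from heelstrike import PipelineConfig, process_records
from heelstrike.errors import ConfigError, RenderError
from heelstrike.forceplate import reduce_channels
from heelstrike.synthetic import (
    SimConfig,
    make_fixture_study,
    render_markers,
    render_plate_channels,
    render_trial,
    simulate_heel_impact,
)
from tests.conftest import make_clean_config


class TestImpactDynamics:
    def test_undamped_matches_linear_oscillator(self):
        """c = 0, n = 1: in contact the mass follows
        z(t) = -(g/w^2)(1 - cos wt) + (v0/w) sin wt with w = sqrt(k/M);
        the end of compression (v = 0) solves tan wt = v0 w / g with
        wt in (pi/2, pi)."""
        cfg = make_clean_config(c=0.0)
        _, truth = simulate_heel_impact(cfg)
        w = np.sqrt(cfg.k / cfg.mass)
        g = 9.81
        t_e_exact = (np.pi - np.arctan(-cfg.v0 * w / g)) / w
        t_e_sim = truth.t_e_true - truth.touchdown_time
        assert t_e_sim == pytest.approx(t_e_exact, rel=1e-3)
        z_exact = -(g / w**2) * (1 - np.cos(w * t_e_exact)) + (cfg.v0 / w) * np.sin(w * t_e_exact)
        i_e = np.searchsorted(truth.t, t_e_sim)
        assert truth.z[i_e] == pytest.approx(z_exact, rel=1e-3)

    def test_conservative_contact_energy(self):
        """c = 0: nothing dissipates and the contact work at t_e equals
        -(KE at touchdown + potential drop)."""
        cfg = make_clean_config(c=0.0)
        _, truth = simulate_heel_impact(cfg)
        assert np.all(truth.dissipated_energy == 0.0)
        t_e = truth.t_e_true - truth.touchdown_time
        i_e = np.searchsorted(truth.t, t_e)
        delta = truth.deformation[i_e]
        expected = -(0.5 * cfg.mass * cfg.v0**2 + cfg.mass * 9.81 * delta)
        assert truth.work_by_contact[i_e] == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("zeta", [0.0, 0.2, 0.35, 0.6, 1.0])
    def test_energy_audit(self, zeta):
        cfg = make_clean_config(c=zeta * 2 * np.sqrt(15e3 * 8.5))
        _, truth = simulate_heel_impact(cfg)
        max_ke = 0.5 * cfg.mass * cfg.v0**2
        assert truth.audit_residual() <= 1e-6 * max_ke
        assert np.all(np.diff(truth.dissipated_energy) >= -1e-15)

    def test_damped_default_looks_like_walking(self):
        """Default parameters give impact timing and deformation of the
        magnitude observed in barefoot walking."""
        cfg = make_clean_config()
        _, truth = simulate_heel_impact(cfg)
        assert truth.t_p_true < truth.t_e_true
        t_p = truth.t_p_true - truth.touchdown_time
        delta_e = truth.summary()["deformation_te"]
        assert 0.010 <= t_p <= 0.030
        assert 0.005 <= delta_e <= 0.020  # millimetre range, ~13 mm scale

    def test_upward_v0_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(v0=0.1)


class TestRenderChannels:
    def test_centred_load_splits_evenly(self):
        from heelstrike.synthetic import channels_for_load

        geom = SimConfig().plate
        ch = channels_for_load(0.0, 0.0, 400.0, 0.0, 0.0, geom)
        for i in range(1, 5):
            assert ch[f"fz{i}"][0] == pytest.approx(100.0)

    def test_noiseless_roundtrip(self, clean_trial):
        rec, _, truth, cfg = clean_trial
        sol, _ = simulate_heel_impact(cfg)
        grf = reduce_channels(rec, cfg.plate)
        # recovered F_Z equals the simulated contact force at stamp times
        ts = rec.time - cfg.lead_in
        expected = np.interp(ts, sol.t, sol.F, left=0.0, right=0.0)
        np.testing.assert_allclose(grf.F_Z, expected, rtol=1e-9, atol=1e-9)
        # COP equals the touchdown point wherever valid
        np.testing.assert_allclose(grf.cop_X[grf.cop_valid], cfg.touchdown_xy[0],
                                   rtol=1e-9)
        np.testing.assert_allclose(grf.cop_Y[grf.cop_valid], cfg.touchdown_xy[1],
                                   rtol=1e-9)

    def test_jitter_shifts_events_but_not_energies(self):
        results = {}
        for jitter in (0.0, 8e-4):
            cfg = make_clean_config(sync_jitter=jitter)
            rec, markers, _ = render_trial(cfg)
            results[jitter] = process_records(rec, markers)
        dt0 = abs(results[8e-4].t0 - results[0.0].t0)
        assert dt0 <= 1e-3 + 1e-9
        # the dominant jitter effect is the shifted deformation reference:
        # |v0| * jitter / |S_Z(t_e)| ~ 0.46 mm / 12.9 mm ~ 4%
        assert results[8e-4].W == pytest.approx(results[0.0].W, rel=0.05)
        assert results[8e-4].M_e == pytest.approx(results[0.0].M_e, rel=0.03)

    def test_cop_outside_plate_rejected(self):
        cfg = make_clean_config(touchdown_xy=(0.5, 0.0))
        sol, _ = simulate_heel_impact(cfg)
        with pytest.raises(RenderError):
            render_plate_channels(sol, cfg)


class TestRenderMarkers:
    def test_inter_led_distance(self, clean_trial):
        _, markers, _, cfg = clean_trial
        d = markers.inter_marker_distance()
        np.testing.assert_allclose(d, 0.16, atol=1e-12)

    def test_marker_noise_propagates_to_distance(self):
        cfg = SimConfig(noise_marker_sd=1e-4, noise_channel_sd=0.0, seed=11)
        sol, _ = simulate_heel_impact(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            markers = render_markers(sol, cfg)
        d = markers.inter_marker_distance()
        # distance error ~ N(0, sqrt(2) * sd) for small noise
        assert np.std(d) == pytest.approx(np.sqrt(2) * 1e-4, rel=0.25)

    def test_pure_translation_heel_point_xy_exact(self):
        """Zero noise, zero tilt: the estimated heel point matches the
        configured local offset exactly in x and y; the z component
        carries the penetration of the heel point through the plate
        surface (a property of the COP-median definition itself)."""
        from heelstrike.forceplate import detect_contact_onset, detect_impact_peak
        from heelstrike.kinematics import build_local_frames, estimate_heel_point, localize_cop

        cfg = make_clean_config(tilt_deg=0.0, tilt_ramp=0.0)
        rec, markers, truth = render_trial(cfg)
        grf = reduce_channels(rec, cfg.plate)
        t0 = detect_contact_onset(grf)
        t_p = detect_impact_peak(grf, t0)
        frames = build_local_frames(markers)  # unfiltered: noiseless
        local = localize_cop(frames, grf)
        r_H = estimate_heel_point(local, grf, t_p)
        np.testing.assert_allclose(r_H[:2], np.asarray(cfg.cop_local)[:2],
                                   rtol=0, atol=1e-9)
        bias = r_H[2] - cfg.cop_local[2]
        assert 0.0 <= bias <= truth.deformation.max() + 1e-9


class TestFixtureStudy:
    def test_deterministic_given_seed(self):
        a = make_fixture_study(n_subjects=2, n_trials=2, seed=5)
        b = make_fixture_study(n_subjects=2, n_trials=2, seed=5)
        assert len(a) == len(b) == 4
        for ta, tb in zip(a, b):
            assert ta["config"] == tb["config"]
            np.testing.assert_array_equal(ta["channels"].fz1, tb["channels"].fz1)
            np.testing.assert_array_equal(ta["markers"].led1, tb["markers"].led1)
            assert ta["truth"].summary() == tb["truth"].summary()

    def test_damping_sweep_increases_te_over_tp(self):
        ratios = []
        for c in (50.0, 150.0, 250.0, 350.0, 450.0):
            cfg = make_clean_config(c=c)
            _, truth = simulate_heel_impact(cfg)
            ratios.append(
                (truth.t_e_true - truth.touchdown_time)
                / (truth.t_p_true - truth.touchdown_time)
            )
        assert all(r2 > r1 for r1, r2 in zip(ratios, ratios[1:]))
        assert ratios[0] > 1.0

    def test_aggregate_recovers_truth_work(self):
        """End-to-end: the fixture study's mean estimated work matches
        the truth-ledger work over the same intervals within 15%."""
        from heelstrike.study import aggregate

        trials = make_fixture_study(n_subjects=4, n_trials=3, seed=9)
        results, truths = [], []
        for tr in trials:
            res = process_records(
                tr["channels"], tr["markers"],
                PipelineConfig(body_mass=tr["config"].body_mass),
                subject_id=tr["subject_id"], trial_id=tr["trial_id"],
            )
            results.append(res)
            truths.append(tr["truth"].total_work_between(res.t0, res.t_e))
        _, study = aggregate(results)
        assert study.overall_mean["W"] == pytest.approx(np.mean(truths), rel=0.15)
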