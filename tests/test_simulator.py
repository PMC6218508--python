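"""Physics of the forward simulator: environment forces, plant dynamics,
the trial-to-trial learner, and EMG synthesis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cocoadapt import (
    LearnerState,
    SimConfig,
    channel_force,
    curl_field_force,
    simulate_pulse_trial,
    simulate_reach,
    update_learner,
)
from cocoadapt.adaptation import adaptation_score, channel_profile
from cocoadapt.kinematics import max_perpendicular_error
from cocoadapt.simulator import (
    iter_experiment,
    minimum_jerk,
    pulse_displacement,
    synthesize_emg,
)
from cocoadapt.trialdata import ScheduleSpec, TrialDescriptor


def _desc(trial_type, target=90.0, trial_id=1):
    return TrialDescriptor(trial_id, "exposure", trial_type, target, 1)


class TestEnvironmentForces:
    def test_curl_force_matches_gain_times_velocity(self):
        np.testing.assert_allclose(curl_field_force((0.0, 0.5), 16.0), [-8.0, 0.0])
        np.testing.assert_allclose(curl_field_force((0.0, 0.0), 16.0), [0.0, 0.0])

    @given(vx=st.floats(-2, 2), vy=st.floats(-2, 2), b=st.floats(-20, 20))
    @settings(deadline=None, derandomize=True)
    def test_curl_force_does_no_work(self, vx, vy, b):
        f = curl_field_force((vx, vy), b)
        assert abs(f[0] * vx + f[1] * vy) <= 1e-12 * (1 + abs(b) * (vx * vx + vy * vy))

    def test_channel_restoring_force(self):
        # 1 mm lateral deviation, no lateral velocity, 6000 N/m wall
        f = channel_force((-0.001, 0.05), (0.0, 0.3), (0.0, 1.0))
        np.testing.assert_allclose(f, [6.0, 0.0], atol=1e-12)

    def test_channel_force_zero_on_axis(self):
        f = channel_force((0.0, 0.08), (0.0, 0.4), (0.0, 1.0))
        np.testing.assert_allclose(f, [0.0, 0.0], atol=1e-12)

    @given(e=st.floats(-0.01, 0.01), ed=st.floats(-0.2, 0.2), ang=st.floats(0, 2 * math.pi))
    @settings(deadline=None, derandomize=True)
    def test_channel_force_has_no_component_along_axis(self, e, ed, ang):
        axis = np.array([math.cos(ang), math.sin(ang)])
        lat = np.array([-axis[1], axis[0]])
        f = channel_force(0.05 * axis + e * lat, 0.3 * axis + ed * lat, axis)
        assert abs(f @ axis) < 1e-9


class TestMinimumJerk:
    def test_peak_speed_is_1875_l_over_t(self):
        t = np.linspace(0, 0.45, 4501)
        _, v, _ = minimum_jerk(t, 0.45, 0.12)
        assert np.max(v) == pytest.approx(1.875 * 0.12 / 0.45, rel=1e-6)

    def test_endpoints(self):
        t = np.array([0.0, 0.45])
        s, v, _ = minimum_jerk(t, 0.45, 0.12)
        np.testing.assert_allclose(s, [0.0, 0.12])
        np.testing.assert_allclose(v, [0.0, 0.0], atol=1e-12)


class TestLearner:
    def test_single_field_trial_arithmetic(self):
        cfg = SimConfig(retention_a=1.0)
        s = update_learner(LearnerState(0.0), "field", cfg, b_eff=0.1)
        assert s.k_internal == pytest.approx(0.1)

    def test_closed_form_recursion(self):
        cfg = SimConfig(retention_a=1.0)
        s = LearnerState(0.0)
        ks = []
        for _ in range(50):
            s = update_learner(s, "field", cfg, b_eff=0.07)
            ks.append(s.k_internal)
        expected = 1 - (1 - 0.07) ** np.arange(1, 51)
        np.testing.assert_allclose(ks, expected, rtol=1e-12)
        assert np.all(np.diff(ks) > 0)

    def test_no_learning_when_rate_zero(self):
        cfg = SimConfig(retention_a=1.0)
        s = update_learner(LearnerState(0.4), "field", cfg, b_eff=0.0)
        assert s.k_internal == 0.4

    def test_retention_on_channel_and_rest_break(self):
        cfg = SimConfig(retention_a=0.9)
        s = update_learner(LearnerState(1.0), "channel", cfg, b_eff=0.5)
        assert s.k_internal == pytest.approx(0.9)
        s = update_learner(LearnerState(1.0), "channel", cfg, b_eff=0.5,
                           rest_break_after=True)
        assert s.k_internal == pytest.approx(0.81)


class TestPulseTrials:
    def test_ballistic_displacement_closed_form(self, rng):
        # free 2 kg mass, no stiffness/damping: x(T) = F T^2 / (2 m)
        cfg = SimConfig(mass_kg=2.0, k_hold_base_n_m=0.0, k_coco_n_m=0.0,
                        d_base_ns_m=0.0, d_coco_ns_m=0.0, motor_noise_sd_n=0.0,
                        emg_gain_jitter_cv=0.0)
        tr = simulate_pulse_trial(cfg, 0.0, 0.0, rng)
        i_end = int(round((cfg.pulse_hold_pre_s + cfg.pulse_duration_s) * 1000))
        x_end = tr.pos_m[i_end, 0]
        assert x_end == pytest.approx(0.5 * 5.0 / 2.0 * 0.5**2, rel=5e-3)

    def test_quasi_static_displacement(self, rng):
        # overdamped K_total = 2000 N/m: settles near F/K = 2.5 mm
        cfg = SimConfig(k_hold_base_n_m=2000.0, k_coco_n_m=0.0, d_base_ns_m=250.0,
                        d_coco_ns_m=0.0, motor_noise_sd_n=0.0, emg_gain_jitter_cv=0.0)
        tr = simulate_pulse_trial(cfg, 30.0, 0.0, rng)
        d, inside = pulse_displacement(tr)
        assert d == pytest.approx(5.0 / 2000.0, rel=0.1)
        assert inside

    def test_displacement_monotone_in_stiffness(self, rng):
        disps = []
        for k in (100.0, 400.0, 1600.0):
            cfg = SimConfig(k_hold_base_n_m=k, k_coco_n_m=0.0, d_base_ns_m=40.0,
                            d_coco_ns_m=0.0, motor_noise_sd_n=0.0,
                            emg_gain_jitter_cv=0.0)
            disps.append(pulse_displacement(simulate_pulse_trial(cfg, 90.0, 0.0, rng))[0])
        assert disps[0] > disps[1] > disps[2]


class TestReachTrials:
    def test_unperturbed_null_reach_is_straight(self, quiet_config, rng):
        tr = simulate_reach(LearnerState(0.0), _desc("null"), quiet_config, rng,
                            c=0.5, b_session=16.0)
        assert np.max(np.abs(tr.pos_m[:, 0])) < 1e-6  # off-axis for the 90 deg target

    def test_full_compensation_scores_near_100(self, quiet_config, rng):
        tr = simulate_reach(LearnerState(1.0), _desc("channel"), quiet_config, rng,
                            c=0.0, b_session=16.0)
        score = adaptation_score(channel_profile(tr, 16.0))
        assert 90.0 < score < 102.0

    def test_field_error_decreases_with_cocontraction(self, quiet_config):
        mpes = []
        for c in (0.0, 1.0, 2.0):
            rng = np.random.default_rng(9)
            tr = simulate_reach(LearnerState(0.0), _desc("field"), quiet_config, rng,
                                c=c, b_session=16.0)
            mpes.append(abs(max_perpendicular_error(tr)))
        assert mpes[0] > mpes[1] > mpes[2]

    def test_after_effect_mirrors_field_deviation(self, quiet_config):
        rng = np.random.default_rng(11)
        field_tr = simulate_reach(LearnerState(0.0), _desc("field"), quiet_config,
                                  rng, c=0.4, b_session=16.0)
        null_tr = simulate_reach(LearnerState(0.8), _desc("null"), quiet_config,
                                 rng, c=0.4, b_session=16.0)
        m_field = max_perpendicular_error(field_tr)
        m_null = max_perpendicular_error(null_tr)
        assert np.sign(m_field) == -np.sign(m_null)
        assert abs(m_null) > 1e-3


class TestSyntheticEMG:
    def test_baseline_only_at_rest(self, quiet_config, rng):
        n = 1000
        zeros = np.zeros((n, 2))
        _, emg = synthesize_emg(zeros, zeros, 0.0, quiet_config, rng)
        # envelope = baseline everywhere: sample std matches baseline
        assert emg.to_numpy().std() == pytest.approx(quiet_config.emg_baseline, rel=0.05)

    def test_envelope_scales_with_cocontraction(self, quiet_config):
        n = 2000
        zeros = np.zeros((n, 2))
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        _, low = synthesize_emg(zeros, zeros, 0.0, quiet_config, rng1)
        _, high = synthesize_emg(zeros, zeros, 1.0, quiet_config, rng2)
        ratio = high.to_numpy().std() / low.to_numpy().std()
        expected = (quiet_config.emg_baseline + quiet_config.emg_coco_gain) / quiet_config.emg_baseline
        assert ratio == pytest.approx(expected, rel=1e-6)

    def test_emg_rate_doubles_kinematic_rate(self, quiet_config, rng):
        uff = np.zeros((500, 2))
        t, emg = synthesize_emg(uff, uff, 0.0, quiet_config, rng)
        assert len(emg) == 1000
        assert t[1] - t[0] == pytest.approx(1 / 2000)


class TestExperiment:
    def test_same_seed_reproduces_dataset(self, tiny_spec):
        cfg = SimConfig()
        a = list(iter_experiment(tiny_spec, cfg, seed=5, n_per_group=1,
                                 groups=("stiff",)))[0]
        b = list(iter_experiment(tiny_spec, cfg, seed=5, n_per_group=1,
                                 groups=("stiff",)))[0]
        assert len(a.trials) == len(b.trials)
        for ta, tb in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta.pos_m, tb.pos_m)
            np.testing.assert_array_equal(ta.emg.to_numpy(), tb.emg.to_numpy())

    def test_counterbalanced_directions_and_phases(self, tiny_spec):
        cfg = SimConfig()
        sessions = list(iter_experiment(tiny_spec, cfg, seed=6, n_per_group=2))
        assert len(sessions) == 6
        for sess in sessions:
            phases = {t.phase for t in sess.trials}
            if sess.group == "control":
                assert "pulse" not in phases
            else:
                assert "pulse" in phases
        dirs = {s.group: [x.field_direction for x in sessions if x.group == s.group]
                for s in sessions}
        for group, ds in dirs.items():
            assert set(ds) == {"ccw", "cw"}
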