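"""Force-compensation scoring, oscillation index, and sign adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cocoadapt import SimConfig, adaptation_score, channel_profile, ideal_force, sign_adjust
from cocoadapt.adaptation import (
    ChannelForceProfile,
    DegenerateProfile,
    IllPosedRegression,
    _speed_mask,
    oscillation_index,
)
from cocoadapt.simulator import LearnerState, minimum_jerk, simulate_reach
from cocoadapt.trialdata import TrialDescriptor
from conftest import make_reach_trial


def bell_profile(n=450, peak=8.0):
    """A minimum-jerk-speed-shaped ideal force profile with full mask."""
    t = np.linspace(0, 0.45, n)
    _, v, _ = minimum_jerk(t, 0.45, 0.12)
    f_i = peak / v.max() * v
    speed = v
    mask = _speed_mask(speed)
    return t, f_i, speed, mask


def profile_with(f_a, f_i=None):
    t, fi, speed, mask = bell_profile()
    if f_i is not None:
        fi = f_i
    return ChannelForceProfile(t=t, f_a=np.asarray(f_a, float), f_i=fi,
                               speed=speed, mask=mask)


class TestAdaptationScore:
    def test_exact_proportionality(self):
        t, fi, speed, mask = bell_profile()
        p = ChannelForceProfile(t, 0.5 * fi, fi, speed, mask)
        assert adaptation_score(p) == pytest.approx(50.0, abs=1e-12)

    def test_orthogonal_profile_scores_zero(self):
        t, fi, speed, mask = bell_profile()
        # odd function around the profile midpoint is orthogonal to the
        # symmetric bell on the symmetric mask
        fa = np.sin(2 * np.pi * (t / t[-1] - 0.5))
        fa = fa - (fa[mask] @ fi[mask]) / (fi[mask] @ fi[mask]) * fi  # exact orthogonalization
        p = ChannelForceProfile(t, fa, fi, speed, mask)
        assert adaptation_score(p) == pytest.approx(0.0, abs=1e-9)

    def test_monte_carlo_unbiasedness(self):
        rng = np.random.default_rng(17)
        t, fi, speed, mask = bell_profile()
        est = []
        for _ in range(1000):
            fa = 0.435 * fi + 0.5 * rng.standard_normal(fi.size)
            est.append(adaptation_score(ChannelForceProfile(t, fa, fi, speed, mask)))
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - 43.5) < 3 * se

    def test_brute_force_least_squares_equivalence(self):
        rng = np.random.default_rng(4)
        t, fi, speed, mask = bell_profile()
        for _ in range(100):
            fa = rng.uniform(-1, 1) * fi + rng.standard_normal(fi.size)
            p = ChannelForceProfile(t, fa, fi, speed, mask)
            k_hat = adaptation_score(p) / 100.0
            # dense scan refined by the normal-equation solution of lstsq
            k_ls = np.linalg.lstsq(fi[mask, None], fa[mask], rcond=None)[0][0]
            assert abs(k_hat - k_ls) < 1e-10

    @given(alpha=st.floats(-3, 3), gamma=st.floats(0.1, 10))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_scale_equivariance(self, alpha, gamma):
        t, fi, speed, mask = bell_profile()
        base = ChannelForceProfile(t, 0.7 * fi, fi, speed, mask)
        scaled_fa = ChannelForceProfile(t, alpha * 0.7 * fi, fi, speed, mask)
        joint = ChannelForceProfile(t, gamma * 0.7 * fi, gamma * fi, speed, mask)
        k0 = adaptation_score(base)
        assert adaptation_score(scaled_fa) == pytest.approx(alpha * k0, rel=1e-9, abs=1e-9)
        assert adaptation_score(joint) == pytest.approx(k0, rel=1e-9)

    def test_zero_energy_ideal_force_errors(self):
        t, fi, speed, mask = bell_profile()
        p = ChannelForceProfile(t, fi, np.zeros_like(fi), speed, mask)
        with pytest.raises(IllPosedRegression):
            adaptation_score(p)

    def test_speed_mask_is_contiguous_interval_around_peak(self):
        speed = np.array([0.0, 0.02, 0.005, 0.3, 0.5, 0.3, 0.005, 0.02, 0.0])
        mask = _speed_mask(speed)
        # the early/late blips below-above threshold are excluded
        assert list(np.nonzero(mask)[0]) == [3, 4, 5]


class TestIdealForce:
    def test_peak_matches_gain_times_peak_speed(self, quiet_config, rng):
        desc = TrialDescriptor(1, "exposure", "channel", 90.0, 1)
        tr = simulate_reach(LearnerState(0.5), desc, quiet_config, rng,
                            c=0.4, b_session=16.0)
        fi = ideal_force(tr, 16.0)
        peak_speed = np.max(np.hypot(*tr.vel_m_s.T))
        assert np.max(np.abs(fi)) == pytest.approx(16.0 * peak_speed, rel=1e-6)

    def test_stationary_hand_zero(self):
        tr = make_reach_trial(np.zeros((400, 2)), trial_type="channel")
        np.testing.assert_allclose(ideal_force(tr, 16.0), 0.0)

    def test_non_channel_trial_rejected(self):
        tr = make_reach_trial(trial_type="field")
        with pytest.raises(ValueError, match="channel"):
            ideal_force(tr, 16.0)


class TestOscillationIndex:
    def test_monotone_linear_profile_is_sqrt2(self):
        t, fi, speed, mask = bell_profile()
        fa = np.linspace(0, 1, fi.size)
        p = ChannelForceProfile(t, fa, fi, speed, mask)
        assert oscillation_index(p) == pytest.approx(np.sqrt(2), rel=1e-12)

    @given(seed=st.integers(0, 100))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_monotone_profiles_bounded(self, seed):
        rng = np.random.default_rng(seed)
        t, fi, speed, mask = bell_profile()
        fa = np.cumsum(rng.uniform(0, 1, fi.size))
        p = ChannelForceProfile(t, fa, fi, speed, mask)
        v = oscillation_index(p)
        assert np.sqrt(2) - 1e-9 <= v <= 2.0 + 1e-9

    def test_cosine_family_strictly_increasing(self):
        t, fi, speed, mask = bell_profile()
        tau = np.linspace(0, 1, int(mask.sum()))
        vals = []
        for n in (1, 2, 4):
            fa = np.zeros(fi.size)
            fa[mask] = (1 - np.cos(2 * np.pi * n * tau)) / 2
            vals.append(oscillation_index(ChannelForceProfile(t, fa, fi, speed, mask)))
        assert vals[0] < vals[1] < vals[2]

    @given(a=st.floats(0.1, 5), b=st.floats(-10, 10), flip=st.booleans())
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_affine_invariance(self, a, b, flip):
        t, fi, speed, mask = bell_profile()
        rng = np.random.default_rng(0)
        fa = np.cumsum(rng.uniform(-1, 1.5, fi.size))
        scale = -a if flip else a
        p0 = ChannelForceProfile(t, fa, fi, speed, mask)
        p1 = ChannelForceProfile(t, scale * fa + b, fi, speed, mask)
        assert oscillation_index(p1) == pytest.approx(oscillation_index(p0), rel=1e-9)

    def test_constant_profile_errors(self):
        t, fi, speed, mask = bell_profile()
        p = ChannelForceProfile(t, np.ones(fi.size), fi, speed, mask)
        with pytest.raises(DegenerateProfile):
            oscillation_index(p)

    def test_variation_mode_of_monotone_profile_is_one(self):
        t, fi, speed, mask = bell_profile()
        fa = np.linspace(0, 3, fi.size)
        p = ChannelForceProfile(t, fa, fi, speed, mask)
        assert oscillation_index(p, mode="variation") == pytest.approx(1.0, rel=1e-12)


class TestSignAdjust:
    def test_involution(self):
        df = pd.DataFrame({"mpe_m": [0.01, -0.02], "adaptation_pct": [30.0, 40.0]})
        twice = sign_adjust(sign_adjust(df, "cw"), "cw")
        pd.testing.assert_frame_equal(twice, df)

    def test_mirror_sessions_combine(self):
        df = pd.DataFrame({"mpe_m": [0.01, 0.02], "adaptation_pct": [30.0, 40.0]})
        mirrored = df.assign(mpe_m=-df["mpe_m"])
        pd.testing.assert_frame_equal(sign_adjust(mirrored, "cw"), sign_adjust(df, "ccw"))

    def test_adaptation_untouched(self):
        df = pd.DataFrame({"mpe_m": [0.01], "adaptation_pct": [30.0]})
        out = sign_adjust(df, "cw")
        assert out["adaptation_pct"].iloc[0] == 30.0
        assert out["mpe_m"].iloc[0] == -0.01
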