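"""Shared fixtures and builders for synthetic trials and schedules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cocoadapt import MUSCLES, ScheduleSpec, SimConfig, Trial, TrialEvents
from cocoadapt.simulator import minimum_jerk
from cocoadapt.trialdata import TARGETS_DEG, target_position


def make_reach_trial(pos=None, *, dt=0.001, target_deg=90.0, trial_type="null",
                     b=16.0, phase="pre_exposure", trial_id=1, block=1,
                     vel=None, force=None, emg=None, duration_s=0.45,
                     hold_s=0.3, tail_s=0.4, emg_carrier=None):
    """Construct a valid Trial from a path (or a default minimum-jerk reach).

    ``emg_carrier``: optional (n_emg,) carrier multiplied into a unit
    envelope for all muscles; defaults to zeros plus epsilon noise-free
    silence is fine for kinematic tests.
    """
    if pos is None:
        n = int(round((hold_s + duration_s + tail_s) / dt))
        t = np.arange(n) * dt
        d = target_position(target_deg, 1.0)
        s, v, _ = minimum_jerk(t - hold_s, duration_s, 0.12)
        pos = np.column_stack([s * d[0], s * d[1]])
        vel = np.column_stack([v * d[0], v * d[1]])
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    t = np.arange(n) * dt
    if vel is None:
        vel = np.gradient(pos, dt, axis=0)
    if force is None:
        force = np.zeros_like(pos)
    n_emg = 2 * n
    emg_t = np.arange(n_emg) / 2000.0
    if emg is None:
        if emg_carrier is None:
            emg_carrier = np.zeros(n_emg)
        emg = pd.DataFrame({m: np.asarray(emg_carrier, dtype=float) for m in MUSCLES})
    return Trial(
        trial_id=trial_id, phase=phase, trial_type=trial_type,
        target_angle_deg=target_deg, field_gain_b=b, block=block,
        time_s=t, pos_m=pos, vel_m_s=vel, force_n=force,
        emg_time_s=emg_t, emg=emg, events=TrialEvents(),
    )


def assert_schedule_valid(descs, spec: ScheduleSpec, group: str):
    """Check every sequencing rule on a generated schedule."""
    phases = {}
    for d in descs:
        phases.setdefault(d.phase, []).append(d)
    assert len(phases.get("pre_exposure", [])) == spec.pre_exposure_trials
    assert len(phases.get("exposure", [])) == spec.exposure_trials
    assert len(phases.get("post_exposure", [])) == spec.post_exposure_trials
    if group == "control":
        assert "pulse" not in phases and "post_pulse" not in phases
    elif spec.pulse_trials:
        assert len(phases["pulse"]) == spec.pulse_trials
        dirs = sorted(d.pulse_direction_deg for d in phases["pulse"])
        expected = sorted((np.arange(spec.pulse_trials) * 360.0 / spec.pulse_trials) % 360.0)
        assert np.allclose(dirs, expected)

    # block composition and channel placement
    moves_since_break = 10**9
    block_pos = 0
    cur_block = None
    block_members = []

    def check_block(members):
        types = [m.trial_type for m in members]
        assert types.count("channel") == 1
        targets = sorted(m.target_angle_deg for m in members if m.trial_type != "channel")
        assert targets == sorted(TARGETS_DEG)
        ch = members[[i for i, m in enumerate(members) if m.trial_type == "channel"][0]]
        assert ch.target_angle_deg == spec.channel_target_deg

    for d in descs:
        if d.trial_type == "pulse":
            continue
        moves_since_break += 1
        if d.block is not None:
            key = (d.phase, d.block)
            if key != cur_block:
                if block_members:
                    check_block(block_members)
                cur_block = key
                block_members = []
                block_pos = 0
            block_pos += 1
            block_members.append(d)
            if d.trial_type == "channel":
                assert block_pos > 1, "channel trial first in block"
                assert moves_since_break > spec.channel_free_trials_after_break, \
                    "channel trial within first movements after a rest break"
        if d.rest_break_after:
            moves_since_break = 0
    if block_members:
        check_block(block_members)

    # rest breaks: after pre-exposure and after every 13th exposure block,
    # except the end of the exposure phase
    pre = phases.get("pre_exposure", [])
    if pre:
        assert pre[-1].rest_break_after
    exp_breaks = [d.block for d in phases.get("exposure", []) if d.rest_break_after]
    expected_breaks = [b for b in range(spec.rest_break_every_blocks, spec.exposure_blocks,
                                        spec.rest_break_every_blocks)]
    assert exp_breaks == expected_breaks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free simulator configuration for deterministic physics tests."""
    return SimConfig(motor_noise_sd_n=0.0, reach_duration_jitter_sd_s=0.0,
                     emg_gain_jitter_cv=0.0, coco_jitter_cv=0.0,
                     learning_rate_jitter_cv=0.0)


@pytest.fixture(scope="session")
def tiny_spec():
    return ScheduleSpec(pre_exposure_trials=10, pulse_trials=2, post_pulse_trials=2,
                        exposure_trials=15, post_exposure_trials=5)
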