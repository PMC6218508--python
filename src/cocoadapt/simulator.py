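"""Forward simulator of the curl-field reaching paradigm.

The plant is a planar point mass (hand + handle) driven by a controller
with three parts: feedforward inverse dynamics of a minimum-jerk desired
trajectory, a learned compensation of the curl field scaled by the internal
compensation fraction ``k_internal``, and impedance feedback (stiffness and
damping around the desired state) whose gains grow with the co-contraction
level ``c``.  Environment forces depend on trial type: nothing on null
trials, the velocity-dependent curl field on field trials, a stiff
spring-damper wall perpendicular to the reach on channel trials, and a
constant force pulse on pulse trials.

Trial-to-trial learning follows a single-state linear dynamical system:
on field trials ``k <- A k + B_eff (1 - k)`` with retention ``A`` and an
effective learning rate ``B_eff = B + slope * c`` (the co-contraction
dependence of learning is the switch that makes stiff cohorts adapt faster;
set ``coco_learning_slope = 0`` for a null world in which co-contraction
leaves learning untouched); on all other trials only retention applies, and
rest breaks add one extra retention step.

Synthetic EMG per muscle is an amplitude-modulated broadband carrier: the
envelope is a baseline plus a co-contraction term plus cosine-tuned
contributions of the feedforward motor command (zero lag) and of the
feedback correction delayed by the physiological feedback latency, so that
band-pass filtering plus rectification recovers the envelope in
expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .trialdata import (
    GROUPS,
    MUSCLES,
    ScheduleSpec,
    Session,
    Trial,
    TrialDescriptor,
    TrialEvents,
    generate_schedule,
    target_position,
)

try:  # optional JIT; the pure-Python loop is the reference path
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]


# Preferred pulling direction (degrees) of the force each muscle produces
# at the hand.  Antagonist pairs sit opposite and the three pairs are spread
# evenly over direction, so the summed rectified drive across the set is
# close to direction-independent (as with a real antagonist muscle montage).
MUSCLE_PREF_DEG = {
    "pectoralis_major": 210.0,
    "posterior_deltoid": 30.0,
    "biceps": 90.0,
    "triceps_long": 270.0,
    "triceps_lat": 330.0,
    "brachioradialis": 150.0,
}


@dataclass
class SimConfig:
    """All simulator parameters (SI units unless noted)."""

    mass_kg: float = 2.0
    # Impedance: K(c) = k_base + k_coco * c, D(c) = d_base + d_coco * sqrt(c).
    # Baseline stiffness is task dependent: postural gains during the
    # stationary pulse phase are far lower than gains during reaching.
    k_reach_base_n_m: float = 250.0
    k_hold_base_n_m: float = 20.0
    k_coco_n_m: float = 300.0
    d_base_ns_m: float = 12.0
    d_coco_ns_m: Optional[float] = None  # default sqrt(k_coco * mass)
    # Group co-contraction levels (dimensionless c) and the shared
    # pre-exposure level before any instruction differentiates the groups.
    coco_levels: dict = field(default_factory=lambda: {"stiff": 2.0, "relaxed": 0.0, "control": 0.4})
    coco_pre: float = 0.4
    coco_jitter_cv: float = 0.25  # between-participant lognormal CV on c
    # Environment
    curl_gain_b_ns_m: float = 16.0
    channel_stiffness_n_m: float = 6000.0
    channel_damping_ns_m: float = 5.0
    pulse_force_n: float = 5.0
    pulse_duration_s: float = 0.5
    # Reach geometry / timing
    reach_length_m: float = 0.12
    reach_duration_s: float = 0.45  # minimum-jerk peak speed 1.875 L/T = 50 cm/s
    reach_duration_jitter_sd_s: float = 0.02
    hold_pre_s: float = 0.3
    tail_s: float = 0.35  # minimum post-reach recording
    tail_max_s: float = 2.0  # recording continues until the hand settles at the target
    pulse_hold_pre_s: float = 0.3
    pulse_tail_s: float = 0.4
    # Learner
    retention_a: float = 0.998
    learning_rate_b: float = 0.02
    coco_learning_slope: float = 0.004  # dB/dc; 0 gives the null world
    learning_rate_jitter_cv: float = 0.15
    # Motor noise: Ornstein-Uhlenbeck force noise added to the command
    motor_noise_sd_n: float = 0.25
    motor_noise_tau_s: float = 0.04
    # EMG synthesis
    emg_baseline: float = 0.05
    emg_coco_gain: float = 0.05
    emg_force_gain: float = 0.01  # per newton of command
    feedback_delay_s: float = 0.13
    emg_gain_jitter_cv: float = 0.1  # per-trial, per-muscle envelope jitter
    # Rates
    kin_rate_hz: float = 1000.0
    emg_rate_hz: float = 2000.0

    def __post_init__(self):
        if not (0.0 < self.retention_a <= 1.0):
            raise ValueError("retention_a must be in (0, 1]")
        if self.learning_rate_b < 0:
            raise ValueError("learning_rate_b must be >= 0")
        if self.channel_stiffness_n_m <= 0 or self.channel_damping_ns_m < 0:
            raise ValueError("channel parameters must be positive")
        for name in ("mass_kg", "k_reach_base_n_m", "k_hold_base_n_m", "k_coco_n_m",
                     "d_base_ns_m", "pulse_force_n", "pulse_duration_s",
                     "reach_length_m", "reach_duration_s"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.d_coco_ns_m is None:
            self.d_coco_ns_m = math.sqrt(self.k_coco_n_m * self.mass_kg)

    def stiffness(self, c: float, task: str = "reach") -> float:
        base = self.k_reach_base_n_m if task == "reach" else self.k_hold_base_n_m
        return base + self.k_coco_n_m * c

    def damping(self, c: float) -> float:
        return self.d_base_ns_m + self.d_coco_ns_m * math.sqrt(max(c, 0.0))


@dataclass
class LearnerState:
    """Ground-truth compensation fraction (the simulator-side analogue of
    the channel-trial regression coefficient)."""

    k_internal: float = 0.0


# ---------------------------------------------------------------------------
# Environment force primitives
# ---------------------------------------------------------------------------

def curl_field_force(vel: Sequence[float], b: float) -> np.ndarray:
    """Velocity-dependent curl force ``(-b*vy, b*vx)``.

    Orthogonal to the velocity at every instant, so it does no work.
    """
    vx, vy = float(vel[0]), float(vel[1])
    return np.array([-b * vy, b * vx])


def channel_force(pos: Sequence[float], vel: Sequence[float], reach_axis: Sequence[float],
                  stiffness: float = 6000.0, damping: float = 5.0) -> np.ndarray:
    """Restoring force of the virtual channel wall acting on the hand.

    ``reach_axis`` is a unit vector through the home position; only the
    position/velocity components perpendicular to it are penalized.
    """
    ax, ay = float(reach_axis[0]), float(reach_axis[1])
    lx, ly = -ay, ax  # lateral unit vector (axis rotated +90 degrees)
    e = pos[0] * lx + pos[1] * ly
    ed = vel[0] * lx + vel[1] * ly
    f = -(stiffness * e + damping * ed)
    return np.array([f * lx, f * ly])


# ---------------------------------------------------------------------------
# Fixed-step integrator (semi-implicit Euler at the kinematic rate)
# ---------------------------------------------------------------------------

def _integrate_py(code, n, dt, m, K, D, k_int, b_session, Kch, Dch, lx, ly,
                  xd, yd, vxd, vyd, axd, ayd, fext, noise,
                  pos, vel, fmeas, uff, ufb,
                  i_min, tgt_x, tgt_y, settle_thresh, margin_steps):
    """Semi-implicit Euler steps; returns the number of recorded samples,
    or ``-(i+1)`` if the state became non-finite at step i.

    When ``i_min < n`` the loop keeps integrating past ``i_min`` only until
    the hand has been seen within ``settle_thresh`` of the target (the
    paradigm ends a trial on arrival), then records ``margin_steps`` more.
    """
    x = 0.0
    y = 0.0
    vx = 0.0
    vy = 0.0
    remaining = -1
    for i in range(n):
        pos[i, 0] = x
        pos[i, 1] = y
        vel[i, 0] = vx
        vel[i, 1] = vy
        # feedforward: inverse dynamics of the plan + learned field compensation
        ufx = m * axd[i] + k_int * b_session * vyd[i]
        ufy = m * ayd[i] - k_int * b_session * vxd[i]
        # impedance feedback around the desired state
        ubx = -K * (x - xd[i]) - D * (vx - vxd[i])
        uby = -K * (y - yd[i]) - D * (vy - vyd[i])
        uff[i, 0] = ufx
        uff[i, 1] = ufy
        ufb[i, 0] = ubx
        ufb[i, 1] = uby
        if code == 1:  # curl field
            ex = -b_session * vy
            ey = b_session * vx
            fmeas[i, 0] = ex
            fmeas[i, 1] = ey
        elif code == 2:  # channel wall
            e = x * lx + y * ly
            ed = vx * lx + vy * ly
            f = -(Kch * e + Dch * ed)
            ex = f * lx
            ey = f * ly
            fmeas[i, 0] = -ex  # wall reaction: force the hand exerts on the wall
            fmeas[i, 1] = -ey
        else:  # null or externally forced (pulse)
            ex = 0.0
            ey = 0.0
            fmeas[i, 0] = fext[i, 0]
            fmeas[i, 1] = fext[i, 1]
        fx = ufx + ubx + ex + fext[i, 0] + noise[i, 0]
        fy = ufy + uby + ey + fext[i, 1] + noise[i, 1]
        vx += dt * fx / m
        vy += dt * fy / m
        x += dt * vx
        y += dt * vy
        if not (math.isfinite(x) and math.isfinite(y)):
            return -(i + 1)
        if remaining < 0:
            if i >= i_min:
                dx = x - tgt_x
                dy = y - tgt_y
                if math.sqrt(dx * dx + dy * dy) < settle_thresh:
                    remaining = margin_steps
        else:
            remaining -= 1
            if remaining == 0:
                return i + 1
    return n


if _HAVE_NUMBA:
    _integrate = _njit(cache=True)(_integrate_py)
else:  # pragma: no cover
    _integrate = _integrate_py


def minimum_jerk(t: np.ndarray, duration: float, length: float):
    """Minimum-jerk position/velocity/acceleration along a straight reach.

    Clamped to the endpoints outside [0, duration].  Peak speed is
    ``1.875 * length / duration``.
    """
    tau = np.clip(t / duration, 0.0, 1.0)
    s = length * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    v = length / duration * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    a = length / duration**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)
    return s, v, a


def _ou_noise(n: int, dt: float, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck force noise, shape (n, 2)."""
    if sd == 0.0:
        return np.zeros((n, 2))
    a = math.exp(-dt / tau)
    w = rng.standard_normal((n, 2)) * sd * math.sqrt(1 - a * a)
    w[0] = rng.standard_normal(2) * sd
    return sp_signal.lfilter([1.0], [1.0, -a], w, axis=0)


class IntegrationError(RuntimeError):
    pass


def _run_trial(code: int, desc: TrialDescriptor, cfg: SimConfig, k_internal: float,
               b_session: float, c: float, rng: np.random.Generator,
               duration_s: float, reach_dir: Optional[np.ndarray]):
    dt = 1.0 / cfg.kin_rate_hz
    is_pulse = code == 3
    hold = cfg.pulse_hold_pre_s if is_pulse else cfg.hold_pre_s
    tail = cfg.pulse_tail_s if is_pulse else cfg.tail_max_s
    total = hold + duration_s + tail
    n = int(round(total / dt))
    t = np.arange(n) * dt

    if is_pulse:
        xd = yd = vxd = vyd = axd = ayd = np.zeros(n)
        a = math.radians(desc.pulse_direction_deg)
        fext = np.zeros((n, 2))
        i0 = int(round(hold / dt))
        i1 = i0 + int(round(cfg.pulse_duration_s / dt))
        fext[i0:i1, 0] = cfg.pulse_force_n * math.cos(a)
        fext[i0:i1, 1] = cfg.pulse_force_n * math.sin(a)
        lx = ly = 0.0
        K = cfg.stiffness(c, task="hold")
    else:
        s, v, acc = minimum_jerk(t - hold, duration_s, cfg.reach_length_m)
        xd = s * reach_dir[0]
        yd = s * reach_dir[1]
        vxd = v * reach_dir[0]
        vyd = v * reach_dir[1]
        axd = acc * reach_dir[0]
        ayd = acc * reach_dir[1]
        fext = np.zeros((n, 2))
        lx, ly = -reach_dir[1], reach_dir[0]
        K = cfg.stiffness(c, task="reach")
    D = cfg.damping(c)
    noise = _ou_noise(n, dt, cfg.motor_noise_sd_n, cfg.motor_noise_tau_s, rng)

    pos = np.empty((n, 2))
    vel = np.empty((n, 2))
    fmeas = np.empty((n, 2))
    uff = np.empty((n, 2))
    ufb = np.empty((n, 2))
    if is_pulse:
        i_min, tgt_x, tgt_y = n, 0.0, 0.0
        margin = 0
    else:
        # the paradigm ends a reaching trial once the cursor has settled at
        # the target: record until first arrival after the planned reach,
        # plus a tail of at least cfg.tail_s
        i_min = int(round((hold + duration_s) / dt))
        tgt_x, tgt_y = cfg.reach_length_m * reach_dir
        margin = int(round(cfg.tail_s / dt))
    n_used = _integrate(code, n, dt, cfg.mass_kg, K, D, k_internal, b_session,
                        cfg.channel_stiffness_n_m, cfg.channel_damping_ns_m, lx, ly,
                        np.ascontiguousarray(xd), np.ascontiguousarray(yd),
                        np.ascontiguousarray(vxd), np.ascontiguousarray(vyd),
                        np.ascontiguousarray(axd), np.ascontiguousarray(ayd),
                        fext, np.ascontiguousarray(noise), pos, vel, fmeas, uff, ufb,
                        i_min, tgt_x, tgt_y, 0.003, margin)
    if n_used < 0:
        raise IntegrationError(
            f"non-finite state in trial {desc.trial_id} at step {-n_used - 1}")
    sl = slice(0, n_used)
    return t[sl], pos[sl], vel[sl], fmeas[sl], uff[sl], ufb[sl]


def synthesize_emg(uff: np.ndarray, ufb: np.ndarray, c: float, cfg: SimConfig,
                   rng: np.random.Generator):
    """Raw six-channel EMG for one trial from the command time series.

    ``uff``/``ufb`` are (n, 2) feedforward/feedback command forces at the
    kinematic rate.  Returns ``(emg_time_s, DataFrame)`` at the EMG rate.
    The returned signal is envelope-modulated zero-mean Gaussian noise: the
    analysis pipeline's band-pass + rectification recovers the envelope up
    to a fixed rectification constant that cancels under per-muscle
    normalization.
    """
    n = uff.shape[0]
    up = int(round(cfg.emg_rate_hz / cfg.kin_rate_hz))
    delay = int(round(cfg.feedback_delay_s * cfg.kin_rate_hz))
    ufb_del = np.zeros_like(ufb)
    if delay < n:
        ufb_del[delay:] = ufb[: n - delay]
    cols = {}
    base = cfg.emg_baseline + cfg.emg_coco_gain * max(c, 0.0)
    for m in MUSCLES:
        a = math.radians(MUSCLE_PREF_DEG[m])
        px, py = math.cos(a), math.sin(a)
        drive_ff = np.maximum(0.0, uff[:, 0] * px + uff[:, 1] * py)
        drive_fb = np.maximum(0.0, ufb_del[:, 0] * px + ufb_del[:, 1] * py)
        env = base + cfg.emg_force_gain * (drive_ff + drive_fb)
        if cfg.emg_gain_jitter_cv > 0:
            env = env * rng.lognormal(0.0, cfg.emg_gain_jitter_cv)
        env2 = np.repeat(env, up)
        cols[m] = env2 * rng.standard_normal(env2.size)
    emg = pd.DataFrame(cols)
    emg_t = np.arange(len(emg)) / cfg.emg_rate_hz
    return emg_t, emg


def simulate_reach(state: LearnerState, desc: TrialDescriptor, cfg: SimConfig,
                   rng: np.random.Generator, c: float, b_session: float) -> Trial:
    """Simulate one reaching trial (null, field, or channel)."""
    code = {"null": 0, "field": 1, "channel": 2}[desc.trial_type]
    reach_dir = target_position(desc.target_angle_deg, 1.0)
    duration = cfg.reach_duration_s
    if cfg.reach_duration_jitter_sd_s > 0:
        duration = float(np.clip(rng.normal(duration, cfg.reach_duration_jitter_sd_s),
                                 0.30, 0.70))
    # the learned compensation acts on all reaching trials; the environment
    # applies the field only on field trials
    t, pos, vel, fmeas, uff, ufb = _run_trial(
        code, desc, cfg, state.k_internal, b_session, c, rng, duration, reach_dir)
    emg_t, emg = synthesize_emg(uff, ufb, c, cfg, rng)
    return Trial(
        trial_id=desc.trial_id, phase=desc.phase, trial_type=desc.trial_type,
        target_angle_deg=desc.target_angle_deg, field_gain_b=b_session,
        block=desc.block, time_s=t, pos_m=pos, vel_m_s=vel, force_n=fmeas,
        emg_time_s=emg_t, emg=emg, events=TrialEvents(),
        rest_break_after=desc.rest_break_after,
        kin_rate_hz=cfg.kin_rate_hz, emg_rate_hz=cfg.emg_rate_hz,
    )


def simulate_pulse_trial(cfg: SimConfig, pulse_direction_deg: float, group_c: float,
                         rng: np.random.Generator,
                         desc: Optional[TrialDescriptor] = None) -> Trial:
    """Simulate one stationary force-pulse trial (5 N for 500 ms)."""
    if desc is None:
        desc = TrialDescriptor(0, "pulse", "pulse", None, None,
                               pulse_direction_deg=pulse_direction_deg)
    t, pos, vel, fmeas, uff, ufb = _run_trial(
        3, desc, cfg, 0.0, 0.0, group_c, rng, cfg.pulse_duration_s, None)
    emg_t, emg = synthesize_emg(uff, ufb, group_c, cfg, rng)
    return Trial(
        trial_id=desc.trial_id, phase="pulse", trial_type="pulse",
        target_angle_deg=None, field_gain_b=0.0, block=None,
        time_s=t, pos_m=pos, vel_m_s=vel, force_n=fmeas,
        emg_time_s=emg_t, emg=emg,
        events=TrialEvents(pulse_onset_s=cfg.pulse_hold_pre_s),
        pulse_direction_deg=pulse_direction_deg,
        rest_break_after=desc.rest_break_after,
        kin_rate_hz=cfg.kin_rate_hz, emg_rate_hz=cfg.emg_rate_hz,
    )


def pulse_displacement(trial: Trial, border_radius_m: float = 0.015):
    """Maximum displacement from home on a pulse trial and whether the hand
    stayed within the instructed border ring."""
    d = float(np.max(np.hypot(trial.pos_m[:, 0], trial.pos_m[:, 1])))
    return d, d <= border_radius_m


def update_learner(state: LearnerState, trial_type: str, cfg: SimConfig, *,
                   b_eff: Optional[float] = None, c: float = 0.0,
                   rest_break_after: bool = False) -> LearnerState:
    """One step of the trial-to-trial learning rule.

    Field trials: ``k <- A k + B_eff (1 - k)``; other trials retain only
    (``k <- A k``).  A rest break applies one extra retention step.
    """
    a = cfg.retention_a
    if b_eff is None:
        b_eff = max(0.0, cfg.learning_rate_b + cfg.coco_learning_slope * c)
    k = state.k_internal
    if trial_type == "field":
        k = a * k + b_eff * (1.0 - k)
    else:
        k = a * k
    if rest_break_after:
        k = a * k
    return LearnerState(k_internal=k)


# ---------------------------------------------------------------------------
# Whole sessions and cohorts
# ---------------------------------------------------------------------------

def _participant_draws(cfg: SimConfig, group: str, rng: np.random.Generator):
    c_group = cfg.coco_levels[group]
    c = c_group * rng.lognormal(0.0, cfg.coco_jitter_cv) if c_group > 0 else 0.0
    b = cfg.learning_rate_b * rng.lognormal(0.0, cfg.learning_rate_jitter_cv)
    b_eff = max(0.0, b + cfg.coco_learning_slope * c)
    return c, b_eff


def simulate_session(spec: ScheduleSpec, cfg: SimConfig, group: str,
                     field_direction: str, participant_id: str,
                     rng: np.random.Generator) -> Session:
    """Simulate one participant's full session.

    Per-trial ground-truth ``k_internal`` (the value in force during the
    trial) is stored on the returned session for parameter-recovery tests.
    """
    b_session = cfg.curl_gain_b_ns_m * (1.0 if field_direction == "ccw" else -1.0)
    c_i, b_eff = _participant_draws(cfg, group, rng)
    schedule = generate_schedule(spec, group, field_direction, rng=rng)
    state = LearnerState(0.0)
    trials = []
    gt_rows = []
    breaks = []
    for desc in schedule:
        c_trial = cfg.coco_pre if desc.phase in ("training", "pre_exposure") else c_i
        if desc.trial_type == "pulse":
            tr = simulate_pulse_trial(cfg, desc.pulse_direction_deg, c_trial, rng, desc=desc)
        else:
            tr = simulate_reach(state, desc, cfg, rng, c_trial, b_session)
        trials.append(tr)
        gt_rows.append((desc.trial_id, state.k_internal))
        state = update_learner(state, desc.trial_type, cfg, b_eff=b_eff,
                               rest_break_after=desc.rest_break_after)
        if desc.rest_break_after:
            breaks.append(desc.trial_id)
    gt = pd.DataFrame(gt_rows, columns=["trial_id", "k_internal"])
    return Session(
        participant_id=participant_id, group=group, field_direction=field_direction,
        field_gain_b=b_session, trials=trials, rest_break_positions=breaks,
        ground_truth=gt,
        extras={"c": c_i, "b_eff": b_eff, "retention_a": cfg.retention_a},
    )


def iter_experiment(spec: ScheduleSpec, cfg: SimConfig, seed: int,
                    n_per_group: int = 12,
                    groups: Sequence[str] = GROUPS) -> Iterator[Session]:
    """Yield sessions one by one (memory-friendly for large cohorts).

    Field direction is counterbalanced within each group; all randomness
    derives from ``seed`` and the result is reproducible bit for bit.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(groups) * n_per_group)
    idx = 0
    for group in groups:
        for i in range(n_per_group):
            rng = np.random.default_rng(children[idx])
            idx += 1
            direction = "ccw" if i % 2 == 0 else "cw"
            pid = f"{group}_{i + 1:02d}"
            yield simulate_session(spec, cfg, group, direction, pid, rng)


def simulate_experiment(spec: ScheduleSpec, cfg: SimConfig, seed: int,
                        n_per_group: int = 12,
                        groups: Sequence[str] = GROUPS) -> list[Session]:
    """Simulate full stiff/relaxed/control cohorts; returns all sessions."""
    return list(iter_experiment(spec, cfg, seed, n_per_group, groups))
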