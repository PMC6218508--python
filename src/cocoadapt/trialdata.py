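"""Core data model, experiment-schedule generation, and on-disk formats.

A :class:`Trial` holds one trial's synchronized kinematic/force time series
(1 kHz) and raw six-channel surface EMG (2 kHz) plus metadata; a
:class:`Session` is the ordered trial list for one participant.
:func:`generate_schedule` reproduces the paradigm's trial-sequencing rules:
blocks of five (one reach per target plus one channel trial to the 90
degree target), pseudorandom order with the channel trial never first in a
block and never within the first four movements after a rest break, rest
breaks after the pre-exposure phase and after every 13 exposure blocks.

Coordinates: home position at the origin, +x rightward, +y toward the 90
degree target.  SI units (m, m/s, N, s) everywhere; angles in degrees only
in metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MUSCLES = (
    "pectoralis_major",
    "posterior_deltoid",
    "biceps",
    "triceps_long",
    "triceps_lat",
    "brachioradialis",
)

PHASES = ("training", "pre_exposure", "pulse", "post_pulse", "exposure", "post_exposure")
TRIAL_TYPES = ("null", "field", "channel", "pulse")
TARGETS_DEG = (0.0, 90.0, 180.0, 270.0)
GROUPS = ("stiff", "relaxed", "control")
FIELD_DIRECTIONS = ("cw", "ccw")

SCHEMA_VERSION = 1


class SessionValidationError(ValueError):
    """Raised when a trial or session violates the documented schema.

    Carries ``trial_id`` and ``field`` so callers can locate the offender.
    """

    def __init__(self, message: str, trial_id: Optional[int] = None, field: Optional[str] = None):
        self.trial_id = trial_id
        self.field = field
        prefix = f"trial {trial_id}: " if trial_id is not None else ""
        super().__init__(prefix + message)


def target_position(target_angle_deg: float, reach_length_m: float = 0.12) -> np.ndarray:
    """Cartesian target location for a center-out reach."""
    a = math.radians(target_angle_deg)
    return np.array([reach_length_m * math.cos(a), reach_length_m * math.sin(a)])


@dataclass
class TrialEvents:
    movement_onset_s: Optional[float] = None
    movement_end_s: Optional[float] = None
    pulse_onset_s: Optional[float] = None


@dataclass
class TrialDescriptor:
    """One entry of a generated schedule (no time series yet)."""

    trial_id: int
    phase: str
    trial_type: str
    target_angle_deg: Optional[float]
    block: Optional[int]  # 1-based block ordinal within its phase
    pulse_direction_deg: Optional[float] = None
    rest_break_after: bool = False


@dataclass
class Trial:
    trial_id: int
    phase: str
    trial_type: str
    target_angle_deg: Optional[float]
    field_gain_b: float  # the session's field gain; applied only on field trials
    block: Optional[int]
    time_s: np.ndarray  # (n,) kinematic time grid
    pos_m: np.ndarray  # (n, 2)
    vel_m_s: np.ndarray  # (n, 2)
    force_n: np.ndarray  # (n, 2) measured handle force (wall reaction on channel trials)
    emg_time_s: np.ndarray  # (m,)
    emg: pd.DataFrame  # (m, 6), columns MUSCLES
    events: TrialEvents = field(default_factory=TrialEvents)
    pulse_direction_deg: Optional[float] = None
    rest_break_after: bool = False
    kin_rate_hz: float = 1000.0
    emg_rate_hz: float = 2000.0

    @property
    def field_applied(self) -> bool:
        return self.trial_type == "field"

    def validate(self) -> None:
        tid = self.trial_id
        if self.phase not in PHASES:
            raise SessionValidationError(f"unknown phase {self.phase!r}", tid, "phase")
        if self.trial_type not in TRIAL_TYPES:
            raise SessionValidationError(f"unknown trial_type {self.trial_type!r}", tid, "trial_type")
        for name, t, rate in (("time_s", self.time_s, self.kin_rate_hz),
                              ("emg_time_s", self.emg_time_s, self.emg_rate_hz)):
            if len(t) < 2:
                raise SessionValidationError(f"{name} too short", tid, name)
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise SessionValidationError(f"{name} not strictly increasing", tid, name)
            if not np.allclose(dt, 1.0 / rate, rtol=1e-6, atol=1e-9):
                raise SessionValidationError(
                    f"{name} not uniform at {rate:g} Hz", tid, name)
        # kinematic and EMG series must cover the same wall-clock span
        if abs(self.time_s[-1] - self.emg_time_s[-1]) > 1.5 / self.kin_rate_hz:
            raise SessionValidationError("kinematic and EMG spans differ", tid, "emg_time_s")
        missing = [m for m in MUSCLES if m not in self.emg.columns]
        if missing:
            raise SessionValidationError(
                f"missing EMG channel(s): {', '.join(missing)}", tid, "emg")
        extra = [c for c in self.emg.columns if c not in MUSCLES]
        if extra:
            raise SessionValidationError(
                f"unknown EMG channel(s): {', '.join(extra)}", tid, "emg")
        if self.trial_type == "pulse":
            if self.events.pulse_onset_s is None:
                raise SessionValidationError("pulse trial lacks pulse_onset_s", tid, "events.pulse_onset_s")
        else:
            if self.target_angle_deg is None:
                raise SessionValidationError("reaching trial lacks target", tid, "target_angle_deg")
            if float(np.hypot(*self.pos_m[0])) > 0.003:
                raise SessionValidationError(
                    "start position more than 0.3 cm from home", tid, "pos_m")
        if self.pos_m.shape != (len(self.time_s), 2):
            raise SessionValidationError("pos_m shape mismatch", tid, "pos_m")
        if self.vel_m_s.shape != self.pos_m.shape or self.force_n.shape != self.pos_m.shape:
            raise SessionValidationError("series shape mismatch", tid, "vel_m_s")


@dataclass
class Session:
    participant_id: str
    group: str
    field_direction: str  # "ccw" <-> b > 0, "cw" <-> b < 0
    field_gain_b: float
    trials: list[Trial]
    rest_break_positions: list[int] = field(default_factory=list)
    ground_truth: Optional[pd.DataFrame] = None  # columns trial_id, k_internal
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise SessionValidationError(f"unknown group {self.group!r}", field="group")
        if self.field_direction not in FIELD_DIRECTIONS:
            raise SessionValidationError(
                f"unknown field_direction {self.field_direction!r}", field="field_direction")
        if np.sign(self.field_gain_b) != (1.0 if self.field_direction == "ccw" else -1.0):
            raise SessionValidationError(
                "sign of field_gain_b inconsistent with field_direction", field="field_gain_b")
        for tr in self.trials:
            tr.validate()


# ---------------------------------------------------------------------------
# Schedule generation
# ---------------------------------------------------------------------------

@dataclass
class ScheduleSpec:
    """Declarative experiment design.

    Phase lengths are in trials; block-structured phases must be divisible
    by ``block_size``.  The exposure phase defaults to 410 trials (82 blocks
    of 5).  ``channel_free_trials_after_break`` enforces that a channel
    trial does not occur within the first N reaching movements after a rest
    break.
    """

    training_trials: int = 0
    pre_exposure_trials: int = 100
    pulse_trials: int = 50
    post_pulse_trials: int = 4
    exposure_trials: int = 410
    post_exposure_trials: int = 100
    block_size: int = 5
    rest_break_every_blocks: int = 13
    channel_target_deg: float = 90.0
    channel_free_trials_after_break: int = 4

    def __post_init__(self):
        for name in ("pre_exposure_trials", "exposure_trials", "post_exposure_trials"):
            n = getattr(self, name)
            if n % self.block_size != 0:
                raise ValueError(
                    f"{name}={n} does not divide into blocks of {self.block_size}; "
                    "block-structured phases need a whole number of blocks "
                    "(each block = one reach per target plus one channel trial)")
        if self.channel_target_deg not in TARGETS_DEG:
            raise ValueError(f"channel_target_deg must be one of {TARGETS_DEG}")

    @property
    def pre_exposure_blocks(self) -> int:
        return self.pre_exposure_trials // self.block_size

    @property
    def exposure_blocks(self) -> int:
        return self.exposure_trials // self.block_size

    @property
    def post_exposure_blocks(self) -> int:
        return self.post_exposure_trials // self.block_size


def _make_block(rng: np.random.Generator, spec: ScheduleSpec, reach_type: str,
                moves_since_break: int) -> list[tuple[str, float]]:
    """Order of (trial_type, target) for one block of five.

    The channel trial is never at block position 1 and its movement index
    since the last rest break must exceed ``channel_free_trials_after_break``.
    """
    targets = list(TARGETS_DEG)
    rng.shuffle(targets)
    free = spec.channel_free_trials_after_break
    allowed = [p for p in range(2, spec.block_size + 1) if moves_since_break + p > free]
    pos = int(rng.choice(allowed))
    block: list[tuple[str, float]] = [(reach_type, t) for t in targets]
    block.insert(pos - 1, ("channel", spec.channel_target_deg))
    return block


def generate_schedule(spec: ScheduleSpec, group: str, field_direction: str,
                      seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None) -> list[TrialDescriptor]:
    """Generate the full trial sequence for one participant.

    The pulse phase (and the post-pulse transition trials) are present only
    for the stiff and relaxed groups; the control group proceeds directly
    from pre-exposure to exposure.  Pulse directions are 50 directions
    uniformly spaced over 360 degrees, shuffled.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if field_direction not in FIELD_DIRECTIONS:
        raise ValueError(f"unknown field_direction {field_direction!r}")
    if rng is None:
        rng = np.random.default_rng(seed)

    out: list[TrialDescriptor] = []
    tid = 0
    moves_since_break = 10**9  # no break yet: placement unconstrained

    def add(phase, trial_type, target, block, pulse_dir=None):
        nonlocal tid, moves_since_break
        tid += 1
        out.append(TrialDescriptor(tid, phase, trial_type, target, block,
                                   pulse_direction_deg=pulse_dir))
        if trial_type != "pulse":
            moves_since_break += 1

    for _ in range(spec.training_trials):
        add("training", "null", float(rng.choice(TARGETS_DEG)), None)

    for b in range(1, spec.pre_exposure_blocks + 1):
        for trial_type, target in _make_block(rng, spec, "null", moves_since_break):
            add("pre_exposure", trial_type, target, b)

    # 45 s rest break after the pre-exposure phase
    if out:
        out[-1].rest_break_after = True
    moves_since_break = 0

    if group in ("stiff", "relaxed") and spec.pulse_trials > 0:
        dirs = (np.arange(spec.pulse_trials) * (360.0 / spec.pulse_trials)) % 360.0
        rng.shuffle(dirs)
        for d in dirs:
            add("pulse", "pulse", None, None, pulse_dir=float(d))
        post_targets = list(TARGETS_DEG)
        rng.shuffle(post_targets)
        for i in range(spec.post_pulse_trials):
            add("post_pulse", "null", post_targets[i % len(post_targets)], None)

    for b in range(1, spec.exposure_blocks + 1):
        for trial_type, target in _make_block(rng, spec, "field", moves_since_break):
            add("exposure", trial_type, target, b)
        if (b % spec.rest_break_every_blocks == 0) and b < spec.exposure_blocks:
            out[-1].rest_break_after = True
            moves_since_break = 0

    for b in range(1, spec.post_exposure_blocks + 1):
        for trial_type, target in _make_block(rng, spec, "null", moves_since_break):
            add("post_exposure", trial_type, target, b)

    return out


# ---------------------------------------------------------------------------
# On-disk format: one JSON metadata document per session plus one kinematic
# and one EMG CSV per trial.  CSV is the normative interchange format.
# ---------------------------------------------------------------------------

_KIN_COLUMNS = ["t", "x", "y", "vx", "vy", "fx", "fy"]


def _kin_name(tid: int) -> str:
    return f"trial_{tid:04d}_kin.csv"


def _emg_name(tid: int) -> str:
    return f"trial_{tid:04d}_emg.csv"


def write_session(session: Session, path) -> None:
    """Write a session to ``path`` (a directory, created if absent)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "participant_id": session.participant_id,
        "group": session.group,
        "field_direction": session.field_direction,
        "field_gain_b": session.field_gain_b,
        "rest_break_positions": list(session.rest_break_positions),
        "extras": session.extras,
        "trials": [],
    }
    for tr in session.trials:
        meta["trials"].append({
            "trial_id": tr.trial_id,
            "phase": tr.phase,
            "trial_type": tr.trial_type,
            "target_angle_deg": tr.target_angle_deg,
            "block": tr.block,
            "pulse_direction_deg": tr.pulse_direction_deg,
            "rest_break_after": tr.rest_break_after,
            "kin_rate_hz": tr.kin_rate_hz,
            "emg_rate_hz": tr.emg_rate_hz,
            "events": {
                "movement_onset_s": tr.events.movement_onset_s,
                "movement_end_s": tr.events.movement_end_s,
                "pulse_onset_s": tr.events.pulse_onset_s,
            },
            "kin_file": _kin_name(tr.trial_id),
            "emg_file": _emg_name(tr.trial_id),
        })
        kin = pd.DataFrame({
            "t": tr.time_s,
            "x": tr.pos_m[:, 0], "y": tr.pos_m[:, 1],
            "vx": tr.vel_m_s[:, 0], "vy": tr.vel_m_s[:, 1],
            "fx": tr.force_n[:, 0], "fy": tr.force_n[:, 1],
        })
        kin.to_csv(path / _kin_name(tr.trial_id), index=False)
        emg = tr.emg.copy()
        emg.insert(0, "t", tr.emg_time_s)
        emg.to_csv(path / _emg_name(tr.trial_id), index=False)
    (path / "session.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    if session.ground_truth is not None:
        session.ground_truth.to_csv(path / "ground_truth.csv", index=False)


def read_session(path) -> Session:
    """Read a session directory written by :func:`write_session`.

    Validates the schema; violations raise :class:`SessionValidationError`
    naming the offending trial and field.
    """
    path = Path(path)
    meta = json.loads((path / "session.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SessionValidationError(
            f"unsupported schema_version {meta.get('schema_version')!r}", field="schema_version")
    trials = []
    for tm in meta["trials"]:
        tid = tm["trial_id"]
        kin = pd.read_csv(path / tm["kin_file"], float_precision="round_trip")
        if list(kin.columns) != _KIN_COLUMNS:
            raise SessionValidationError(
                f"kinematic file columns {list(kin.columns)} != {_KIN_COLUMNS}", tid, "kin_file")
        emg = pd.read_csv(path / tm["emg_file"], float_precision="round_trip")
        if "t" not in emg.columns:
            raise SessionValidationError("EMG file lacks time column 't'", tid, "emg_file")
        ev = tm.get("events", {})
        tr = Trial(
            trial_id=tid,
            phase=tm["phase"],
            trial_type=tm["trial_type"],
            target_angle_deg=tm["target_angle_deg"],
            field_gain_b=meta["field_gain_b"],
            block=tm["block"],
            time_s=kin["t"].to_numpy(),
            pos_m=kin[["x", "y"]].to_numpy(),
            vel_m_s=kin[["vx", "vy"]].to_numpy(),
            force_n=kin[["fx", "fy"]].to_numpy(),
            emg_time_s=emg["t"].to_numpy(),
            emg=emg.drop(columns="t"),
            events=TrialEvents(ev.get("movement_onset_s"), ev.get("movement_end_s"),
                               ev.get("pulse_onset_s")),
            pulse_direction_deg=tm.get("pulse_direction_deg"),
            rest_break_after=tm.get("rest_break_after", False),
            kin_rate_hz=tm.get("kin_rate_hz", 1000.0),
            emg_rate_hz=tm.get("emg_rate_hz", 2000.0),
        )
        tr.validate()
        trials.append(tr)
    gt_path = path / "ground_truth.csv"
    ground_truth = pd.read_csv(gt_path) if gt_path.exists() else None
    sess = Session(
        participant_id=meta["participant_id"],
        group=meta["group"],
        field_direction=meta["field_direction"],
        field_gain_b=meta["field_gain_b"],
        trials=trials,
        rest_break_positions=list(meta.get("rest_break_positions", [])),
        ground_truth=ground_truth,
        extras=meta.get("extras", {}),
    )
    sess.validate()
    return sess
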