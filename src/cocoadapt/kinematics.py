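"""Movement event detection and kinematic error metrics.

Movement onset is the first sample more than 0.3 cm from the home
position; movement end is the first subsequent sample within 0.3 cm of the
target.  The maximum perpendicular error (MPE) is the largest distance
between the hand path and the straight line from the initial hand position
(the position at movement onset, not the nominal home center) to the
target, evaluated over [onset, end].  The raw MPE sign follows the
right-hand rule (positive = deviation to the counterclockwise side of the
reach direction); :func:`cocoadapt.adaptation.sign_adjust` flips clockwise
sessions so cohorts trained on opposite field directions combine.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .trialdata import Trial, target_position

ONSET_THRESHOLD_M = 0.003


class MovementNotDetected(ValueError):
    pass


def detect_onset_end(trial: Trial, threshold_m: float = ONSET_THRESHOLD_M) -> Tuple[float, float]:
    """Movement onset and end times for a reaching trial."""
    if trial.trial_type == "pulse":
        raise ValueError("pulse trials have no reach onset/end")
    r = np.hypot(trial.pos_m[:, 0], trial.pos_m[:, 1])
    out = np.nonzero(r > threshold_m)[0]
    if out.size == 0:
        raise MovementNotDetected(f"trial {trial.trial_id}: movement not detected")
    i_on = int(out[0])
    tgt = target_position(trial.target_angle_deg)
    d = np.hypot(trial.pos_m[:, 0] - tgt[0], trial.pos_m[:, 1] - tgt[1])
    arrived = np.nonzero(d[i_on:] < threshold_m)[0]
    if arrived.size == 0:
        raise MovementNotDetected(f"trial {trial.trial_id}: target never reached")
    i_end = i_on + int(arrived[0])
    return float(trial.time_s[i_on]), float(trial.time_s[i_end])


def _window_indices(t: np.ndarray, onset_s: float, end_s: float) -> slice:
    i0 = int(np.searchsorted(t, onset_s))
    i1 = int(np.searchsorted(t, end_s, side="right"))
    return slice(i0, i1)


def max_perpendicular_error(trial: Trial, field_direction: Optional[str] = None,
                            onset_s: Optional[float] = None,
                            end_s: Optional[float] = None) -> float:
    """Signed maximum perpendicular error in meters.

    With ``field_direction`` given, clockwise sessions are flipped so that
    the exposure-phase deviation is positive regardless of training
    direction (and after-effects come out negative).
    """
    if onset_s is None or end_s is None:
        onset_s, end_s = detect_onset_end(trial)
    sl = _window_indices(trial.time_s, onset_s, end_s)
    path = trial.pos_m[sl]
    start = path[0]
    tgt = target_position(trial.target_angle_deg)
    line = tgt - start
    norm = float(np.hypot(*line))
    if norm < 1e-9:
        raise ValueError(f"trial {trial.trial_id}: degenerate reach line (start == target)")
    d = line / norm
    rel = path - start
    # signed perpendicular distance: positive to the left (CCW side) of d
    cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
    i = int(np.argmax(np.abs(cross)))
    mpe = float(cross[i])
    if field_direction == "cw":
        mpe = -mpe
    return mpe


def peak_speed_check(trial: Trial, onset_s: Optional[float] = None,
                     end_s: Optional[float] = None,
                     slow_m_s: float = 0.40, fast_m_s: float = 0.60):
    """Peak hand speed over [onset, end] and the speed-window flag.

    Only speeds strictly outside [slow, fast] are flagged.
    """
    if onset_s is None or end_s is None:
        onset_s, end_s = detect_onset_end(trial)
    sl = _window_indices(trial.time_s, onset_s, end_s)
    speed = np.hypot(trial.vel_m_s[sl, 0], trial.vel_m_s[sl, 1])
    peak = float(np.max(speed))
    if peak < slow_m_s:
        flag = "too_slow"
    elif peak > fast_m_s:
        flag = "too_fast"
    else:
        flag = "ok"
    return peak, flag


def time_normalize(time_s: np.ndarray, series: np.ndarray, onset_s: float,
                   end_s: float, n_points: int = 1000) -> np.ndarray:
    """Linearly resample ``series`` onto ``n_points`` uniform points over
    [onset, end]; works on 1-D series or (n, k) column stacks."""
    if end_s <= onset_s:
        raise ValueError("end must follow onset")
    mask = (time_s >= onset_s) & (time_s <= end_s)
    if int(mask.sum()) < 2:
        raise ValueError("fewer than 2 samples between onset and end")
    grid = np.linspace(onset_s, end_s, n_points)
    series = np.asarray(series)
    if series.ndim == 1:
        return np.interp(grid, time_s, series)
    return np.column_stack([np.interp(grid, time_s, series[:, j])
                            for j in range(series.shape[1])])
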