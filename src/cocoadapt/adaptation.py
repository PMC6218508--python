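"""Channel-trial force-compensation scoring and the oscillation index.

On a channel trial the hand is clamped to the straight home-target line,
so the lateral force pressed into the channel wall reveals the predictive
(feedforward) compensation.  Adaptation is the coefficient of a regression
through the origin of the measured lateral wall force ``f_a(t)`` on the
ideal fully-compensating force ``f_i(t)`` (the negative of the lateral
curl-field force evaluated on the actual channel-trial velocity),
expressed in percent.  Throughout, the ideal force refers to the field of
the exposure phase, so pre-exposure channel trials score near zero.

The oscillation index is the 2-D path length of the force profile after
normalizing amplitude by its range and time to [0, 1]; a straight monotone
profile gives sqrt(2) and more oscillatory profiles give longer paths.
Both statistics use the contiguous portion of the movement where hand
speed exceeds 1 cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trialdata import Trial, target_position

SPEED_MASK_M_S = 0.01


class IllPosedRegression(ValueError):
    pass


class DegenerateProfile(ValueError):
    pass


@dataclass
class ChannelForceProfile:
    """Lateral force trace of one channel trial.

    ``f_a``: measured force into the wall; ``f_i``: ideal compensating
    force.  Both are signed coordinates on the same lateral axis, so full
    compensation gives ``f_a(t) = f_i(t)`` whichever way the field points.
    ``mask`` selects the contiguous segment with hand speed above 1 cm/s
    that contains the speed peak.
    """

    t: np.ndarray
    f_a: np.ndarray
    f_i: np.ndarray
    speed: np.ndarray
    mask: np.ndarray  # boolean


def _speed_mask(speed: np.ndarray, threshold: float = SPEED_MASK_M_S) -> np.ndarray:
    """Contiguous above-threshold interval containing the speed peak."""
    mask = np.zeros(speed.size, dtype=bool)
    i = int(np.argmax(speed))
    if speed[i] <= threshold:
        return mask
    lo = i
    while lo > 0 and speed[lo - 1] > threshold:
        lo -= 1
    hi = i
    while hi < speed.size - 1 and speed[hi + 1] > threshold:
        hi += 1
    mask[lo:hi + 1] = True
    return mask


def ideal_force(trial: Trial, b: float) -> np.ndarray:
    """Ideal fully-compensating lateral force series for a channel trial.

    Computed from the actual velocity along the channel: with reach axis
    ``d`` and lateral axis ``l = rot90(d)``, the curl field would push with
    ``b * v_along`` along ``l``, so the compensation is ``-b * v_along``.
    """
    if trial.trial_type != "channel":
        raise ValueError(f"trial {trial.trial_id} is not a channel trial")
    d = target_position(trial.target_angle_deg, 1.0)
    v_along = trial.vel_m_s @ d
    return -b * v_along


def channel_profile(trial: Trial, b: float,
                    speed_threshold: float = SPEED_MASK_M_S) -> ChannelForceProfile:
    """Build the lateral force profile of a channel trial."""
    f_i = ideal_force(trial, b)
    d = target_position(trial.target_angle_deg, 1.0)
    lat = np.array([-d[1], d[0]])
    f_a = trial.force_n @ lat
    speed = np.hypot(trial.vel_m_s[:, 0], trial.vel_m_s[:, 1])
    return ChannelForceProfile(t=trial.time_s, f_a=f_a, f_i=f_i, speed=speed,
                               mask=_speed_mask(speed, speed_threshold))


def adaptation_score(profile: ChannelForceProfile) -> float:
    """Force compensation in percent: regression through the origin of
    ``f_a`` on ``f_i`` over the speed-masked samples, times 100."""
    fa = profile.f_a[profile.mask]
    fi = profile.f_i[profile.mask]
    denom = float(fi @ fi)
    if fa.size == 0 or denom <= 0.0:
        raise IllPosedRegression("ill-posed regression: no masked samples or zero-energy f_i")
    k = float(fa @ fi) / denom
    return 100.0 * k


def oscillation_index(profile: ChannelForceProfile, mode: str = "curve") -> float:
    """Path length of the amplitude- and time-normalized force profile.

    ``mode='curve'`` (default) measures the 2-D curve length of the
    normalized profile in the (time, force) unit square; ``mode='variation'``
    measures only the total variation of the normalized force.  Invariant
    to affine transforms of ``f_a`` by construction.
    """
    fa = profile.f_a[profile.mask]
    if fa.size < 2:
        raise DegenerateProfile("degenerate profile: fewer than 2 masked samples")
    rng = float(fa.max() - fa.min())
    if rng <= 0.0:
        raise DegenerateProfile("degenerate profile: zero force range")
    f_hat = (fa - fa.min()) / rng
    dtau = 1.0 / (fa.size - 1)
    df = np.diff(f_hat)
    if mode == "variation":
        return float(np.sum(np.abs(df)))
    if mode != "curve":
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.sum(np.sqrt(dtau * dtau + df * df)))


def sign_adjust(metrics: pd.DataFrame, field_direction: str) -> pd.DataFrame:
    """Flip signed force/error conventions for clockwise-trained sessions.

    Returns a copy with ``mpe_m`` negated when ``field_direction == 'cw'``
    so data from participants trained on opposite field directions can be
    averaged; adaptation percentages are direction-invariant and are left
    untouched.  Applying the adjustment twice restores the original frame.
    """
    if field_direction not in ("cw", "ccw"):
        raise ValueError(f"unknown field_direction {field_direction!r}")
    out = metrics.copy()
    if field_direction == "cw" and "mpe_m" in out.columns:
        out["mpe_m"] = -out["mpe_m"]
    return out
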