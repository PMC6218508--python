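"""Surface-EMG processing: filtering, rectification, windowed means,
per-muscle normalization, and the global EMG statistic.

Raw EMG (2 kHz) is band-pass filtered 30-500 Hz with a 10th-order
Butterworth applied forward-backward (zero phase; the effective order
doubles) and full-wave rectified.  Two analysis windows are defined per
trial kind: for reaching movements an early window (-200 ms to +130 ms
relative to movement onset, feedforward activity only, since feedback
responses appear ~130 ms after onset) and a later window (+130 ms to
+400 ms, feedforward plus feedback); for pulse trials the windows are
-200-0 ms and 0-130 ms relative to pulse onset.

Each muscle is normalized by its mean rectified activity over the early
window of the pre-exposure non-channel trials, computed per participant.
Global EMG for a trial and window is the sum across muscles of the
normalized window mean minus the matching pre-exposure baseline sum:
positive values mean more activity than pre-exposure.  Baselines are kept
separately per window (the early-window baseline sum is exactly the number
of muscles by construction; the later-window baseline is not).  Pulse-trial
windows are referenced to the early-window baseline, the only
stationary-hand reference the pre-exposure phase provides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .trialdata import MUSCLES, Trial
from .kinematics import detect_onset_end, time_normalize


class EMGError(ValueError):
    pass


_DEFAULT_WINDOWS = {
    "movement_early": (-0.200, 0.130),
    "movement_later": (0.130, 0.400),
    "pulse_early": (-0.200, 0.0),
    "pulse_later": (0.0, 0.130),
}


@dataclass
class EMGConfig:
    band_hz: tuple = (30.0, 500.0)
    filter_order: int = 10  # total band-pass design order (even)
    zero_phase: bool = True
    windows: dict = field(default_factory=lambda: dict(_DEFAULT_WINDOWS))
    rate_hz: float = 2000.0

    def __post_init__(self):
        lo, hi = self.band_hz
        if not (0.0 < lo < hi < self.rate_hz / 2.0):
            raise ValueError("band must lie within (0, Nyquist)")
        if self.filter_order % 2 != 0 or self.filter_order <= 0:
            raise ValueError("filter_order must be a positive even band-pass order")
        for name, (a, b) in self.windows.items():
            if b <= a:
                raise ValueError(f"window {name!r} is empty or reversed")

    def sos(self) -> np.ndarray:
        # scipy designs a band-pass of order 2N from N; halve to get the
        # stated total order before the forward-backward pass
        cached = getattr(self, "_sos", None)
        if cached is None:
            cached = sp_signal.butter(self.filter_order // 2, self.band_hz,
                                      btype="bandpass", fs=self.rate_hz, output="sos")
            object.__setattr__(self, "_sos", cached)
        return cached


@dataclass
class NormalizationConstants:
    """Per-participant normalization: one scalar per muscle (mean rectified
    early-window EMG over pre-exposure non-channel trials) plus the
    per-window baseline sums entering the global EMG subtraction."""

    per_muscle: dict
    baseline_sums: dict
    n_trials: int

    def __post_init__(self):
        if set(self.per_muscle) != set(MUSCLES):
            raise EMGError("normalization constants must cover exactly the 6 muscles")
        bad = [m for m, v in self.per_muscle.items() if not np.isfinite(v) or v <= 0]
        if bad:
            raise EMGError(f"non-positive normalization constant for: {', '.join(bad)}")


def _min_length(sos: np.ndarray) -> int:
    return 3 * (2 * sos.shape[0] + 1) + 1


def filter_rectify(raw, cfg: Optional[EMGConfig] = None) -> np.ndarray:
    """Zero-phase band-pass then full-wave rectification.

    ``raw`` may be a 1-D array (one channel) or a 2-D array/DataFrame with
    channels in columns; output matches the input layout.
    """
    if cfg is None:
        cfg = EMGConfig()
    sos = cfg.sos()
    x = raw.to_numpy() if isinstance(raw, pd.DataFrame) else np.asarray(raw, dtype=float)
    n = x.shape[0]
    if n < _min_length(sos):
        raise EMGError(f"series of length {n} too short for order-{cfg.filter_order} "
                       "zero-phase filtering")
    if cfg.zero_phase:
        y = sp_signal.sosfiltfilt(sos, x, axis=0)
    else:
        y = sp_signal.sosfilt(sos, x, axis=0)
    y = np.abs(y)
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(y, columns=raw.columns, index=raw.index)
    return y


_RECTIFICATION_CONSTANT: Optional[float] = None


def rectification_constant(cfg: Optional[EMGConfig] = None, n: int = 2 ** 17,
                           seed: int = 1234) -> float:
    """Expected rectified output of the pipeline for a unit-envelope
    Gaussian carrier (estimated once numerically and cached).

    Relates a synthetic envelope to the mean of the filtered, rectified
    signal; it cancels in all normalized statistics.
    """
    global _RECTIFICATION_CONSTANT
    if cfg is None and _RECTIFICATION_CONSTANT is not None:
        return _RECTIFICATION_CONSTANT
    rng = np.random.default_rng(seed)
    out = float(np.mean(filter_rectify(rng.standard_normal(n), cfg or EMGConfig())))
    if cfg is None:
        _RECTIFICATION_CONSTANT = out
    return out


def _window_mean(rect: np.ndarray, t: np.ndarray, anchor_s: float, window) -> np.ndarray:
    """Mean of each column of ``rect`` over ``anchor + window``."""
    a, b = window
    lo, hi = anchor_s + a, anchor_s + b
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise EMGError(f"window [{lo:.3f}, {hi:.3f}] s outside recorded span "
                       f"[{t[0]:.3f}, {t[-1]:.3f}] s")
    i0 = int(np.searchsorted(t, lo))
    i1 = int(np.searchsorted(t, hi, side="right"))
    return rect[i0:i1].mean(axis=0)


def _anchor(trial: Trial, window_name: str, onset_s: Optional[float]) -> float:
    if window_name.startswith("pulse"):
        if trial.events.pulse_onset_s is None:
            raise EMGError(f"trial {trial.trial_id} has no pulse onset")
        return trial.events.pulse_onset_s
    if onset_s is not None:
        return onset_s
    if trial.events.movement_onset_s is not None:
        return trial.events.movement_onset_s
    onset, _ = detect_onset_end(trial)
    return onset


def compute_normalization(session, cfg: Optional[EMGConfig] = None) -> NormalizationConstants:
    """Per-participant normalization constants from the pre-exposure phase.

    Uses the early-window rectified mean of every pre-exposure non-channel
    trial; a dead (zero-mean) electrode raises an error naming the muscle.
    """
    if cfg is None:
        cfg = EMGConfig()
    trials = [tr for tr in session.trials
              if tr.phase == "pre_exposure" and tr.trial_type != "channel"]
    if not trials:
        raise EMGError("no pre-exposure non-channel trials to normalize from")
    early = []
    later = []
    for tr in trials:
        rect = filter_rectify(tr.emg[list(MUSCLES)], cfg).to_numpy()
        onset = _anchor(tr, "movement_early", None)
        early.append(_window_mean(rect, tr.emg_time_s, onset, cfg.windows["movement_early"]))
        later.append(_window_mean(rect, tr.emg_time_s, onset, cfg.windows["movement_later"]))
    early = np.asarray(early)
    later = np.asarray(later)
    consts = early.mean(axis=0)
    dead = [m for m, v in zip(MUSCLES, consts) if v <= 0 or not np.isfinite(v)]
    if dead:
        raise EMGError(f"zero-mean EMG channel (dead electrode?): {', '.join(dead)}")
    per_muscle = dict(zip(MUSCLES, consts.astype(float)))
    # Baseline sums of normalized window means; early is len(MUSCLES) by
    # construction.  Pulse windows reference the early (stationary-hand
    # feedforward) baseline.
    later_sum = float((later / consts).sum(axis=1).mean())
    early_sum = float(len(MUSCLES))
    baseline_sums = {
        "movement_early": early_sum,
        "movement_later": later_sum,
        "pulse_early": early_sum,
        "pulse_later": early_sum,
    }
    return NormalizationConstants(per_muscle=per_muscle, baseline_sums=baseline_sums,
                                  n_trials=len(trials))


def global_emg(trial: Trial, constants: NormalizationConstants, window: str,
               cfg: Optional[EMGConfig] = None, *,
               rect: Optional[np.ndarray] = None,
               onset_s: Optional[float] = None) -> float:
    """Global EMG of one trial for one named window.

    Sum across muscles of the normalized rectified window mean, minus the
    pre-exposure baseline sum for that window.  Pass ``rect`` (the already
    filtered/rectified channel stack) to avoid re-filtering.
    """
    if cfg is None:
        cfg = EMGConfig()
    if window not in cfg.windows:
        raise EMGError(f"unknown window {window!r}")
    if rect is None:
        rect = filter_rectify(trial.emg[list(MUSCLES)], cfg).to_numpy()
    anchor = _anchor(trial, window, onset_s)
    means = _window_mean(rect, trial.emg_time_s, anchor, cfg.windows[window])
    consts = np.array([constants.per_muscle[m] for m in MUSCLES])
    return float((means / consts).sum() - constants.baseline_sums[window])


def emg_waveform_average(trials: Sequence[Trial], constants: NormalizationConstants,
                         cfg: Optional[EMGConfig] = None, pre_time_s: float = 0.2,
                         n_points: int = 1000) -> dict:
    """Per-muscle mean and s.e.m. waveforms across trials.

    The pre-onset segment is kept in real time; the onset-to-end segment is
    time-normalized to ``n_points`` samples.  Returns a dict per muscle
    with keys ``pre_t`` (negative times), ``tau`` (0-1), ``mean``/``sem``
    over the concatenated grid.
    """
    if cfg is None:
        cfg = EMGConfig()
    if len(trials) < 2:
        raise EMGError("need at least 2 trials to average")
    for tr in trials:
        missing = [m for m in MUSCLES if m not in tr.emg.columns]
        if missing:
            raise EMGError(f"trial {tr.trial_id} missing channel(s): {', '.join(missing)}")
    n_pre = int(round(pre_time_s * cfg.rate_hz))
    consts = np.array([constants.per_muscle[m] for m in MUSCLES])
    stacks = []  # (n_trials, n_pre + n_points, 6)
    for tr in trials:
        rect = filter_rectify(tr.emg[list(MUSCLES)], cfg).to_numpy() / consts
        onset, end = detect_onset_end(tr)
        i_on = int(np.searchsorted(tr.emg_time_s, onset))
        if i_on < n_pre:
            raise EMGError(f"trial {tr.trial_id}: only {i_on} pre-onset samples, "
                           f"need {n_pre}")
        pre = rect[i_on - n_pre:i_on]
        post = time_normalize(tr.emg_time_s, rect, onset, end, n_points)
        stacks.append(np.vstack([pre, post]))
    arr = np.asarray(stacks)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    pre_t = (np.arange(-n_pre, 0) + 1) / cfg.rate_hz
    tau = np.linspace(0.0, 1.0, n_points)
    return {m: {"pre_t": pre_t, "tau": tau,
                "mean": mean[:, j], "sem": sem[:, j]}
            for j, m in enumerate(MUSCLES)}
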