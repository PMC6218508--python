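"""Top-level model object tying the whole analysis together.

:class:`CocontractionAdaptationModel` is built from a collection of
sessions (simulated or loaded from disk); ``fit()`` runs the full pipeline
— event detection, maximum perpendicular error, channel-trial force
compensation and oscillation index, EMG normalization and global EMG —
and returns a :class:`CocontractionAdaptationResults` carrying the
per-trial metric table, the per-participant cohort table, group summaries,
and the headline regressions of adaptation on global EMG (with the
oscillation index as a nuisance predictor in the multiple regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import adaptation as adapt
from . import emg as emg_mod
from . import kinematics as kin
from . import stats as stats_mod
from .simulator import pulse_displacement
from .trialdata import MUSCLES, Session, read_session

INITIAL_FINAL_BLOCKS = 13  # "first/last 13 blocks of the exposure phase"

_METRIC_COLUMNS = [
    "participant_id", "group", "field_direction", "trial_id", "phase", "block",
    "trial_type", "target_angle_deg", "rest_break_after",
    "movement_onset_s", "movement_end_s", "peak_speed_m_s", "speed_flag",
    "mpe_m", "adaptation_pct", "oscillation_index",
    "global_emg_early", "global_emg_later", "pulse_max_disp_m", "k_internal",
]


def session_metrics(session: Session, emg_config: Optional[emg_mod.EMGConfig] = None,
                    compute_emg: bool = True) -> pd.DataFrame:
    """Per-trial derived metrics for one session (one row per trial).

    Kinematic error (MPE) is computed on reaching trials that are not
    channel trials; adaptation and the oscillation index on channel trials;
    global EMG on every trial (movement windows for reaches, pulse windows
    for pulse trials).  The signed MPE is adjusted for the session's field
    direction so sessions trained on opposite fields can be pooled.
    """
    cfg = emg_config or emg_mod.EMGConfig()
    constants = emg_mod.compute_normalization(session, cfg) if compute_emg else None
    gt = None
    if session.ground_truth is not None:
        gt = dict(zip(session.ground_truth["trial_id"], session.ground_truth["k_internal"]))
    rows = []
    for tr in session.trials:
        row = dict.fromkeys(_METRIC_COLUMNS, np.nan)
        row.update(
            participant_id=session.participant_id, group=session.group,
            field_direction=session.field_direction, trial_id=tr.trial_id,
            phase=tr.phase, block=tr.block, trial_type=tr.trial_type,
            target_angle_deg=tr.target_angle_deg, rest_break_after=tr.rest_break_after,
            speed_flag="", k_internal=gt.get(tr.trial_id, np.nan) if gt else np.nan,
        )
        rect = None
        if compute_emg:
            rect = emg_mod.filter_rectify(tr.emg[list(MUSCLES)], cfg).to_numpy()
        if tr.trial_type == "pulse":
            d, _ = pulse_displacement(tr)
            row["pulse_max_disp_m"] = d
            if compute_emg:
                row["global_emg_early"] = emg_mod.global_emg(tr, constants, "pulse_early",
                                                             cfg, rect=rect)
                row["global_emg_later"] = emg_mod.global_emg(tr, constants, "pulse_later",
                                                             cfg, rect=rect)
        else:
            onset, end = kin.detect_onset_end(tr)
            tr.events.movement_onset_s, tr.events.movement_end_s = onset, end
            peak, flag = kin.peak_speed_check(tr, onset, end)
            row.update(movement_onset_s=onset, movement_end_s=end,
                       peak_speed_m_s=peak, speed_flag=flag)
            if tr.trial_type == "channel":
                profile = adapt.channel_profile(tr, session.field_gain_b)
                row["adaptation_pct"] = adapt.adaptation_score(profile)
                row["oscillation_index"] = adapt.oscillation_index(profile)
            else:
                row["mpe_m"] = kin.max_perpendicular_error(tr, onset_s=onset, end_s=end)
            if compute_emg:
                row["global_emg_early"] = emg_mod.global_emg(tr, constants, "movement_early",
                                                             cfg, rect=rect, onset_s=onset)
                row["global_emg_later"] = emg_mod.global_emg(tr, constants, "movement_later",
                                                             cfg, rect=rect, onset_s=onset)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_METRIC_COLUMNS)
    return adapt.sign_adjust(df, session.field_direction)


def build_cohort_table(trial_metrics: pd.DataFrame,
                       n_blocks: int = INITIAL_FINAL_BLOCKS,
                       combine: str = "mean",
                       extras: Optional[dict] = None) -> pd.DataFrame:
    """One row per participant: initial/final adaptation, matched
    oscillation indices, first-block MPE, and global EMG over the first
    ``n_blocks`` exposure blocks (early and later windows combined)."""
    if combine not in ("mean", "sum"):
        raise ValueError("combine must be 'mean' or 'sum'")
    rows = []
    for pid, df in trial_metrics.groupby("participant_id", sort=False):
        exp = df[df["phase"] == "exposure"]
        if exp.empty:
            continue
        last = int(exp["block"].max())
        first_w = exp[exp["block"] <= n_blocks]
        final_w = exp[exp["block"] > last - n_blocks]
        ge = first_w[["global_emg_early", "global_emg_later"]].mean()
        ge_combined = ge.mean() if combine == "mean" else ge.sum()
        row = {
            "participant_id": pid,
            "group": df["group"].iloc[0],
            "field_direction": df["field_direction"].iloc[0],
            "global_emg_first13": float(ge_combined),
            "initial_adaptation_pct": float(first_w["adaptation_pct"].mean()),
            "final_adaptation_pct": float(final_w["adaptation_pct"].mean()),
            "oscillation_initial": float(first_w["oscillation_index"].mean()),
            "oscillation_final": float(final_w["oscillation_index"].mean()),
            "first_block_mpe_m": float(exp.loc[exp["block"] == 1, "mpe_m"].mean()),
        }
        for key in ("c", "b_eff", "retention_a"):
            if extras and pid in extras and key in extras[pid]:
                row[f"true_{key}"] = extras[pid][key]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CocontractionAdaptationResults:
    """Fitted results: metric tables, group summaries, and regressions."""

    trial_metrics: pd.DataFrame
    cohort: pd.DataFrame
    block_metrics: pd.DataFrame
    group_summary: Optional[pd.DataFrame]
    ols_initial: Optional[stats_mod.OLSResult]
    ols_final: Optional[stats_mod.OLSResult]
    multi_initial: Optional[stats_mod.MultiRegressionResult]
    multi_final: Optional[stats_mod.MultiRegressionResult]
    n_blocks_window: int = INITIAL_FINAL_BLOCKS

    @classmethod
    def from_metrics(cls, trial_metrics: pd.DataFrame,
                     cohort: Optional[pd.DataFrame] = None,
                     n_blocks: int = INITIAL_FINAL_BLOCKS,
                     combine: str = "mean") -> "CocontractionAdaptationResults":
        """Rebuild results from a per-trial metric table (e.g. a CSV
        written by the ``analyze`` command)."""
        if cohort is None:
            cohort = build_cohort_table(trial_metrics, n_blocks, combine)
        return cls(
            trial_metrics=trial_metrics,
            cohort=cohort,
            block_metrics=stats_mod.block_average(trial_metrics),
            group_summary=_maybe_group_summary(cohort),
            ols_initial=_maybe_ols(cohort, "initial_adaptation_pct"),
            ols_final=_maybe_ols(cohort, "final_adaptation_pct"),
            multi_initial=_maybe_multi(cohort, "initial_adaptation_pct", "oscillation_initial"),
            multi_final=_maybe_multi(cohort, "final_adaptation_pct", "oscillation_final"),
            n_blocks_window=n_blocks,
        )

    def summary(self) -> str:
        w = self.n_blocks_window
        lines = ["Co-contraction / force-field adaptation analysis",
                 "=" * 49,
                 f"Participants: {len(self.cohort)} "
                 f"({', '.join(f'{g}: {n}' for g, n in self.cohort.groupby('group').size().items())})",
                 ""]
        if self.group_summary is not None:
            lines.append(f"Group means +/- s.e.m. (adaptation windows = {w} blocks):")
            cols = [c for c in self.group_summary.columns if not c.startswith("true_")]
            lines.append(self.group_summary[cols].round(3).to_string())
            lines.append("")
        if self.ols_initial is not None:
            lines.append("Initial adaptation ~ global EMG (first "
                         f"{w} blocks): {self.ols_initial}")
        if self.ols_final is not None:
            lines.append(f"Final adaptation ~ global EMG: {self.ols_final}")
        if self.multi_initial is not None:
            lines.append("Initial adaptation ~ global EMG + oscillation index:")
            lines.append(str(self.multi_initial))
        if self.multi_final is not None:
            lines.append("Final adaptation ~ global EMG + oscillation index:")
            lines.append(str(self.multi_final))
        return "\n".join(lines)

    # plotting / reporting -------------------------------------------------
    def plot_timecourse(self, metric: str = "mpe_m", ax=None):
        from . import report
        return report.plot_timecourse(self, metric, ax=ax)

    def plot_regression(self, which: str = "initial", ax=None):
        from . import report
        return report.plot_regression(self, which, ax=ax)

    def save_report(self, outdir) -> dict:
        from . import report
        return report.build_report(self, outdir)


def _maybe_group_summary(cohort: pd.DataFrame):
    try:
        return stats_mod.group_summary(cohort)
    except ValueError:
        return None


def _maybe_ols(cohort: pd.DataFrame, ycol: str):
    df = cohort.dropna(subset=["global_emg_first13", ycol])
    if len(df) < 3 or np.ptp(df["global_emg_first13"].to_numpy()) == 0:
        return None
    return stats_mod.ols_through_points(df["global_emg_first13"], df[ycol])


def _maybe_multi(cohort: pd.DataFrame, ycol: str, osccol: str):
    df = cohort.dropna(subset=["global_emg_first13", ycol, osccol])
    if len(df) <= 3:
        return None
    try:
        return stats_mod.multiple_regression(df[ycol], df["global_emg_first13"], df[osccol])
    except ValueError:
        return None


class CocontractionAdaptationModel:
    """Cohort-level analysis model.

    Parameters
    ----------
    sessions : iterable of Session
        Sessions to analyze.  A generator is consumed lazily, so a large
        simulated cohort never needs to be held in memory at once.
    emg_config : EMGConfig, optional
        Filtering/window configuration for the EMG pipeline.
    n_blocks_window : int
        Width (in blocks) of the initial/final adaptation windows.
    combine : {"mean", "sum"}
        How the early- and later-window global EMG are combined into the
        regression predictor.
    """

    def __init__(self, sessions: Iterable[Session],
                 emg_config: Optional[emg_mod.EMGConfig] = None,
                 n_blocks_window: int = INITIAL_FINAL_BLOCKS,
                 combine: str = "mean",
                 compute_emg: bool = True):
        self.sessions = sessions
        self.emg_config = emg_config or emg_mod.EMGConfig()
        self.n_blocks_window = n_blocks_window
        self.combine = combine
        self.compute_emg = compute_emg

    @classmethod
    def from_directory(cls, path, **kwargs) -> "CocontractionAdaptationModel":
        """Load every session directory (containing ``session.json``)
        under ``path``."""
        from pathlib import Path
        root = Path(path)
        dirs = sorted(p.parent for p in root.glob("*/session.json"))
        if (root / "session.json").exists():
            dirs = [root] + dirs
        if not dirs:
            raise FileNotFoundError(f"no session.json found under {root}")
        return cls((read_session(d) for d in dirs), **kwargs)

    def fit(self) -> CocontractionAdaptationResults:
        frames = []
        extras = {}
        for sess in self.sessions:
            frames.append(session_metrics(sess, self.emg_config, self.compute_emg))
            if sess.extras:
                extras[sess.participant_id] = sess.extras
        if not frames:
            raise ValueError("no sessions to fit")
        tm = pd.concat(frames, ignore_index=True)
        cohort = build_cohort_table(tm, self.n_blocks_window, self.combine, extras)
        res = CocontractionAdaptationResults.from_metrics(
            tm, cohort, self.n_blocks_window, self.combine)
        return res
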