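"""Cohort aggregation and the EMG-adaptation regressions.

Simple OLS (with intercept) relates each participant's global EMG over the
first 13 exposure blocks to their initial and final adaptation; a multiple
regression adds the channel-trial oscillation index as a second predictor
to check that any EMG-adaptation relationship is not mediated by force
oscillations.  Group contrasts are reported as mean +/- s.e.m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class OLSResult:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    slope_se: float
    n: int
    sm_result: object = None  # underlying statsmodels RegressionResults

    def __str__(self):
        return (f"beta = {self.slope:.3f} (SE {self.slope_se:.3f}), "
                f"R^2 = {self.r_squared:.3f}, F(1, {self.n - 2}) = {self.f_stat:.2f}, "
                f"P = {self.p_value:.3g}")


def ols_through_points(x: Sequence[float], y: Sequence[float]) -> OLSResult:
    """Simple linear regression of y on x with intercept.

    Returns the slope, intercept, R^2 and the F-test of the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope is not identifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return OLSResult(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        r_squared=float(res.rsquared), f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue), slope_se=float(res.bse[1]),
        n=int(x.size), sm_result=res,
    )


@dataclass
class MultiRegressionResult:
    params: dict
    bse: dict
    tvalues: dict
    pvalues: dict
    r_squared: float
    n: int
    sm_result: object = None

    def __str__(self):
        lines = [f"R^2 = {self.r_squared:.3f}, n = {self.n}"]
        for name in self.params:
            lines.append(f"  {name}: beta = {self.params[name]:.3f} "
                         f"(SE {self.bse[name]:.3f}), t = {self.tvalues[name]:.2f}, "
                         f"P = {self.pvalues[name]:.3g}")
        return "\n".join(lines)


def multiple_regression(y: Sequence[float], x1: Sequence[float], x2: Sequence[float],
                        names: tuple = ("global_emg", "oscillation_index")) -> MultiRegressionResult:
    """OLS of y on two predictors with intercept and per-coefficient t-tests."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)])
    if y.size <= 3:
        raise ValueError("need more than 3 observations")
    design = sm.add_constant(X)
    cond = float(np.linalg.cond(design))
    if cond > 1e8:
        raise ValueError(f"collinear predictors (condition number {cond:.3g})")
    res = sm.OLS(y, design).fit()
    keys = ("intercept",) + names
    return MultiRegressionResult(
        params={k: float(v) for k, v in zip(keys, res.params)},
        bse={k: float(v) for k, v in zip(keys, res.bse)},
        tvalues={k: float(v) for k, v in zip(keys, res.tvalues)},
        pvalues={k: float(v) for k, v in zip(keys, res.pvalues)},
        r_squared=float(res.rsquared), n=int(y.size), sm_result=res,
    )


def block_average(metrics: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-block means of per-trial metrics.

    Rows must carry ``phase`` and ``block``; channel-only metrics (stored
    as NaN on non-channel rows) average over the channel trials of each
    block.  Pulse-phase trials carry no block and are excluded.
    """
    df = metrics.dropna(subset=["block"])
    if columns is None:
        columns = [c for c in df.columns
                   if c not in ("participant_id", "group", "field_direction",
                                "phase", "block", "trial_id", "trial_type",
                                "target_angle_deg", "speed_flag", "rest_break_after")
                   and pd.api.types.is_numeric_dtype(df[c])]
    keys = ["phase", "block"]
    if "participant_id" in df.columns and df["participant_id"].nunique() > 1:
        keys = ["participant_id"] + keys
    out = df.groupby(keys, sort=False)[list(columns)].mean().reset_index()
    return out


def group_summary(cohort: pd.DataFrame, metrics: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Mean +/- s.e.m. per group for each cohort-table metric."""
    if "group" not in cohort.columns:
        raise ValueError("cohort table lacks a 'group' column")
    counts = cohort.groupby("group").size()
    if (counts < 2).any() or cohort.empty:
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 participants per group (offending: {small})")
    if metrics is None:
        metrics = [c for c in cohort.columns
                   if c not in ("participant_id", "group", "field_direction")
                   and pd.api.types.is_numeric_dtype(cohort[c])]
    g = cohort.groupby("group")[list(metrics)]
    mean = g.mean()
    sem = g.std(ddof=1) / np.sqrt(g.count())
    out = pd.concat({"mean": mean, "sem": sem}, axis=1)
    out.columns = [f"{m}_{stat}" for stat, m in out.columns]
    return out
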