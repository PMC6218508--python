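"""Figures and machine-readable summaries for a fitted analysis.

``build_report`` writes block-course plots (MPE, adaptation, global EMG,
with rest-break markers), the EMG-adaptation scatter plots with the 95%
confidence band of the fitted line, and a deterministic ``summary.json``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

_PHASE_ORDER = ["pre_exposure", "exposure", "post_exposure"]
_GROUP_COLORS = {"stiff": "tab:red", "relaxed": "tab:blue", "control": "tab:cyan"}

_METRIC_LABELS = {
    "mpe_m": "MPE (m)",
    "adaptation_pct": "Adaptation (%)",
    "global_emg_early": "Global EMG (early window)",
    "global_emg_later": "Global EMG (later window)",
}


def _group_block_course(trial_metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    df = trial_metrics.dropna(subset=["block"])
    df = df[df["phase"].isin(_PHASE_ORDER)]
    per = (df.groupby(["group", "participant_id", "phase", "block"])[metric]
             .mean().reset_index())
    agg = (per.groupby(["group", "phase", "block"])[metric]
              .agg(["mean", "sem"]).reset_index())
    offsets = {}
    off = 0
    for ph in _PHASE_ORDER:
        offsets[ph] = off
        blocks = df.loc[df["phase"] == ph, "block"]
        off += int(blocks.max()) if not blocks.empty else 0
    agg["x"] = agg["block"] + agg["phase"].map(offsets)
    return agg


def _rest_break_x(trial_metrics: pd.DataFrame) -> list:
    df = trial_metrics[trial_metrics["rest_break_after"].fillna(False).astype(bool)]
    df = df.dropna(subset=["block"])
    agg = _group_block_course(trial_metrics.assign(_one=1.0), "_one")
    span = dict(zip(zip(agg["phase"], agg["block"]), agg["x"]))
    xs = sorted({span.get((r.phase, r.block)) for r in df.itertuples()
                 if (r.phase, r.block) in span})
    return [x + 0.5 for x in xs if x is not None]


def plot_timecourse(results, metric: str = "mpe_m", ax=None):
    """Block-averaged group-mean time course with rest-break markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.2))
    agg = _group_block_course(results.trial_metrics, metric)
    for grp, gdf in agg.groupby("group"):
        gdf = gdf.sort_values("x")
        color = _GROUP_COLORS.get(grp)
        ax.plot(gdf["x"], gdf["mean"], label=grp, color=color, lw=1.2)
        ax.fill_between(gdf["x"], gdf["mean"] - gdf["sem"], gdf["mean"] + gdf["sem"],
                        alpha=0.25, color=color, lw=0)
    for x in _rest_break_x(results.trial_metrics):
        ax.axvline(x, ls="--", color="0.6", lw=0.8)
    ax.set_xlabel("block")
    ax.set_ylabel(_METRIC_LABELS.get(metric, metric))
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_regression(results, which: str = "initial", ax=None):
    """Scatter of adaptation vs global EMG with the fitted line and its
    95% confidence band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ycol = f"{which}_adaptation_pct"
    ols = results.ols_initial if which == "initial" else results.ols_final
    df = results.cohort.dropna(subset=["global_emg_first13", ycol])
    for grp, gdf in df.groupby("group"):
        ax.scatter(gdf["global_emg_first13"], gdf[ycol], s=18,
                   color=_GROUP_COLORS.get(grp), label=grp)
    if ols is not None and ols.sm_result is not None:
        import statsmodels.api as sm
        x = df["global_emg_first13"].to_numpy()
        grid = np.linspace(x.min(), x.max(), 100)
        pred = ols.sm_result.get_prediction(sm.add_constant(grid))
        frame = pred.summary_frame(alpha=0.05)
        ax.plot(grid, frame["mean"], color="k", lw=1.2)
        ax.plot(grid, frame["mean_ci_lower"], "k--", lw=0.8)
        ax.plot(grid, frame["mean_ci_upper"], "k--", lw=0.8)
        ax.set_title(f"{which}: {ols}", fontsize=7)
    ax.set_xlabel("global EMG (first-13-block mean)")
    ax.set_ylabel(f"{which} adaptation (%)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def summary_dict(results) -> dict:
    """Machine-readable summary of a fitted analysis."""
    out: dict = {
        "n_participants": int(len(results.cohort)),
        "n_blocks_window": int(results.n_blocks_window),
        "groups": {g: int(n) for g, n in results.cohort.groupby("group").size().items()},
    }
    if results.group_summary is not None:
        out["group_summary"] = {
            g: {c: results.group_summary.loc[g, c] for c in results.group_summary.columns}
            for g in results.group_summary.index
        }
    for name, ols in (("ols_initial", results.ols_initial), ("ols_final", results.ols_final)):
        if ols is not None:
            out[name] = {"slope": ols.slope, "intercept": ols.intercept,
                         "r_squared": ols.r_squared, "f_stat": ols.f_stat,
                         "p_value": ols.p_value, "slope_se": ols.slope_se, "n": ols.n}
    for name, mr in (("multi_initial", results.multi_initial),
                     ("multi_final", results.multi_final)):
        if mr is not None:
            out[name] = {"params": mr.params, "bse": mr.bse, "tvalues": mr.tvalues,
                         "pvalues": mr.pvalues, "r_squared": mr.r_squared, "n": mr.n}
    return _round_floats(out)


def build_report(results, outdir) -> dict:
    """Write figures and ``summary.json`` to ``outdir``; returns the
    summary dict.  Re-running on identical inputs produces byte-identical
    JSON."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    needed = ["mpe_m", "adaptation_pct", "global_emg_early", "global_emg_later"]
    missing = [c for c in needed
               if c not in results.trial_metrics.columns
               or results.trial_metrics[c].isna().all()]
    if missing:
        raise ValueError(f"missing metrics for report: {', '.join(missing)}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for metric in needed:
        ax = plot_timecourse(results, metric)
        ax.figure.savefig(outdir / f"timecourse_{metric}.png", dpi=120,
                          bbox_inches="tight")
        plt.close(ax.figure)
    for which in ("initial", "final"):
        if getattr(results, f"ols_{which}") is not None:
            ax = plot_regression(results, which)
            ax.figure.savefig(outdir / f"regression_{which}.png", dpi=120,
                              bbox_inches="tight")
            plt.close(ax.figure)
    summary = summary_dict(results)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n")
    results.trial_metrics.to_csv(outdir / "trial_metrics.csv", index=False)
    results.cohort.to_csv(outdir / "cohort.csv", index=False)
    return summary
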