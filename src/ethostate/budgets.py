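"""Bout delineation, daily activity budgets, and sex comparisons.

A *bout* is a maximal run of consecutive 30-s windows decoded to the same
state within one burst (bouts never bridge recording gaps). Daily budgets
are the per-individual, per-local-calendar-day fractions of observed
windows spent in each state; partial first/last days are kept and the
denominator is the number of windows actually observed that day.

The sex comparison on bout durations follows the classical decision rule:
Shapiro-Wilk normality in each group first, then a Wilcoxon rank-sum test
if either group departs from normality, otherwise a Student's t test
(equal-variance; Welch via flag). Daily proportions are exported as a tidy
table for external beta-GLMM modelling rather than modelled here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .states import STATE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "Bout",
    "delineate_bouts",
    "daily_budget",
    "compare_sexes",
    "deployment_budget",
]

WINDOW_S = 30.0
#: Study-site local time; configurable (Eastern daylight time by default).
DEFAULT_UTC_OFFSET_H = -4.0


@dataclass
class Bout:
    individual_id: str
    burst_id: str
    state: int  # 1-based
    state_name: str
    start_time: pd.Timestamp
    duration_s: float
    n_windows: int


def delineate_bouts(decoded: pd.DataFrame, window_s: float = WINDOW_S) -> pd.DataFrame:
    """Maximal same-state runs of a decoded window frame.

    ``decoded`` needs ``individual_id``, ``burst_id``, ``window_index``,
    ``window_start`` and (1-based) ``state``. Returns one row per bout with
    ``duration_s`` = run length x window_s.
    """
    req = {"individual_id", "burst_id", "window_index", "state"}
    if missing := req - set(decoded.columns):
        raise ValueError(f"decoded frame is missing columns: {sorted(missing)}")
    d = decoded.sort_values(["individual_id", "burst_id", "window_index"], kind="stable")
    rows = []
    for (ind, burst), grp in d.groupby(["individual_id", "burst_id"], sort=True):
        states = grp["state"].to_numpy(dtype=int)
        change = np.flatnonzero(np.diff(states) != 0) + 1
        edges = np.concatenate([[0], change, [len(states)]])
        for a, b in zip(edges[:-1], edges[1:]):
            rows.append(
                {
                    "individual_id": ind,
                    "burst_id": burst,
                    "state": int(states[a]),
                    "state_name": STATE_NAMES[states[a] - 1],
                    "start_time": grp["window_start"].iloc[a]
                    if "window_start" in grp.columns
                    else pd.NaT,
                    "duration_s": (b - a) * window_s,
                    "n_windows": int(b - a),
                }
            )
    return pd.DataFrame(rows)


def daily_budget(
    decoded: pd.DataFrame,
    utc_offset_h: float = DEFAULT_UTC_OFFSET_H,
    window_s: float = WINDOW_S,
) -> pd.DataFrame:
    """Per individual-day fractions of observed windows in each state.

    Local calendar days come from shifting the UTC window timestamps by
    ``utc_offset_h`` hours. Proportions sum to 1 within each individual-day;
    states an individual cannot occupy simply have proportion 0.
    """
    d = decoded.copy()
    local = pd.to_datetime(d["window_start"], utc=True) + pd.Timedelta(hours=utc_offset_h)
    d["date"] = local.dt.date
    rows = []
    for (ind, date), grp in d.groupby(["individual_id", "date"], sort=True):
        n = len(grp)
        counts = np.bincount(grp["state"].to_numpy(dtype=int) - 1, minlength=len(STATE_NAMES))
        row = {
            "individual_id": ind,
            "sex": grp["sex"].iloc[0] if "sex" in grp.columns else "",
            "gravid": bool(grp["gravid"].iloc[0]) if "gravid" in grp.columns else False,
            "date": date,
            "n_windows": n,
        }
        for name, c in zip(STATE_NAMES, counts):
            row[f"prop_{name}"] = c / n
        rows.append(row)
    return pd.DataFrame(rows)


def deployment_budget(budgets: pd.DataFrame) -> pd.DataFrame:
    """Whole-deployment proportions per individual: the window-count
    weighted mean of that individual's daily proportions."""
    rows = []
    for ind, grp in budgets.groupby("individual_id", sort=True):
        w = grp["n_windows"].to_numpy(float)
        row = {"individual_id": ind, "n_windows": int(w.sum())}
        if "sex" in grp.columns:
            row["sex"] = grp["sex"].iloc[0]
        for name in STATE_NAMES:
            row[f"prop_{name}"] = float(
                np.average(grp[f"prop_{name}"].to_numpy(float), weights=w)
            )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_sexes(
    bouts: pd.DataFrame,
    budgets: pd.DataFrame | None = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> dict:
    """Per-state male-vs-female comparison of bout durations.

    Females are pooled across gravidity. For each state present in both
    sexes: Shapiro-Wilk in each group, then Wilcoxon rank-sum if either
    group rejects normality at ``alpha``, else a Student's t test. Returns
    a dict with the per-state test table and (if ``budgets`` is given) the
    tidy daily-proportion export for external beta-GLMM fitting.
    """
    if "sex" not in bouts.columns:
        raise ValueError("bouts frame needs a 'sex' column")
    sexes = set(bouts["sex"].unique())
    if not {"male", "female"} <= sexes:
        raise ValueError("both sexes must be present for a comparison")
    rows = []
    for state_name in STATE_NAMES:
        sub = bouts[bouts["state_name"] == state_name]
        male = sub.loc[sub["sex"] == "male", "duration_s"].to_numpy(float)
        female = sub.loc[sub["sex"] == "female", "duration_s"].to_numpy(float)
        if len(male) == 0 or len(female) == 0:
            logger.info("state %s absent in one sex; skipped", state_name)
            rows.append(
                {
                    "state_name": state_name, "n_male": len(male), "n_female": len(female),
                    "test": "skipped (state absent in one sex)",
                    "statistic": np.nan, "p_value": np.nan,
                    "shapiro_p_male": np.nan, "shapiro_p_female": np.nan,
                    "mean_male_s": male.mean() if len(male) else np.nan,
                    "mean_female_s": female.mean() if len(female) else np.nan,
                }
            )
            continue
        sw_m = stats.shapiro(male).pvalue if len(np.unique(male)) > 2 else 0.0
        sw_f = stats.shapiro(female).pvalue if len(np.unique(female)) > 2 else 0.0
        nonnormal = (sw_m < alpha) or (sw_f < alpha)
        if nonnormal:
            res = stats.mannwhitneyu(male, female, alternative="two-sided")
            test = "wilcoxon_rank_sum"
        else:
            res = stats.ttest_ind(male, female, equal_var=not welch)
            test = "welch_t" if welch else "student_t"
        rows.append(
            {
                "state_name": state_name, "n_male": len(male), "n_female": len(female),
                "test": test, "statistic": float(res.statistic), "p_value": float(res.pvalue),
                "shapiro_p_male": float(sw_m), "shapiro_p_female": float(sw_f),
                "mean_male_s": float(male.mean()), "mean_female_s": float(female.mean()),
            }
        )
    out = {"bout_tests": pd.DataFrame(rows), "alpha": alpha}
    if budgets is not None:
        export = budgets.melt(
            id_vars=[c for c in ("individual_id", "sex", "gravid", "date", "n_windows")
                     if c in budgets.columns],
            value_vars=[f"prop_{n}" for n in STATE_NAMES],
            var_name="state_name",
            value_name="proportion",
        )
        export["state_name"] = export["state_name"].str.removeprefix("prop_")
        out["budget_export"] = export
    return out
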