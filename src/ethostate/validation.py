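"""Validation of decoded states against annotated windows.

Ground truth for a window can come from contemporaneous video, from
expert-read sensor traces, or (for synthetic studies) from the generator's
labels. The report follows the field's confusion-matrix convention: counts
with manually-classified rows and model-inferred columns, percentages
normalised within each inferred column, per-state accuracies on the
diagonal, and overall accuracy as the matched fraction of all annotated
windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import STATE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionReport",
    "sample_windows_for_annotation",
    "confusion",
    "annotate_from_intervals",
]

_KEY = ["burst_id", "window_index"]


def sample_windows_for_annotation(
    features: pd.DataFrame, n_per_individual: int = 50, seed: int | None = None
) -> pd.DataFrame:
    """Uniform without-replacement sample of windows per individual.

    Returns the sampled ``(individual_id, burst_id, window_index)`` rows,
    reproducible from ``seed``. An individual with fewer windows than
    requested contributes everything it has, with a logged warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ind, grp in features.groupby("individual_id", sort=True):
        n = min(n_per_individual, len(grp))
        if n < n_per_individual:
            logger.warning(
                "individual %s has only %d windows (requested %d); sampling all",
                ind, len(grp), n_per_individual,
            )
        take = rng.choice(len(grp), size=n, replace=False)
        rows.append(grp.iloc[np.sort(take)][["individual_id", *_KEY]])
    return pd.concat(rows, ignore_index=True)


@dataclass
class ConfusionReport:
    """Confusion matrix and accuracy summaries.

    ``counts`` has manually-classified rows and model-inferred columns.
    ``percent_by_inferred`` normalises each inferred column to 100 (the
    printed convention); ``percent_by_manual`` normalises each manual row.
    """

    counts: pd.DataFrame
    percent_by_inferred: pd.DataFrame
    percent_by_manual: pd.DataFrame
    per_state_accuracy: pd.Series
    overall_accuracy: float

    def __str__(self) -> str:
        lines = [
            "Confusion matrix (counts; rows = manual, columns = inferred)",
            self.counts.to_string(),
            "",
            "Percent within inferred class",
            self.percent_by_inferred.to_string(float_format=lambda v: f"{v:6.1f}"),
            "",
            "Per-state accuracy (%):",
            self.per_state_accuracy.to_string(float_format=lambda v: f"{v:6.1f}"),
            f"Overall accuracy: {self.overall_accuracy:.1f}%",
        ]
        return "\n".join(lines)


def confusion(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    state_names: tuple[str, ...] = STATE_NAMES,
) -> ConfusionReport:
    """Cross-tabulate decoded states against annotated windows.

    ``predicted`` needs ``burst_id``, ``window_index`` and (1-based)
    ``state``; ``truth`` needs the same key plus ``true_state``. Every
    annotated window must have a prediction; offenders are listed in the
    error otherwise.
    """
    merged = truth.merge(
        predicted[[*_KEY, "state"]], on=_KEY, how="left", validate="one_to_one"
    )
    if merged["state"].isna().any():
        missing = merged.loc[merged["state"].isna(), _KEY].to_records(index=False)
        raise ValueError(f"annotated windows without predictions: {list(missing)[:10]}")
    k = len(state_names)
    counts = np.zeros((k, k), dtype=int)
    man = merged["true_state"].to_numpy(dtype=int) - 1
    inf = merged["state"].to_numpy(dtype=int) - 1
    np.add.at(counts, (man, inf), 1)
    counts_df = pd.DataFrame(counts, index=list(state_names), columns=list(state_names))
    col_tot = counts.sum(axis=0, keepdims=True)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        by_inf = np.where(col_tot > 0, 100.0 * counts / col_tot, 0.0)
        by_man = np.where(row_tot > 0, 100.0 * counts / row_tot, 0.0)
    per_state = pd.Series(np.diag(by_inf), index=list(state_names))
    overall = 100.0 * np.trace(counts) / counts.sum()
    return ConfusionReport(
        counts=counts_df,
        percent_by_inferred=pd.DataFrame(by_inf, index=list(state_names), columns=list(state_names)),
        percent_by_manual=pd.DataFrame(by_man, index=list(state_names), columns=list(state_names)),
        per_state_accuracy=per_state,
        overall_accuracy=float(overall),
    )


def annotate_from_intervals(
    intervals: pd.DataFrame,
    windows: pd.DataFrame,
    window_s: float = 30.0,
) -> pd.DataFrame:
    """Map annotated time intervals onto 30-s windows by dominant duration.

    ``intervals`` needs ``start_time``, ``end_time`` and ``behaviour``
    (a 1-based state integer or a state name); each window gets the label
    with the largest overlap duration. Ties are excluded and logged.
    """
    name_to_state = {n: i + 1 for i, n in enumerate(STATE_NAMES)}
    iv = intervals.copy()
    if iv["behaviour"].dtype == object:
        iv["behaviour"] = iv["behaviour"].map(name_to_state)
    start = pd.to_datetime(iv["start_time"], utc=True)
    end = pd.to_datetime(iv["end_time"], utc=True)
    rows = []
    for _, w in windows.iterrows():
        w0 = pd.Timestamp(w["window_start"])
        w1 = w0 + pd.Timedelta(seconds=window_s)
        overlap = (np.minimum(end, w1) - np.maximum(start, w0)).dt.total_seconds().clip(lower=0)
        if overlap.sum() <= 0:
            continue
        by_label = overlap.groupby(iv["behaviour"]).sum().sort_values(ascending=False)
        if len(by_label) > 1 and np.isclose(by_label.iloc[0], by_label.iloc[1]):
            logger.warning(
                "window %s/%s has a duration tie; excluded",
                w["burst_id"], w["window_index"],
            )
            continue
        rows.append(
            {
                "burst_id": w["burst_id"],
                "window_index": w["window_index"],
                "true_state": int(by_label.index[0]),
                "source": "video",
            }
        )
    return pd.DataFrame(rows)
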