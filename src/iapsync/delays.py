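"""Gaze–gesture delay metrics, aggregation, extreme-value fences, and
free-task channel-use coding.

The per-trial synchrony index is the delay, in integer ms, from the onset of
the selected communicative gaze shift to the onset of the pointing gesture.
Delays aggregate two ways: per-subject means (the between-subject index) and
sample SDs per subject x block x target side (the within-subject variability
index; cells with fewer than two observations yield no SD).

Extreme values are flagged per group with 3 x IQR fences (quartiles by
linear interpolation between order statistics).

Channel coding turns per-trial binary verbal/gesture annotations plus the
gaze-selection outcome into six mutually exclusive combination flags
(gaze-only, verbal-only, gesture-only, gaze-and-gesture, gaze-and-verbal,
verbal-and-gesture) and three modality-count flags (unimodal, bimodal,
trimodal). Gaze is 1 exactly when the selection algorithm selected a shift;
dismissed trials code 0. First trials of each block are dropped, matching
their exclusion upstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMBO_FLAGS = ["gaze_only", "verbal_only", "gesture_only", "gaze_and_gesture",
               "gaze_and_verbal", "verbal_and_gesture"]
COUNT_FLAGS = ["unimodal", "bimodal", "trimodal"]


def compute_delays(selections: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """One delay record per selected trial: gesture onset minus shift onset.

    ``selections`` comes from the selection module; ``trials`` supplies
    ``gesture_onset_ms``, ``group`` and ``side`` keyed by subject/block/trial.
    Trials with a missing gesture onset are dropped with a log entry.
    """
    sel = selections.loc[selections["status"] == "selected",
                         ["subject", "block", "trial", "onset"]]
    cols = ["subject", "block", "trial", "side", "gesture_onset_ms"]
    if "group" in trials.columns:
        cols.append("group")
    df = sel.merge(trials[cols], on=["subject", "block", "trial"], how="left")
    missing = df["gesture_onset_ms"].isna()
    if missing.any():
        logger.warning("dropping %d selected trials without a gesture onset",
                       int(missing.sum()))
        df = df[~missing]
    df["delay"] = (df["gesture_onset_ms"] - df["onset"]).round().astype(int)
    keep = ["subject", "block", "trial", "side", "delay"]
    if "group" in df.columns:
        keep.insert(1, "group")
    return df[keep].reset_index(drop=True)


def aggregate(records: pd.DataFrame, level: str) -> pd.DataFrame:
    """Aggregate delay records.

    ``level='subject'``: mean delay per subject (one row per subject).
    ``level='sd'``: sample SD (n-1 denominator) per subject x block x side;
    cells with a single observation are omitted (with their count logged).
    """
    if records.empty:
        raise ValueError("no delay records to aggregate")
    keys = ["subject"] + (["group"] if "group" in records.columns else [])
    if level == "subject":
        out = (records.groupby(keys, as_index=False)["delay"]
               .agg(mean_delay="mean", n_obs="size"))
        return out
    if level == "sd":
        g = records.groupby(keys + ["block", "side"], as_index=False)["delay"]
        out = g.agg(sd_delay=lambda v: v.std(ddof=1), n_obs="size")
        thin = out["n_obs"] < 2
        if thin.any():
            logger.info("omitting %d single-observation cells", int(thin.sum()))
        return out[~thin].reset_index(drop=True)
    raise ValueError(f"unknown aggregation level {level!r}")


def flag_extremes(values, group_labels, k: float = 3.0) -> np.ndarray:
    """Per-group 3 x IQR fences; True marks an extreme value.

    Quartiles use linear interpolation between order statistics. Groups with
    fewer than 4 values are not flagged (a warning is logged).
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    mask = np.zeros(values.shape, dtype=bool)
    for g in pd.unique(group_labels):
        sel = group_labels == g
        v = values[sel]
        if v.size < 4:
            logger.warning("group %r has %d values; skipping extreme-value "
                           "flagging", g, v.size)
            continue
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        mask[sel] = (v > q3 + k * iqr) | (v < q1 - k * iqr)
    return mask


def table2_report(subject_means: pd.DataFrame, sd_records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive group summary of the two synchrony indices, from
    participant-wise aggregated data: M, SD, Mdn, min, max per group."""
    subj_sd = (sd_records.groupby(["subject", "group"], as_index=False)["sd_delay"]
               .mean().rename(columns={"sd_delay": "value"}))
    subj_mean = subject_means.rename(columns={"mean_delay": "value"})
    rows = []
    for name, df in (("gaze_gesture_delay", subj_mean), ("sd_of_delays", subj_sd)):
        for g, sub in df.groupby("group"):
            v = sub["value"]
            rows.append({"measure": name, "group": g, "M": v.mean(),
                         "SD": v.std(ddof=1), "Mdn": v.median(),
                         "min": v.min(), "max": v.max(), "n": len(v)})
    return pd.DataFrame(rows)


def code_channels(annotations: pd.DataFrame, selections: pd.DataFrame) -> pd.DataFrame:
    """Per-trial channel-use codes from rater annotations plus the gaze
    algorithm's outcome.

    ``annotations`` must hold subject/block/trial plus binary ``verbal`` and
    ``gesture`` columns. Trials without a matching annotation are dropped
    with a log entry; first trials of each block are excluded from the
    output. The six combination flags are mutually exclusive, and the
    count flags partition trials using at least one channel.
    """
    keys = ["subject", "block", "trial"]
    sel = selections[keys + ["status"]].copy()
    sel["gaze"] = (sel.pop("status") == "selected").astype(int)
    df = sel.merge(annotations, on=keys, how="left", indicator=True)
    unmatched = df["_merge"] != "both"
    if unmatched.any():
        logger.warning("dropping %d trials without annotations", int(unmatched.sum()))
        df = df[~unmatched]
    df = df.drop(columns="_merge")
    df = df[df["trial"] != 1].reset_index(drop=True)
    g, v, ge = df["gaze"], df["verbal"].astype(int), df["gesture"].astype(int)
    n_channels = g + v + ge
    df["gaze_only"] = ((g == 1) & (v == 0) & (ge == 0)).astype(int)
    df["verbal_only"] = ((g == 0) & (v == 1) & (ge == 0)).astype(int)
    df["gesture_only"] = ((g == 0) & (v == 0) & (ge == 1)).astype(int)
    df["gaze_and_gesture"] = ((g == 1) & (v == 0) & (ge == 1)).astype(int)
    df["gaze_and_verbal"] = ((g == 1) & (v == 1) & (ge == 0)).astype(int)
    df["verbal_and_gesture"] = ((g == 0) & (v == 1) & (ge == 1)).astype(int)
    df["unimodal"] = (n_channels == 1).astype(int)
    df["bimodal"] = (n_channels == 2).astype(int)
    df["trimodal"] = (n_channels == 3).astype(int)
    return df


def channel_frequencies(codes: pd.DataFrame) -> pd.DataFrame:
    """Per-group usage rates of each channel flag."""
    cols = ["gaze", "verbal", "gesture"] + COMBO_FLAGS + COUNT_FLAGS
    keys = ["group"] if "group" in codes.columns else []
    if keys:
        return codes.groupby(keys, as_index=False)[cols].mean()
    return codes[cols].mean().to_frame("rate").reset_index(names="flag")
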