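"""Communicative gaze-shift selection.

A communicative gaze shift starts in the partner's face region (social RoI)
and ends on the target stimulus. Three pathways qualify:

* **direct** — a single saccade social -> target (candidate: that saccade);
* **social-refix** — saccade social -> social, then social -> target
  (candidate: the *second* saccade);
* **random-refix** — saccade social -> some undefined region, then -> target
  (candidate: the *first* saccade, whose goal the corrective second saccade
  merely completes).

Chains are capped at one intermediate fixation, and a fixation on the
non-target stimulus bar is not a valid intermediate (it lands in a defined
RoI, not an undefined one).

Per trial, six exclusion rules are applied in listed precedence order:

1. first trial of a block (tracker warm-up recommendation);
2. gaze not inside the social RoI at the stimulus-onset sample;
3. no candidate communicative shift;
4. a blink ending within 100 ms before stimulus onset (or spanning it);
5. saccade latency of the pathway's first saccade below 75 ms (too short to
   be externally triggered);
6. gesture onset preceding the candidate shift onset.

Otherwise the earliest qualifying candidate is selected. Exactly one
exclusion code is ever assigned: the lowest-numbered violated rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gazeparse import ParserConfig, RoIMap, assign_roi, detect_events

SELECTION_COLUMNS = ["subject", "block", "trial", "status", "exclusion_code",
                     "onset", "offset", "pathway", "saccade_latency"]

# exclusion codes, in precedence order (after the implicit rule-1 index check)
CODE_FIRST_TRIAL = "first_trial"
CODE_NOT_SOCIAL = "gaze_not_social_at_onset"
CODE_NO_SHIFT = "no_comm_shift"
CODE_BLINK = "blink_pre_onset"
CODE_LATENCY = "latency_lt_75"
CODE_GESTURE_FIRST = "gesture_precedes_gaze"
CODE_INDETERMINATE = "indeterminate_gesture"

MIN_SACCADE_LATENCY_MS = 75
BLINK_WINDOW_MS = 100


@dataclass(frozen=True)
class Candidate:
    pathway: str
    onset: int
    offset: int
    first_saccade_onset: int
    latency: int  # first pathway saccade onset - stimulus onset


def classify_pathways(events: pd.DataFrame, roi_map: RoIMap,
                      stimulus_onset: int, target_side: str) -> list[Candidate]:
    """Enumerate candidate communicative shifts after stimulus onset.

    Fixations are labeled by their centroid. Chains are scanned in order of
    their anchor saccade's onset; when two chains share a candidate saccade
    (a face-refixation chain's second saccade is, viewed alone, also a direct
    saccade), the earlier chain wins.
    """
    target = "left_stim" if target_side == "left" else "right_stim"
    ev = events.reset_index(drop=True)
    kinds = ev["kind"].to_numpy()
    labels = np.full(len(ev), "", dtype=object)
    fix_idx = np.flatnonzero(kinds == "fixation")
    if fix_idx.size:
        labels[fix_idx] = assign_roi(ev.loc[fix_idx, "x_start"].to_numpy(),
                                     ev.loc[fix_idx, "y_start"].to_numpy(), roi_map)

    def _fix_before(i):
        j = i - 1
        return j if j >= 0 and kinds[j] == "fixation" else None

    def _fix_after(i):
        j = i + 1
        return j if j < len(ev) and kinds[j] == "fixation" else None

    def _next_saccade(j):
        k = j + 1
        return k if k < len(ev) and kinds[k] == "saccade" else None

    candidates: list[Candidate] = []
    seen: set[int] = set()
    for i in np.flatnonzero(kinds == "saccade"):
        s1 = ev.iloc[i]
        if s1["onset"] < stimulus_onset:
            continue
        pre = _fix_before(i)
        if pre is None or labels[pre] != "social":
            continue
        post = _fix_after(i)
        if post is None:
            continue
        latency = int(s1["onset"] - stimulus_onset)
        land = labels[post]
        if land == target:
            if i not in seen:
                candidates.append(Candidate("direct", int(s1["onset"]),
                                            int(s1["offset"]), int(s1["onset"]),
                                            latency))
                seen.add(i)
            continue
        if land not in ("social", "random"):
            continue  # landing on the non-target bar: not a valid intermediate
        k = _next_saccade(post)
        if k is None:
            continue
        post2 = _fix_after(k)
        if post2 is None or labels[post2] != target:
            continue
        s2 = ev.iloc[k]
        if land == "social":
            if k not in seen:
                candidates.append(Candidate("social-refix", int(s2["onset"]),
                                            int(s2["offset"]), int(s1["onset"]),
                                            latency))
                seen.add(k)
        else:
            if i not in seen:
                candidates.append(Candidate("random-refix", int(s1["onset"]),
                                            int(s1["offset"]), int(s1["onset"]),
                                            latency))
                seen.add(i)
    candidates.sort(key=lambda c: (c.onset, c.first_saccade_onset))
    return candidates


def select_communicative_shift(samples: pd.DataFrame, events: pd.DataFrame,
                               roi_map: RoIMap, stimulus_onset: int,
                               target_side: str, gesture_onset,
                               is_first_trial: bool,
                               blink_window_ms: int = BLINK_WINDOW_MS,
                               min_latency_ms: int = MIN_SACCADE_LATENCY_MS) -> dict:
    """Apply the exclusion rules and pick the first qualifying shift.

    Returns a dict with ``status`` (``selected`` | ``excluded``),
    ``exclusion_code``, ``onset``/``offset``, ``pathway`` and
    ``saccade_latency`` fields (NaN where not applicable).
    """
    def excluded(code):
        return {"status": "excluded", "exclusion_code": code, "onset": np.nan,
                "offset": np.nan, "pathway": "", "saccade_latency": np.nan}

    if is_first_trial:
        return excluded(CODE_FIRST_TRIAL)

    row = samples.loc[samples["time_ms"] == stimulus_onset]
    in_social = False
    if len(row) == 1 and bool(row["valid"].iloc[0]):
        in_social = assign_roi(float(row["x_px"].iloc[0]),
                               float(row["y_px"].iloc[0]), roi_map) == "social"
    if not in_social:
        return excluded(CODE_NOT_SOCIAL)

    candidates = classify_pathways(events, roi_map, stimulus_onset, target_side)
    if not candidates:
        return excluded(CODE_NO_SHIFT)

    blinks = events[events["kind"] == "blink"]
    for b in blinks.itertuples(index=False):
        ends_in_window = stimulus_onset - blink_window_ms <= b.offset <= stimulus_onset
        spans_onset = b.onset <= stimulus_onset < b.offset
        if ends_in_window or spans_onset:
            return excluded(CODE_BLINK)

    cand = candidates[0]
    if cand.latency < min_latency_ms:
        return excluded(CODE_LATENCY)

    if gesture_onset is None or (isinstance(gesture_onset, float) and np.isnan(gesture_onset)):
        # cannot evaluate the gesture-precedence rule: flag, treat as exclusion
        return excluded(CODE_INDETERMINATE)
    if gesture_onset < cand.onset:
        return excluded(CODE_GESTURE_FIRST)

    return {"status": "selected", "exclusion_code": "", "onset": cand.onset,
            "offset": cand.offset, "pathway": cand.pathway,
            "saccade_latency": cand.latency}


def select_trial(samples: pd.DataFrame, meta: dict, roi_map: RoIMap,
                 parser: ParserConfig | None = None, **kwargs) -> dict:
    """Parse one trial's stream and run selection. ``meta`` needs
    ``subject, block, trial, side, stim_onset_ms, gesture_onset_ms``."""
    events = detect_events(samples, parser)
    res = select_communicative_shift(
        samples, events, roi_map, int(meta["stim_onset_ms"]), meta["side"],
        meta.get("gesture_onset_ms"), is_first_trial=int(meta["trial"]) == 1,
        **kwargs)
    res.update(subject=meta["subject"], block=meta["block"], trial=meta["trial"])
    return res


def select_cohort(stream_iter, roi_map: RoIMap,
                  parser: ParserConfig | None = None, **kwargs) -> pd.DataFrame:
    """Run selection over an iterable of ``(key, meta, stream)`` trials
    (e.g. :func:`iapsync.synthetic.iter_trial_streams`)."""
    rows = [select_trial(stream, meta, roi_map, parser, **kwargs)
            for _, meta, stream in stream_iter]
    return pd.DataFrame(rows, columns=SELECTION_COLUMNS)


def exclusion_tally(selections: pd.DataFrame,
                    groups: pd.DataFrame | None = None) -> pd.DataFrame:
    """Counts of selected/excluded trials per exclusion category (and per
    group when a subject->group mapping is supplied)."""
    df = selections.copy()
    df["category"] = np.where(df["status"] == "selected", "selected",
                              df["exclusion_code"])
    if groups is not None:
        df = df.merge(groups[["subject", "group"]].drop_duplicates(), on="subject")
        return df.groupby(["group", "category"]).size().rename("n").reset_index()
    return df.groupby("category").size().rename("n").reset_index()
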