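"""Synthetic cohorts for the gaze–gesture synchrony analysis.

The simulator emulates a two-group study (autistic and typically-developed
adults) in which each trial shows a lateralized target that the participant
announces to a partner with a gaze shift from the partner's face to the
target, followed by a pointing gesture. Ground truth is recorded for every
trial: the programmed communicative-shift onset, the gaze–gesture delay, the
gaze pathway, and which (if any) exclusion rule the trial violates.

Structure of the generated data
-------------------------------
* Subject level: each subject receives a mean delay and a within-subject
  delay SD from a bivariate lognormal, so delays are positive/right-skewed
  and subjects with larger mean delays tend to have larger SDs
  (``mean_sd_coupling`` is the correlation on the log scale).
* Group level: the autistic group's subject means are shifted upward by
  ``group_delay_shift`` (default 55 ms) relative to the comparison group.
* Trial level: delay = subject mean + Gaussian noise (redrawn to stay
  positive); saccade latency is uniform on ``saccade_latency_range``.
* Gaze streams are piecewise fixation–saccade–fixation signals at 1000 Hz
  with raised-cosine saccade velocity pulses and additive Gaussian position
  noise. Ground-truth shift onsets are defined operationally: the first
  sample at which the noise-free programmed trace, run through the same
  velocity pipeline as the parser, reaches the 30 deg/s criterion.

Exclusion-rule emulation (labels mirror the selection algorithm's rules,
in precedence order): first trial of a block; gaze not on the partner's
face at stimulus onset; no communicative shift; a blink ending within
100 ms before stimulus onset; saccade latency below 75 ms; gesture onset
preceding the gaze-shift onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

from .gazeparse import (ParserConfig, RoIMap, ScreenGeometry, angular_speed,
                        GAZE_COLUMNS)

EXCLUSION_LABELS = (
    "none",
    "first_trial",
    "gaze_not_social_at_onset",
    "no_comm_shift",
    "blink_pre_onset",
    "latency_lt_75",
    "gesture_precedes_gaze",
)
# rules that are drawn at random for non-first trials
_RANDOM_RULES = EXCLUSION_LABELS[2:]

PATHWAYS = ("direct", "social-refix", "random-refix")

TRUTH_COLUMNS = [
    "subject", "group", "block", "trial", "side", "stim_onset_ms",
    "gesture_onset_ms", "true_shift_onset", "true_delay", "saccade_latency",
    "pathway", "exclusion_label", "subject_mean_ms", "subject_sd_ms",
]
TRIAL_COLUMNS = ["subject", "group", "block", "trial", "side",
                 "stim_onset_ms", "gesture_onset_ms"]


def default_geometry() -> ScreenGeometry:
    return ScreenGeometry()


def default_roi_map() -> RoIMap:
    """Default setup: face square centered above the screen's top edge,
    stimulus bars on the left/right of the upper half of the screen."""
    return RoIMap(
        social=(810.0, -400.0, 1110.0, -100.0),
        left_stim=(200.0, 100.0, 500.0, 300.0),
        right_stim=(1420.0, 100.0, 1720.0, 300.0),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and distributional settings for a synthetic cohort.

    All times in ms. Distributional defaults follow the group summaries the
    analysis is designed around: comparison-group mean delay 206 ms with
    59 ms between-subject SD, a +55 ms group shift, within-subject SDs of
    81 ms (comparison) and 95 ms (autistic) with ~45 ms between-subject
    dispersion, and a +0.6 coupling between subject mean and subject SD.
    """

    n_per_group: int = 24
    n_blocks: int = 4
    trials_per_block: int = 30
    group_delay_shift: float = 55.0
    td_mean_delay: float = 206.0
    td_between_subject_sd: float = 59.0
    within_subject_sd_td: float = 81.0
    within_subject_sd_asd: float = 95.0
    sd_dispersion: float = 45.0
    mean_sd_coupling: float = 0.6
    saccade_latency_range: tuple[int, int] = (120, 300)
    sample_rate: int = 1000
    seed: int = 0
    stim_onset_ms: int = 1000
    exclusion_rate: float = 0.03
    pathway_probs: tuple[float, float, float] = (0.8, 0.1, 0.1)
    position_noise_px: float = 0.5
    p_verbal: float = 0.45
    p_gesture: float = 0.75
    geometry: ScreenGeometry = field(default_factory=default_geometry)
    roi_map: RoIMap = field(default_factory=default_roi_map)
    parser: ParserConfig = field(default_factory=ParserConfig)

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_blocks", "trials_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("td_between_subject_sd", "within_subject_sd_td",
                     "within_subject_sd_asd", "sd_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not -1.0 <= self.mean_sd_coupling <= 1.0:
            raise ValueError("mean_sd_coupling must lie in [-1, 1]")
        if self.sample_rate != 1000:
            raise ValueError("sample_rate is fixed at 1000 Hz")
        if not 0.0 <= self.exclusion_rate <= 0.15:
            raise ValueError("exclusion_rate must lie in [0, 0.15]")
        lo, hi = self.saccade_latency_range
        if not 75 < lo < hi:
            raise ValueError("saccade_latency_range must satisfy 75 < lo < hi")


@dataclass
class CohortData:
    """A generated cohort: public trial table, full ground truth, and
    (optionally) the per-trial gaze streams keyed by (subject, block, trial)."""

    config: CohortConfig
    trials: pd.DataFrame
    truth: pd.DataFrame
    streams: dict | None = None


# --------------------------------------------------------------------------
# subject-level draws

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def draw_subject_params(config: CohortConfig, group: str, n: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mean delay, within-subject SD) pairs for ``n`` subjects.

    Bivariate lognormal with correlation ``mean_sd_coupling`` on the log
    scale; marginal means/SDs follow the group's configured targets.
    """
    m_target = config.td_mean_delay + (config.group_delay_shift if group == "ASD" else 0.0)
    w_target = config.within_subject_sd_asd if group == "ASD" else config.within_subject_sd_td
    mu_m, s_m = _lognormal_params(m_target, config.td_between_subject_sd)
    mu_w, s_w = _lognormal_params(w_target, config.sd_dispersion)
    rho = config.mean_sd_coupling
    cov = np.array([[s_m ** 2, rho * s_m * s_w], [rho * s_m * s_w, s_w ** 2]])
    z = rng.multivariate_normal([mu_m, mu_w], cov, size=n)
    return np.exp(z[:, 0]), np.exp(z[:, 1])


# --------------------------------------------------------------------------
# per-trial planning

def _trial_rng(config: CohortConfig, stream_no: int, subj_idx: int,
               block: int, trial: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream_no,
                                  subj_idx, block, trial])


def _draw_positive_delay(rng, mean, sd) -> float:
    for _ in range(100):
        d = rng.normal(mean, sd)
        if d >= 1.0:
            return float(d)
    return 1.0


def _rect_jitter(rng, rect, margin=40.0):
    x0, y0, x1, y1 = rect
    return (float(rng.uniform(x0 + margin, x1 - margin)),
            float(rng.uniform(y0 + margin, y1 - margin)))


def _saccade_duration_ms(amp_deg: float) -> int:
    # main-sequence style duration: ~21 ms intercept + 2.2 ms/deg
    return max(20, int(round(21.0 + 2.2 * amp_deg)))


def _amp_deg(p0, p1, geometry: ScreenGeometry) -> float:
    from .gazeparse import px_to_deg
    a = px_to_deg(*p0, geometry)
    b = px_to_deg(*p1, geometry)
    return float(math.hypot(b[0] - a[0], b[1] - a[1]))


def _pulse_positions(p0, p1, dur: int) -> np.ndarray:
    """Noise-free saccade samples for t = 0..dur-1 (raised-cosine velocity)."""
    tau = np.arange(dur, dtype=float) / dur
    s = tau - np.sin(2 * np.pi * tau) / (2 * np.pi)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    return p0 + np.outer(s, p1 - p0)


def _crossing_offset(p0, p1, dur: int, config: CohortConfig) -> int:
    """Sample offset (from pulse start) at which the programmed trace first
    reaches the parser's velocity criterion, using the parser's own
    differentiation and smoothing."""
    pad = 6
    pos = np.vstack([
        np.repeat([p0], pad, axis=0),
        _pulse_positions(p0, p1, dur),
        np.repeat([p1], pad, axis=0),
    ])
    speed = angular_speed(pos[:, 0], pos[:, 1], config.geometry,
                          config.parser.smooth_width_ms)
    idx = np.flatnonzero(speed >= config.parser.velocity_threshold_deg_s)
    if idx.size == 0:  # pragma: no cover - pulses are far above threshold
        raise RuntimeError("programmed saccade never reaches the velocity threshold")
    return int(idx[0] - pad)


def _plan_trial(config: CohortConfig, rng: np.random.Generator, subject: str,
                group: str, block: int, trial: int, side: str,
                mean_i: float, sd_i: float, *, forced_exclusion: str | None = None,
                overrides: dict | None = None, geometry_pass: bool = True) -> dict:
    """Draw the ground truth for one trial and (optionally) its segment plan.

    Statistical draws happen first and in a fixed order so that the fast
    (table-only) path and the full (stream) path produce identical truth.
    """
    overrides = overrides or {}

    if forced_exclusion is not None:
        excl = forced_exclusion
    elif trial == 1:
        excl = "first_trial"
    else:
        u = rng.random()
        k = int(u / config.exclusion_rate) if config.exclusion_rate > 0 else len(_RANDOM_RULES)
        excl = _RANDOM_RULES[k] if k < len(_RANDOM_RULES) else "none"

    pw = PATHWAYS[int(rng.choice(3, p=np.asarray(config.pathway_probs) /
                                 np.sum(config.pathway_probs)))]
    if excl == "gaze_not_social_at_onset":
        pw = "direct"  # the anchor fixation is off-face; pathway is moot
    lo, hi = config.saccade_latency_range
    latency = int(rng.integers(lo, hi + 1))
    short_latency = int(rng.integers(30, 71))
    delay = _draw_positive_delay(rng, mean_i, sd_i)
    blink_dur = int(rng.integers(80, 151))
    blink_gap = int(rng.integers(10, 91))
    gesture_lead = int(rng.integers(20, 81))
    fix_dur = int(rng.integers(80, 151))
    no_shift_wait = int(rng.integers(300, 501))

    if excl == "latency_lt_75":
        latency = short_latency
    latency = int(overrides.get("latency", latency))
    blink_gap = int(overrides.get("blink_gap", blink_gap))
    blink_dur = int(overrides.get("blink_dur", blink_dur))
    gesture_lead = int(overrides.get("gesture_lead", gesture_lead))
    delay = float(overrides.get("delay", delay))
    delay_int = int(round(delay))

    plan = {
        "subject": subject, "group": group, "block": block, "trial": trial,
        "side": side, "stim_onset_ms": config.stim_onset_ms,
        "pathway": pw, "exclusion_label": excl,
        "saccade_latency": latency, "subject_mean_ms": mean_i,
        "subject_sd_ms": sd_i,
    }
    if not geometry_pass:
        plan.update(gesture_onset_ms=np.nan, true_shift_onset=np.nan,
                    true_delay=delay_int if excl == "none" else np.nan)
        return plan

    stim = config.stim_onset_ms
    roi = config.roi_map
    social_rect = roi.social
    target_rect = roi.rect("left_stim" if side == "left" else "right_stim")

    p_social = _rect_jitter(rng, social_rect)
    p_target = _rect_jitter(rng, target_rect)
    segments: list[dict] = []

    if excl == "gaze_not_social_at_onset":
        # start outside every RoI; otherwise a normal direct trial
        p_start = (float(rng.uniform(700, 1200)), float(rng.uniform(500, 900)))
    else:
        p_start = p_social

    if excl == "no_comm_shift":
        gesture = stim + no_shift_wait
        t_end = gesture + 200
        segments.append({"kind": "fix", "t0": 0, "t1": t_end, "pos": p_start})
        plan.update(gesture_onset_ms=gesture, true_shift_onset=np.nan,
                    true_delay=np.nan, segments=segments, t_end=t_end)
        return plan

    if pw == "direct":
        dur1 = _saccade_duration_ms(_amp_deg(p_start, p_target, config.geometry))
        dt1 = _crossing_offset(p_start, p_target, dur1, config)
        t1 = stim + latency - dt1
        shift_onset = stim + latency
        segments.append({"kind": "fix", "t0": 0, "t1": t1, "pos": p_start})
        segments.append({"kind": "sacc", "t0": t1, "t1": t1 + dur1,
                         "p0": p_start, "p1": p_target})
        last_end = t1 + dur1
        end_pos = p_target
    else:
        if pw == "social-refix":
            while True:
                p_mid = _rect_jitter(rng, social_rect)
                if math.hypot(p_mid[0] - p_start[0], p_mid[1] - p_start[1]) >= 110:
                    break
        else:  # random-refix: an inaccurate landing outside all RoIs
            p_mid = (float(rng.uniform(700, 1200)), float(rng.uniform(450, 850)))
        dur1 = _saccade_duration_ms(_amp_deg(p_start, p_mid, config.geometry))
        dt1 = _crossing_offset(p_start, p_mid, dur1, config)
        t1 = stim + latency - dt1
        dur2 = _saccade_duration_ms(_amp_deg(p_mid, p_target, config.geometry))
        dt2 = _crossing_offset(p_mid, p_target, dur2, config)
        t2 = t1 + dur1 + fix_dur
        segments.append({"kind": "fix", "t0": 0, "t1": t1, "pos": p_start})
        segments.append({"kind": "sacc", "t0": t1, "t1": t1 + dur1,
                         "p0": p_start, "p1": p_mid})
        segments.append({"kind": "fix", "t0": t1 + dur1, "t1": t2, "pos": p_mid})
        segments.append({"kind": "sacc", "t0": t2, "t1": t2 + dur2,
                         "p0": p_mid, "p1": p_target})
        last_end = t2 + dur2
        # the communicative shift: for a face-refixation chain the second
        # saccade counts; for a random-refixation chain the first does
        shift_onset = (t2 + dt2) if pw == "social-refix" else (stim + latency)
        end_pos = p_target

    if excl == "gesture_precedes_gaze":
        gesture = shift_onset - gesture_lead
    else:
        gesture = shift_onset + delay_int

    t_end = max(last_end + 150, gesture) + 200
    segments.append({"kind": "fix", "t0": last_end, "t1": t_end, "pos": end_pos})

    if excl == "blink_pre_onset":
        b1 = stim - blink_gap
        b0 = b1 - blink_dur
        segments.append({"kind": "blink", "t0": b0, "t1": b1})

    plan.update(
        gesture_onset_ms=int(gesture),
        true_shift_onset=int(shift_onset) if excl == "none" else np.nan,
        true_delay=delay_int if excl == "none" else np.nan,
        segments=segments, t_end=int(t_end),
    )
    if excl == "none":
        plan["true_shift_onset"] = int(shift_onset)
    return plan


def _sides_for_block(config: CohortConfig, subj_idx: int, block: int) -> list[str]:
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 3, subj_idx, block])
    n = config.trials_per_block
    sides = ["left", "right"] * (n // 2 + 1)
    sides = sides[:n]
    rng.shuffle(sides)
    return sides


def _subject_table(config: CohortConfig) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 1])
    rows = []
    for group in ("ASD", "TD"):
        means, sds = draw_subject_params(config, group, config.n_per_group, rng)
        for i in range(config.n_per_group):
            rows.append({"subject": f"{group}{i + 1:02d}", "group": group,
                         "subject_mean_ms": means[i], "subject_sd_ms": sds[i]})
    return pd.DataFrame(rows)


def _iter_plans(config: CohortConfig, geometry_pass: bool):
    subjects = _subject_table(config)
    for subj_idx, srow in enumerate(subjects.itertuples(index=False)):
        for block in range(1, config.n_blocks + 1):
            sides = _sides_for_block(config, subj_idx, block)
            for trial in range(1, config.trials_per_block + 1):
                rng = _trial_rng(config, 2, subj_idx, block, trial)
                yield subj_idx, _plan_trial(
                    config, rng, srow.subject, srow.group, block, trial,
                    sides[trial - 1], srow.subject_mean_ms, srow.subject_sd_ms,
                    geometry_pass=geometry_pass)


def _plan_to_truth_row(plan: dict) -> dict:
    return {k: plan.get(k) for k in TRUTH_COLUMNS}


def generate_cohort(config: CohortConfig, streams: bool = False) -> CohortData:
    """Generate a full cohort. With ``streams=True`` the per-trial 1000 Hz
    gaze streams are materialized in memory (sized for small/medium cohorts;
    use :func:`iter_trial_streams` for large ones)."""
    truth_rows, stream_map = [], ({} if streams else None)
    for subj_idx, plan in _iter_plans(config, geometry_pass=True):
        truth_rows.append(_plan_to_truth_row(plan))
        if streams:
            key = (plan["subject"], plan["block"], plan["trial"])
            stream_map[key] = synthesize_stream(config, plan, subj_idx)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    trials = truth[TRIAL_COLUMNS].copy()
    return CohortData(config=config, trials=trials, truth=truth, streams=stream_map)


def simulate_delay_table(config: CohortConfig) -> pd.DataFrame:
    """Fast path for statistical simulation: ground-truth table only, no
    stream geometry. Identical trial-level truth (labels, delays, latencies)
    to :func:`generate_cohort`."""
    rows = [_plan_to_truth_row(plan)
            for _, plan in _iter_plans(config, geometry_pass=False)]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def iter_trial_streams(config: CohortConfig):
    """Yield ``(key, truth_row_dict, stream_df)`` per trial without holding
    the whole cohort's streams in memory."""
    for subj_idx, plan in _iter_plans(config, geometry_pass=True):
        key = (plan["subject"], plan["block"], plan["trial"])
        yield key, _plan_to_truth_row(plan), synthesize_stream(config, plan, subj_idx)


def synthesize_stream(config: CohortConfig, plan: dict,
                      subj_idx: int = 0) -> pd.DataFrame:
    """Render a planned trial into a 1000 Hz gaze sample stream."""
    n = int(plan["t_end"])
    x = np.empty(n)
    y = np.empty(n)
    valid = np.ones(n, dtype=bool)
    for seg in plan["segments"]:
        a, b = int(seg["t0"]), int(seg["t1"])
        if seg["kind"] == "fix":
            x[a:b] = seg["pos"][0]
            y[a:b] = seg["pos"][1]
        elif seg["kind"] == "sacc":
            pos = _pulse_positions(seg["p0"], seg["p1"], b - a)
            x[a:b] = pos[:, 0]
            y[a:b] = pos[:, 1]
        elif seg["kind"] == "blink":
            valid[a:b] = False
    noise_rng = _trial_rng(config, 4, subj_idx, plan["block"], plan["trial"])
    if config.position_noise_px > 0:
        x += noise_rng.normal(0, config.position_noise_px, n)
        y += noise_rng.normal(0, config.position_noise_px, n)
    x[~valid] = np.nan
    y[~valid] = np.nan
    return pd.DataFrame({"time_ms": np.arange(n, dtype=np.int64),
                         "x_px": x, "y_px": y, "valid": valid})


def make_exclusion_case(rule_id: str, config: CohortConfig | None = None,
                        rng: np.random.Generator | int | None = None,
                        overrides: dict | None = None):
    """Construct a single trial violating exactly ``rule_id`` (and no rule of
    higher precedence). Returns ``(stream_df, truth_row_dict)``.

    ``overrides`` may pin specific draws, e.g. ``{"latency": 50}``,
    ``{"blink_gap": 40}``, ``{"gesture_lead": 30}``.
    """
    if rule_id not in EXCLUSION_LABELS:
        raise ValueError(f"unknown exclusion rule {rule_id!r}")
    config = config or CohortConfig()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    trial = 1 if rule_id == "first_trial" else 2
    plan = _plan_trial(config, rng, "S01", "TD", 1, trial, "left",
                       config.td_mean_delay, config.within_subject_sd_td,
                       forced_exclusion=rule_id, overrides=overrides)
    stream = synthesize_stream(config, plan, subj_idx=0)
    return stream, _plan_to_truth_row(plan)


def generate_annotations(config: CohortConfig, trials: pd.DataFrame) -> pd.DataFrame:
    """Synthetic free-task rater annotations: per-trial binary verbal and
    gesture usage, Bernoulli with the configured base rates."""
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 5])
    n = len(trials)
    out = trials[["subject", "group", "block", "trial"]].copy()
    out["verbal"] = rng.random(n) < config.p_verbal
    out["gesture"] = rng.random(n) < config.p_gesture
    out[["verbal", "gesture"]] = out[["verbal", "gesture"]].astype(int)
    return out


def write_cohort_csv(cohort: CohortData, outdir) -> None:
    """Persist a cohort in the package's CSV dialects."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.trials.to_csv(outdir / "trials.csv", index=False)
    cohort.truth.to_csv(outdir / "truth.csv", index=False)
    if cohort.streams:
        sdir = outdir / "streams"
        sdir.mkdir(exist_ok=True)
        for (subj, block, trial), df in cohort.streams.items():
            df.to_csv(sdir / f"{subj}_b{block}_t{trial:02d}.csv", index=False,
                      columns=GAZE_COLUMNS)


# --------------------------------------------------------------------------
# gesture-video ground truth and rendering

@dataclass
class VideoTruth:
    """Programmed fingertip trajectory for a rendered gesture video.

    ``centers`` holds per-frame blob centers in px (x, y); NaN rows mark
    frames in which the blob is absent. The programmed amplitude is the
    start-to-end displacement of the outward stroke, in mm; the programmed
    mean velocity is path length / stroke duration, in mm/ms.
    """

    centers: np.ndarray
    px_per_mm: float
    amplitude_mm: float
    mean_velocity_mm_ms: float
    stroke: tuple[int, int]
    color: str = "red"
    fps: int = 30

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if len(self.centers) < 2:
            raise ValueError("need at least 2 frames")
        if self.amplitude_mm <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class VideoConfig:
    frame_height: int = 160
    frame_width: int = 240
    blob_radius_px: float = 6.0
    background: tuple[int, int, int] = (60, 60, 60)
    red: tuple[int, int, int] = (220, 40, 40)
    blue: tuple[int, int, int] = (40, 40, 220)
    noise_sd: float = 0.0


def minimum_jerk(start, end, n_steps: int) -> np.ndarray:
    """Positions along a straight minimum-jerk reach, ``n_steps + 1`` points."""
    tau = np.linspace(0.0, 1.0, n_steps + 1)
    s = 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    return start + np.outer(s, end - start)


def make_pointing_truth(start, end, move_frames: int = 24, rest_frames: int = 8,
                        px_per_mm: float = 2.0, color: str = "red",
                        out_and_back: bool = True, fps: int = 30) -> VideoTruth:
    """Programmed pointing gesture: rest, minimum-jerk outward stroke, rest,
    and optionally the return stroke plus final rest."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    out = minimum_jerk(start, end, move_frames)
    parts = [np.repeat([start], rest_frames, axis=0), out,
             np.repeat([end], rest_frames - 1, axis=0)]
    stroke = (rest_frames, rest_frames + move_frames)
    if out_and_back:
        parts.append(minimum_jerk(end, start, move_frames))
        parts.append(np.repeat([start], rest_frames - 1, axis=0))
    centers = np.vstack(parts)
    amp_px = float(np.linalg.norm(end - start))
    path_px = float(np.sum(np.linalg.norm(np.diff(out, axis=0), axis=1)))
    duration_ms = move_frames * 1000.0 / fps
    return VideoTruth(centers=centers, px_per_mm=px_per_mm,
                      amplitude_mm=amp_px / px_per_mm,
                      mean_velocity_mm_ms=(path_px / px_per_mm) / duration_ms,
                      stroke=stroke, color=color, fps=fps)


def render_gesture_video(truth: VideoTruth, config: VideoConfig | None = None,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Render frames (uint8, shape ``(n, H, W, 3)``) with one colored disc at
    each programmed center, plus optional Gaussian pixel noise."""
    config = config or VideoConfig()
    h, w = config.frame_height, config.frame_width
    r = config.blob_radius_px
    blob_rgb = {"red": config.red, "blue": config.blue}[truth.color]
    frames = np.empty((len(truth.centers), h, w, 3), dtype=np.uint8)
    frames[...] = np.asarray(config.background, dtype=np.uint8)
    for i, (cx, cy) in enumerate(truth.centers):
        if not (np.isfinite(cx) and np.isfinite(cy)):
            continue
        if not (r <= cx <= w - 1 - r and r <= cy <= h - 1 - r):
            raise ValueError(f"blob center {(cx, cy)} outside frame bounds")
        rr, cc = _disk((cy, cx), r, shape=(h, w))
        frames[i, rr, cc] = blob_rgb
    if config.noise_sd > 0:
        rng = rng or np.random.default_rng()
        noisy = frames.astype(float) + rng.normal(0, config.noise_sd, frames.shape)
        frames = np.clip(noisy, 0, 255).astype(np.uint8)
    return frames


def write_frames(frames: np.ndarray, outdir) -> None:
    """Write frames as a PNG sequence (frame_0000.png, ...)."""
    import imageio.v3 as iio
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(outdir / f"frame_{i:04d}.png", frame)


def read_frames(src) -> np.ndarray:
    """Read a PNG frame directory (sorted) or a video container into an
    ``(n, H, W, 3)`` uint8 array."""
    import imageio.v3 as iio
    from pathlib import Path
    src = Path(src)
    if src.is_dir():
        files = sorted(src.glob("*.png"))
        if not files:
            raise ValueError(f"no PNG frames in {src}")
        return np.stack([iio.imread(f) for f in files])
    return np.asarray(iio.imread(src))
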