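"""Reproducibility studies: end-to-end checks the package runs on itself.

Each function generates fresh synthetic data from a seed, runs the relevant
part of the pipeline, and returns a summary number: selector ground-truth
agreement, mixed-model parameter recovery, likelihood-ratio type-I
calibration, and trajectory-kinematics recovery. They are the computations
behind ``scripts/acceptance.py`` and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import selection as sel
from . import stats as st
from . import synthetic as syn
from . import trajectory as tj
from .pipeline import PipelineConfig, simulate_trajectory_stage, validate_selection


def _sub_seed(seed: int, k: int) -> int:
    return (int(seed) * 10_007 + k) % (2 ** 31 - 1)


def selector_agreement_study(seed: int, n_per_group: int = 24,
                             n_blocks: int = 4, trials_per_block: int = 30):
    """Full-cohort ground-truth recovery: parse and select every generated
    gaze stream and score label agreement. Returns (accuracy, n_trials)."""
    cfg = syn.CohortConfig(seed=_sub_seed(seed, 1), n_per_group=n_per_group,
                           n_blocks=n_blocks, trials_per_block=trials_per_block)
    truths: list[dict] = []

    def tee():
        for key, truth, stream in syn.iter_trial_streams(cfg):
            truths.append(truth)
            yield key, truth, stream

    selections = sel.select_cohort(tee(), cfg.roi_map, cfg.parser)
    truth = pd.DataFrame(truths)
    _, accuracy = validate_selection(selections, truth)
    return accuracy, len(truth)


def _delay_long_table(cfg: syn.CohortConfig) -> pd.DataFrame:
    tab = syn.simulate_delay_table(cfg)
    d = tab[tab["exclusion_label"] == "none"].copy()
    d["delay_ms"] = d["true_delay"].astype(float)
    d["group"] = pd.Categorical(d["group"], categories=["TD", "ASD"])
    return d


def beta_recovery_study(seed: int, n_cohorts: int = 50) -> tuple[float, list[float]]:
    """Fit the group LMM on repeated paper-scale cohorts (24 per group,
    4 blocks x 30 trials, generator shift 55 ms) and return the mean and
    per-cohort group-coefficient estimates (ms).

    The generator places no block/side variance, so the random-intercept
    model is the generating model and is used for the repeated fits.
    """
    betas = []
    for k in range(n_cohorts):
        cfg = syn.CohortConfig(seed=_sub_seed(seed, 100 + k))
        d = _delay_long_table(cfg)
        spec = st.ModelSpec("delay_ms", ("block", "side", "group"))
        fit = st.fit_model(spec, d)
        betas.append(fit.coef("group"))
    return float(np.mean(betas)), betas


def null_lrt_calibration(seed: int, n_reps: int = 200, alpha: float = 0.05,
                         n_per_group: int = 24, n_blocks: int = 2,
                         trials_per_block: int = 10) -> float:
    """Type-I rate of the group LRT on null cohorts (no group shift, equal
    within-subject SDs). Returns the rejection rate at ``alpha``."""
    rej = 0
    for k in range(n_reps):
        cfg = syn.CohortConfig(seed=_sub_seed(seed, 10_000 + k),
                               group_delay_shift=0.0,
                               within_subject_sd_asd=81.0,
                               n_blocks=n_blocks,
                               trials_per_block=trials_per_block,
                               n_per_group=n_per_group,
                               exclusion_rate=0.0)
        d = _delay_long_table(cfg)
        spec0 = st.ModelSpec("delay_ms", ("block", "side"))
        _, _, lr = st.group_term_test(spec0, d)
        rej += lr.p < alpha
    return rej / n_reps


def trajectory_recovery_study(seed: int, n_gestures: int = 20):
    """Render noise-free pointing gestures over a grid of amplitudes and
    stroke durations and measure worst-case recovery error. Returns
    (max amplitude error %, max mean-velocity error %)."""
    rng = np.random.default_rng(_sub_seed(seed, 2))
    worst_amp = worst_vel = 0.0
    for _ in range(n_gestures):
        amp_px = float(rng.uniform(85, 155))
        mf = int(rng.integers(18, 28))
        y0 = float(rng.uniform(60, 100))
        truth = syn.make_pointing_truth((30.0, y0), (30.0 + amp_px, y0 - 5.0),
                                        move_frames=mf, px_per_mm=2.0,
                                        out_and_back=False)
        k = tj.analyze_video(syn.render_gesture_video(truth), "red", 2.0)[0]
        worst_amp = max(worst_amp, 100 * abs(k.amplitude_mm - truth.amplitude_mm)
                        / truth.amplitude_mm)
        worst_vel = max(worst_vel, 100 * abs(k.mean_velocity_mm_ms
                                             - truth.mean_velocity_mm_ms)
                        / truth.mean_velocity_mm_ms)
    return worst_amp, worst_vel


def trajectory_type1_study(seed: int, n_reps: int = 30, alpha: float = 0.05,
                           n_per_group: int = 6,
                           trials_per_subject: int = 3) -> float:
    """Render both groups from identical kinematic distributions, fit the
    amplitude LMM, and return the group-LRT rejection rate (nominal 5%)."""
    rej = 0
    for k in range(n_reps):
        cfg = PipelineConfig(
            out_dir="unused", seed=_sub_seed(seed, 20_000 + k),
            cohort=syn.CohortConfig(n_per_group=n_per_group, n_blocks=1,
                                    trials_per_block=4),
            trajectory_trials_per_subject=trials_per_subject)
        kin = simulate_trajectory_stage(cfg)
        kin["group"] = pd.Categorical(kin["group"], categories=["TD", "ASD"])
        _, _, lr = st.group_term_test(st.ModelSpec("amplitude_mm"), kin)
        rej += lr.p < alpha
    return rej / n_reps


def table_statistics() -> dict[str, float]:
    """Worked examples recomputable from printed group summaries: screening
    battery t statistics and the delay effect size."""
    age_t, _ = st.t_from_summary(40.84, 12.12, 24, 37.05, 12.66, 24)
    eq_t, eq_df = st.t_from_summary(11.96, 5.38, 24, 47.96, 10.79, 23,
                                    equal_var=False)
    _, aq_df = st.t_from_summary(41.50, 3.81, 24, 14.61, 5.87, 23,
                                 equal_var=False)
    iq_t, _ = st.t_from_summary(114.38, 16.48, 24, 108.50, 13.07, 24)
    piq_t, _ = st.t_from_summary(110.67, 17.65, 24, 102.38, 13.66, 24)
    return {
        "delay_cohens_d": abs(st.cohens_d(264.05, 103.13, 24,
                                          206.02, 59.45, 24)),
        "age_t": age_t,
        "age_d": st.cohens_d(40.84, 12.12, 24, 37.05, 12.66, 24),
        "eq_welch_t": eq_t,
        "eq_welch_df": eq_df,
        "aq_welch_df": aq_df,
        "iq_t": iq_t,
        "piq_t": piq_t,
    }
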