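"""Delay records, aggregation, extreme-value fences, channel coding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from iapsync.delays import (aggregate, code_channels, compute_delays,
                            flag_extremes, COMBO_FLAGS, COUNT_FLAGS)


def _sel(rows):
    return pd.DataFrame(rows, columns=["subject", "block", "trial", "status",
                                       "exclusion_code", "onset", "offset",
                                       "pathway", "saccade_latency"])


def _trials(rows):
    return pd.DataFrame(rows, columns=["subject", "group", "block", "trial",
                                       "side", "stim_onset_ms",
                                       "gesture_onset_ms"])


class TestComputeDelays:
    def test_subtraction_and_boundary(self):
        sel = _sel([("s1", 1, 2, "selected", "", 500, 540, "direct", 180),
                    ("s1", 1, 3, "selected", "", 700, 740, "direct", 150),
                    ("s1", 1, 4, "excluded", "no_comm_shift", np.nan, np.nan,
                     "", np.nan)])
        tr = _trials([("s1", "TD", 1, 2, "left", 0, 750),
                      ("s1", "TD", 1, 3, "left", 0, 700),
                      ("s1", "TD", 1, 4, "left", 0, 900)])
        out = compute_delays(sel, tr)
        assert list(out["delay"]) == [250, 0]  # excluded trial dropped

    def test_missing_gesture_dropped_with_log(self, caplog):
        sel = _sel([("s1", 1, 2, "selected", "", 500, 540, "direct", 180)])
        tr = _trials([("s1", "TD", 1, 2, "left", 0, np.nan)])
        with caplog.at_level("WARNING"):
            out = compute_delays(sel, tr)
        assert out.empty and "without a gesture onset" in caplog.text

    def test_cohort_delays_equal_truth_exactly_noise_free(self):
        """On a noise-free cohort the measured delays reproduce the
        generator's programmed delays sample-exactly."""
        from iapsync.synthetic import CohortConfig, iter_trial_streams
        from iapsync.selection import select_cohort
        cfg = CohortConfig(seed=31, n_per_group=2, n_blocks=1,
                           trials_per_block=10, position_noise_px=0.0)
        truths = []
        sels = select_cohort(_tee(iter_trial_streams(cfg), truths),
                             cfg.roi_map, cfg.parser)
        truth = pd.DataFrame(truths)
        out = compute_delays(sels, truth)
        merged = out.merge(truth, on=["subject", "block", "trial"])
        assert len(merged) > 0
        assert (merged["delay"] == merged["true_delay"]).all()


def _tee(it, sink):
    for key, truth, stream in it:
        sink.append(truth)
        yield key, truth, stream


class TestAggregate:
    def test_closed_form_cell_sd(self):
        rec = pd.DataFrame({"subject": ["s1"] * 2, "group": ["TD"] * 2,
                            "block": [1, 1], "side": ["left"] * 2,
                            "trial": [2, 3], "delay": [200, 220]})
        out = aggregate(rec, "sd")
        assert out["sd_delay"].iloc[0] == pytest.approx(14.142, abs=1e-3)

    def test_single_observation_cells_omitted(self):
        rec = pd.DataFrame({"subject": ["s1", "s1", "s1"], "group": ["TD"] * 3,
                            "block": [1, 1, 2], "side": ["left"] * 3,
                            "trial": [2, 3, 2], "delay": [200, 220, 300]})
        out = aggregate(rec, "sd")
        assert len(out) == 1 and (out["n_obs"] >= 2).all()

    def test_permutation_invariance(self, rng):
        rec = pd.DataFrame({
            "subject": rng.choice(["a", "b", "c"], 60),
            "group": "TD", "block": rng.choice([1, 2], 60),
            "side": rng.choice(["left", "right"], 60),
            "trial": np.arange(60), "delay": rng.integers(100, 400, 60)})
        shuffled = rec.sample(frac=1, random_state=3).reset_index(drop=True)
        for level in ("subject", "sd"):
            a = aggregate(rec, level).sort_values(
                [c for c in ("subject", "block", "side") if c in
                 aggregate(rec, level)]).reset_index(drop=True)
            b = aggregate(shuffled, level).sort_values(
                [c for c in ("subject", "block", "side") if c in
                 aggregate(shuffled, level)]).reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)

    def test_matches_brute_force_groupby_oracle(self, rng):
        n = 1000
        rec = pd.DataFrame({
            "subject": rng.choice([f"s{i}" for i in range(10)], n),
            "group": "TD", "block": rng.choice([1, 2, 3, 4], n),
            "side": rng.choice(["left", "right"], n),
            "trial": np.arange(n), "delay": rng.integers(50, 500, n)})
        means = aggregate(rec, "subject")
        for row in means.itertuples(index=False):
            vals = [r.delay for r in rec.itertuples(index=False)
                    if r.subject == row.subject]
            assert row.mean_delay == pytest.approx(sum(vals) / len(vals))
        sds = aggregate(rec, "sd")
        for row in sds.sample(20, random_state=0).itertuples(index=False):
            vals = np.array([r.delay for r in rec.itertuples(index=False)
                             if (r.subject, r.block, r.side)
                             == (row.subject, row.block, row.side)])
            m = vals.mean()
            sd = np.sqrt(((vals - m) ** 2).sum() / (len(vals) - 1))
            assert row.sd_delay == pytest.approx(sd)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate(pd.DataFrame(columns=["subject", "delay"]), "subject")


class TestFlagExtremes:
    def test_hand_computed_fences(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 1000], dtype=float)
        # Q1 = 3, Q3 = 7 (linear interpolation), IQR = 4 -> fences [-9, 19]
        mask = flag_extremes(vals, np.repeat("g", 9))
        assert mask.tolist() == [False] * 8 + [True]

    def test_degenerate_all_equal(self):
        mask = flag_extremes(np.full(10, 5.0), np.repeat("g", 10))
        assert not mask.any()

    def test_fences_computed_per_group(self):
        vals = np.r_[np.arange(8, dtype=float), 1000.0,
                     np.arange(990, 1010, dtype=float)]
        labels = np.r_[np.repeat("a", 9), np.repeat("b", 20)]
        mask = flag_extremes(vals, labels)
        assert mask[8] and not mask[9:].any()

    @given(hst.integers(-1000, 1000))
    @settings(max_examples=25, deadline=None)
    def test_translation_equivariance(self, shift):
        r = np.random.default_rng(4)
        vals = r.normal(size=40) * 10
        labels = np.repeat(["a", "b"], 20)
        base = flag_extremes(vals, labels)
        moved = flag_extremes(vals + shift, labels)
        assert (base == moved).all()

    def test_small_group_warns_and_skips(self, caplog):
        with caplog.at_level("WARNING"):
            mask = flag_extremes([1.0, 2.0, 3.0], ["g"] * 3)
        assert not mask.any() and "skipping" in caplog.text


def _ann(rows):
    return pd.DataFrame(rows, columns=["subject", "block", "trial", "verbal",
                                       "gesture"])


class TestCodeChannels:
    def test_gaze_and_gesture_combination(self):
        sel = _sel([("s1", 1, 2, "selected", "", 500, 540, "direct", 180)])
        out = code_channels(_ann([("s1", 1, 2, 0, 1)]), sel)
        row = out.iloc[0]
        assert row["gaze_and_gesture"] == 1 and row["bimodal"] == 1
        others = [f for f in COMBO_FLAGS if f != "gaze_and_gesture"]
        assert row[others].sum() == 0

    def test_trimodal_clears_pairwise_flags(self):
        sel = _sel([("s1", 1, 2, "selected", "", 500, 540, "direct", 180)])
        out = code_channels(_ann([("s1", 1, 2, 1, 1)]), sel)
        row = out.iloc[0]
        assert row["trimodal"] == 1 and row[COMBO_FLAGS].sum() == 0

    def test_dismissed_trials_code_gaze_zero(self):
        sel = _sel([("s1", 1, 2, "excluded", "no_comm_shift", np.nan, np.nan,
                     "", np.nan)])
        out = code_channels(_ann([("s1", 1, 2, 1, 0)]), sel)
        assert out["gaze"].iloc[0] == 0 and out["verbal_only"].iloc[0] == 1

    def test_first_trials_removed(self):
        sel = _sel([("s1", 1, 1, "excluded", "first_trial", np.nan, np.nan,
                     "", np.nan),
                    ("s1", 1, 2, "selected", "", 500, 540, "direct", 180)])
        out = code_channels(_ann([("s1", 1, 1, 1, 1), ("s1", 1, 2, 0, 0)]), sel)
        assert list(out["trial"]) == [2]

    def test_flag_sums_match_counting_oracle(self, rng):
        n = 300
        sel = _sel([(f"s{i % 5}", 1, i % 28 + 2,
                     "selected" if rng.random() < 0.7 else "excluded",
                     "" if True else "", 500, 540, "direct", 180)
                    for i in range(n)])
        ann = _ann([(s, b, t, int(rng.random() < 0.5), int(rng.random() < 0.5))
                    for s, b, t in sel[["subject", "block", "trial"]]
                    .itertuples(index=False)])
        sel = sel.drop_duplicates(["subject", "block", "trial"])
        ann = ann.drop_duplicates(["subject", "block", "trial"])
        out = code_channels(ann, sel)
        g, v, ge = out["gaze"], out["verbal"], out["gesture"]
        assert out["gaze_only"].sum() == ((g == 1) & (v == 0) & (ge == 0)).sum()
        assert out["unimodal"].sum() == ((g + v + ge) == 1).sum()
        assert out["bimodal"].sum() == ((g + v + ge) == 2).sum()
        # combination flags exclusive; count flags partition multi-channel rows
        assert (out[COMBO_FLAGS].sum(axis=1) <= 1).all()
        used = (g + v + ge) >= 1
        assert (out.loc[used, COUNT_FLAGS].sum(axis=1) == 1).all()
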