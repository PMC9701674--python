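"""Group-comparison dispatch, effect sizes, LRT machinery, mixed-model fits
(with R lme4 as independent oracle for the likelihoods)."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from iapsync.stats import (FitResult, ModelSpec, adjust_pvalues, cohens_d,
                           compare_groups, detect_separation, fit_model,
                           group_term_test, is_nested, lrt, mann_whitney_r,
                           pearson_cor, t_from_summary, welch_df)


class TestSummaryStatistics:
    """Recomputations from printed group summaries (M, SD, n)."""

    @pytest.mark.parametrize("m1,sd1,n1,m2,sd2,n2,equal_var,t_exp,df_exp", [
        # Age: Student t(46) = 1.06
        (40.84, 12.12, 24, 37.05, 12.66, 24, True, 1.06, 46),
        # EQ: Welch t = -14.38, df = 32.0
        (11.96, 5.38, 24, 47.96, 10.79, 23, False, -14.38, 32.0),
        # AQ: Welch t = 18.55, df = 37.5
        (41.50, 3.81, 24, 14.61, 5.87, 23, False, 18.55, 37.5),
        # IQ: Student t(46) = 1.37
        (114.38, 16.48, 24, 108.50, 13.07, 24, True, 1.37, 46),
        # PIQ: Student t(46) = 1.82
        (110.67, 17.65, 24, 102.38, 13.66, 24, True, 1.82, 46),
    ])
    def test_screening_battery_t_statistics(self, m1, sd1, n1, m2, sd2, n2,
                                            equal_var, t_exp, df_exp):
        t, df = t_from_summary(m1, sd1, n1, m2, sd2, n2, equal_var=equal_var)
        # inputs are printed to 2 decimals; their rounding propagates to
        # about 0.01 on t
        assert t == pytest.approx(t_exp, abs=0.015)
        assert df == pytest.approx(df_exp, abs=0.05)

    def test_age_effect_size(self):
        assert cohens_d(40.84, 12.12, 24, 37.05, 12.66, 24) == \
            pytest.approx(0.31, abs=0.005)

    def test_delay_group_effect_size(self):
        # gaze-gesture delay subject means: d = 0.69 for 24 vs 24
        d = cohens_d(264.05, 103.13, 24, 206.02, 59.45, 24)
        assert abs(d) == pytest.approx(0.69, abs=0.005)

    def test_d_zero_when_means_equal(self):
        assert cohens_d(5.0, 1.0, 10, 5.0, 2.0, 10) == 0.0

    def test_d_antisymmetric_under_group_swap(self):
        d1 = cohens_d(10.0, 2.0, 12, 8.0, 3.0, 12)
        d2 = cohens_d(8.0, 3.0, 12, 10.0, 2.0, 12)
        assert d1 == pytest.approx(-d2)

    def test_welch_df_closed_form_oracle(self, rng):
        for _ in range(50):
            sd1, sd2 = rng.uniform(0.5, 20, 2)
            n1, n2 = rng.integers(4, 80, 2)
            a, b = sd1 ** 2 / n1, sd2 ** 2 / n2
            expected = (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))
            assert welch_df(sd1, n1, sd2, n2) == pytest.approx(expected)


class TestCompareGroups:
    def test_identical_groups_null(self, rng):
        x = rng.normal(10, 2, 30)
        res = compare_groups(x, x.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.effect == pytest.approx(0.0, abs=1e-12)

    def test_non_normal_data_dispatches_mann_whitney(self, rng):
        x = rng.exponential(1.0, 40)
        y = rng.exponential(2.0, 40)
        res = compare_groups(x, y)
        assert res.test == "mann_whitney" and res.effect_name == "r"
        u, z, r = mann_whitney_r(x, y)
        assert res.effect == pytest.approx(r)
        assert 0 <= r <= 1

    def test_heteroscedastic_normal_dispatches_welch(self):
        r = np.random.default_rng(11)
        x = r.normal(0, 1, 60)
        y = r.normal(0.2, 5, 60)
        res = compare_groups(x, y)
        assert res.test == "welch_t"

    def test_wellbehaved_normal_dispatches_student(self):
        r = np.random.default_rng(12)
        x = r.normal(0, 1, 40)
        y = r.normal(0.3, 1, 40)
        res = compare_groups(x, y)
        assert res.test == "student_t" and res.df == 78

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [3.0, 4.0])


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        r, ci, p = pearson_cor(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_definition_oracle(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r, _, _ = pearson_cor(x, y)
        expected = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(expected)

    def test_null_simulation_small_r(self):
        hits = 0
        for s in range(100):
            r_ = np.random.default_rng(s)
            r, _, _ = pearson_cor(r_.normal(size=100), r_.normal(size=100))
            hits += abs(r) < 0.3
        assert hits >= 95

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r, (lo, hi), _ = pearson_cor(x, y)
        assert lo < r < hi

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_cor(np.ones(10), np.arange(10.0))


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_stay_equal(self):
        out = adjust_pvalues([0.04] * 6)
        assert np.allclose(out, out[0])

    def test_matches_step_up_oracle(self, rng):
        for _ in range(20):
            ps = rng.uniform(0, 1, rng.integers(2, 15))
            got = adjust_pvalues(ps, "bh")
            m = len(ps)
            order = np.argsort(ps)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, ps[i] * m / rank)
                adj[i] = running
            assert np.allclose(got, adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])


def _sim_lmm(seed, n_sub=24, n_trial=40, beta=55.0, sd_sub=50.0, sd_res=80.0,
             shift=True):
    r = np.random.default_rng(seed)
    rows = []
    for g, grp in enumerate(("TD", "ASD")):
        for i in range(n_sub):
            u = r.normal(0, sd_sub)
            mu = 206.0 + (beta if (grp == "ASD" and shift) else 0.0) + u
            for t in range(n_trial):
                rows.append({"subject": f"{grp}{i}", "group": grp,
                             "block": t % 4 + 1,
                             "side": "left" if t % 2 else "right",
                             "delay_ms": mu + r.normal(0, sd_res)})
    d = pd.DataFrame(rows)
    d["group"] = pd.Categorical(d["group"], categories=["TD", "ASD"])
    return d


class TestMixedModels:
    def test_lrt_identical_fits(self):
        spec = ModelSpec("y", ())
        a = FitResult(spec=spec, params=pd.DataFrame(), llf=-100.0, n_params=3,
                      converged=True, n_obs=50)
        b = FitResult(spec=spec.with_term("group"), params=pd.DataFrame(),
                      llf=-100.0, n_params=4, converged=True, n_obs=50)
        res = lrt(a, b)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_lrt_statistic_definition(self):
        spec = ModelSpec("y", ())
        a = FitResult(spec=spec, params=pd.DataFrame(), llf=-105.3, n_params=3,
                      converged=True, n_obs=50)
        b = FitResult(spec=spec.with_term("group"), params=pd.DataFrame(),
                      llf=-101.1, n_params=4, converged=True, n_obs=50)
        assert lrt(a, b).statistic == pytest.approx(2 * (105.3 - 101.1))

    def test_lrt_rejects_non_nested(self):
        s1 = ModelSpec("y", ("a",))
        s2 = ModelSpec("y", ("b",))
        f1 = FitResult(spec=s1, params=pd.DataFrame(), llf=-1, n_params=3,
                       converged=True, n_obs=10)
        f2 = FitResult(spec=s2, params=pd.DataFrame(), llf=-1, n_params=3,
                       converged=True, n_obs=10)
        with pytest.raises(ValueError):
            lrt(f1, f2)

    def test_nesting_predicate(self):
        base = ModelSpec("y", ("block",))
        assert is_nested(base, base.with_term("group"))
        assert not is_nested(base.with_term("group"), base)

    def test_zero_group_variance_matches_ols(self):
        """With identical subjects the mixed model's fixed estimates collapse
        to ordinary least squares."""
        r = np.random.default_rng(8)
        d = pd.DataFrame({
            "subject": np.repeat([f"s{i}" for i in range(20)], 10),
            "x": r.normal(size=200)})
        d["y"] = 2.0 + 1.5 * d["x"] + r.normal(0, 1, 200)  # no subject effect
        fit = fit_model(ModelSpec("y", ("x",)), d)
        import statsmodels.formula.api as smf
        ols = smf.ols("y ~ x", d).fit()
        assert fit.coef("x") == pytest.approx(ols.params["x"], abs=0.01)

    def test_parameter_recovery_ci_coverage(self):
        """A random-intercept generator (sigma_subject 50, sigma_resid 80,
        group shift 55 ms) is recovered: the Wald 95% CI covers the true
        shift in at least 34 of 40 seeded replicates."""
        cover = 0
        for s in range(40):
            d = _sim_lmm(s, n_trial=20)
            fit = fit_model(ModelSpec("delay_ms", ("group",)), d)
            row = fit.params[fit.params["term"].str.startswith("group")].iloc[0]
            cover += row["ci_low"] <= 55.0 <= row["ci_high"]
        assert cover >= 34

    def test_group_term_test_detects_shift(self):
        d = _sim_lmm(123, n_trial=30)
        _, alt, lr = group_term_test(ModelSpec("delay_ms", ("block", "side")), d)
        assert lr.df == 1 and lr.p < 0.01
        # one cohort's sampling SE for the group contrast is
        # sd_sub * sqrt(2/24) ~ 14.4 ms; allow a bit over 3 SE
        assert alt.coef("group") == pytest.approx(55.0, abs=46.0)

    def test_random_slopes_fallback_is_flagged(self):
        # two observations per subject cannot support slopes for two factors
        r = np.random.default_rng(3)
        d = pd.DataFrame({
            "subject": np.repeat([f"s{i}" for i in range(12)], 2),
            "block": [1, 2] * 12, "side": ["left", "right"] * 12,
            "y": r.normal(size=24)})
        fit = fit_model(ModelSpec("y", ("block",), ("block", "side")), d)
        assert fit.fallback and fit.converged


class TestBinomialGlmm:
    def test_separation_detection(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        X = pd.DataFrame({"Intercept": 1.0, "g": [0, 0, 0, 1, 1, 1]})
        assert detect_separation(y, X)
        X2 = pd.DataFrame({"Intercept": 1.0, "g": [0, 1, 0, 1, 0, 1]})
        assert not detect_separation(np.array([0, 1, 1, 1, 0, 0]), X2)

    def test_perfectly_separated_outcome_flags_fit(self):
        r = np.random.default_rng(4)
        d = pd.DataFrame({
            "subject": np.repeat([f"s{i}" for i in range(12)], 10),
            "group": np.repeat(["ASD"] * 6 + ["TD"] * 6, 10)})
        d["y"] = np.where(d["group"] == "TD",
                          (r.random(len(d)) < 0.4).astype(int), 0)
        fit = fit_model(ModelSpec("y", ("group",), family="binomial"), d)
        assert fit.separation

    def test_rejects_random_slopes(self):
        with pytest.raises(ValueError):
            fit_model(ModelSpec("y", ("g",), ("g",), family="binomial"),
                      pd.DataFrame({"y": [0, 1], "g": [0, 1],
                                    "subject": ["a", "b"]}))


def _simulate_binary(seed=3, n_sub=24, n_tr=20):
    r = np.random.default_rng(seed)
    rows = []
    for i in range(n_sub):
        u = r.normal(0, 1.0)
        grp = "ASD" if i < n_sub // 2 else "TD"
        eta = -0.5 + (0.8 if grp == "ASD" else 0.0) + u
        p = 1 / (1 + np.exp(-eta))
        for _ in range(n_tr):
            rows.append({"subject": f"s{i:02d}", "group": grp,
                         "y": int(r.random() < p)})
    return pd.DataFrame(rows)


def _run_r(script: str) -> str:
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    return out.stdout


class TestAgainstLme4:
    """Independent oracle: R lme4 refits the same models by ML."""

    def test_lmm_loglik_and_beta_match_lmer(self, tmp_path):
        d = _sim_lmm(21, n_sub=10, n_trial=12)
        p = tmp_path / "lmm.csv"
        d.to_csv(p, index=False)
        out = _run_r(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{p}")
            d$group <- relevel(factor(d$group), ref = "TD")
            m <- lmer(delay_ms ~ group + (1|subject), data = d, REML = FALSE)
            cat(as.numeric(logLik(m)), fixef(m)["groupASD"], "\\n")
        """))
        r_llf, r_beta = map(float, out.split())
        fit = fit_model(ModelSpec("delay_ms", ("group",)), d)
        assert fit.llf == pytest.approx(r_llf, abs=0.02)
        assert fit.coef("group") == pytest.approx(r_beta, abs=0.05)

    def test_glmm_loglik_and_beta_match_glmer(self, tmp_path):
        d = _simulate_binary()
        d["group"] = pd.Categorical(d["group"], categories=["TD", "ASD"])
        p = tmp_path / "glmm.csv"
        d.to_csv(p, index=False)
        out = _run_r(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{p}")
            d$group <- relevel(factor(d$group), ref = "TD")
            m <- glmer(y ~ group + (1|subject), data = d, family = binomial,
                       nAGQ = 25)
            cat(as.numeric(logLik(m)), fixef(m)["groupASD"], "\\n")
        """))
        r_llf, r_beta = map(float, out.split())
        fit = fit_model(ModelSpec("y", ("group",), family="binomial"), d)
        assert fit.llf == pytest.approx(r_llf, abs=0.02)
        assert fit.coef("group") == pytest.approx(r_beta, abs=0.02)
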