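"""Multilevel-model inference and group-comparison statistics.

The inferential scheme tests a group effect by comparing nested mixed models
fitted by maximum likelihood: a null model with design factors (experimental
block, target side) and a subject-level random-effects structure, against
the same model plus the group factor. Significance comes from the
likelihood-ratio test, 2*(ll_alt - ll_null) against a chi-square whose df is
the parameter-count difference.

Gaussian LMMs delegate to :class:`statsmodels.regression.mixed_linear_model.MixedLM`
with ``reml=False``; when a random-slopes structure fails to converge the
documented fallback refits with random intercepts only (caller-visible via
the ``fallback`` flag and a logged warning). Binomial responses are fitted
by a random-intercept logistic GLMM whose marginal likelihood is evaluated
with Gauss-Hermite quadrature and maximised with scipy; complete separation
of a binary predictor is detected and flagged (inference on that
coefficient is unreliable).

Coefficient p-values and CIs are Wald normal approximations.

Two-sample group comparisons dispatch on the data: Shapiro-Wilk
non-normality in either group leads to a Mann-Whitney test with effect size
r = |Z|/sqrt(N); otherwise a significant Bartlett test leads to Welch's t
(Welch-Satterthwaite df) with Cohen's d; otherwise Student's t with
pooled-SD d. The same statistics can be recomputed from printed summary
statistics (M, SD, n).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats, special
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# model specification and fitting

@dataclass(frozen=True)
class ModelSpec:
    """A mixed-model specification.

    ``fixed`` lists fixed-effect terms (formula fragments); ``random_slopes``
    lists terms given subject-level random slopes in addition to the random
    intercept; ``family`` is ``gaussian`` or ``binomial`` (binomial supports
    random intercepts only). Estimation is always maximum likelihood.
    """

    response: str
    fixed: tuple[str, ...] = ()
    random_slopes: tuple[str, ...] = ()
    groups: str = "subject"
    family: str = "gaussian"

    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"

    def with_term(self, term: str) -> "ModelSpec":
        return ModelSpec(self.response, self.fixed + (term,),
                         self.random_slopes, self.groups, self.family)


def is_nested(null: ModelSpec, alt: ModelSpec) -> bool:
    return (null.response == alt.response and null.family == alt.family
            and null.groups == alt.groups
            and null.random_slopes == alt.random_slopes
            and set(null.fixed) < set(alt.fixed))


@dataclass
class FitResult:
    """A maximum-likelihood mixed-model fit.

    ``params`` has one row per fixed coefficient: term, estimate, ci_low,
    ci_high, p (Wald normal approximation). ``n_params`` counts all free
    parameters (fixed + variance components) for LRT df bookkeeping.
    """

    spec: ModelSpec
    params: pd.DataFrame
    llf: float
    n_params: int
    converged: bool
    fallback: bool = False
    separation: bool = False
    n_obs: int = 0
    raw: object = field(default=None, repr=False)

    def coef(self, term: str) -> float:
        row = self.params.loc[self.params["term"] == term]
        if row.empty:
            matches = self.params["term"].str.startswith(term)
            row = self.params.loc[matches]
        if row.empty:
            raise KeyError(term)
        return float(row["estimate"].iloc[0])


def fit_model(spec: ModelSpec, data: pd.DataFrame,
              allow_fallback: bool = True) -> FitResult:
    """Fit ``spec`` to long-format data (one row per measurement) by ML."""
    if spec.family == "gaussian":
        return _fit_lmm(spec, data, allow_fallback)
    if spec.family == "binomial":
        if spec.random_slopes:
            raise ValueError("binomial models support random intercepts only")
        return _fit_glmm_logit(spec, data)
    raise ValueError(f"unknown family {spec.family!r}")


def _fit_lmm(spec: ModelSpec, data: pd.DataFrame, allow_fallback: bool) -> FitResult:
    re_formula = "~" + " + ".join(spec.random_slopes) if spec.random_slopes else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)  # singular RE covariance
        model = MixedLM.from_formula(spec.formula(), data=data,
                                     groups=data[spec.groups],
                                     re_formula=re_formula)
        try:
            result = model.fit(reml=False)
        except np.linalg.LinAlgError:
            result = None
    converged = (result is not None and bool(result.converged)
                 and np.isfinite(result.llf))
    if not converged and spec.random_slopes and allow_fallback:
        logger.warning("random-slopes LMM for %s failed to converge; "
                       "refitting with random intercepts only", spec.response)
        fb_spec = ModelSpec(spec.response, spec.fixed, (), spec.groups, spec.family)
        fb = _fit_lmm(fb_spec, data, allow_fallback=False)
        fb.fallback = True
        return fb
    if result is None:
        raise RuntimeError(f"LMM for {spec.response!r} could not be fitted "
                           "(singular design)")
    k_fe = len(result.fe_params)
    ci = result.conf_int()
    rows = []
    for i, term in enumerate(result.fe_params.index):
        rows.append({"term": term, "estimate": float(result.fe_params.iloc[i]),
                     "ci_low": float(ci.iloc[i, 0]), "ci_high": float(ci.iloc[i, 1]),
                     "p": float(result.pvalues.iloc[i])})
    # free parameters: fixed effects + residual variance + random-effect
    # covariance entries actually estimated
    n_params = k_fe + 1 + model.k_re2 if hasattr(model, "k_re2") else k_fe + 1
    return FitResult(spec=spec, params=pd.DataFrame(rows), llf=float(result.llf),
                     n_params=int(n_params), converged=converged,
                     n_obs=int(result.nobs), raw=result)


def _design(spec: ModelSpec, data: pd.DataFrame):
    import patsy
    y, X = patsy.dmatrices(spec.formula(), data, return_type="dataframe")
    return np.asarray(y).ravel(), X


def detect_separation(y: np.ndarray, X: pd.DataFrame) -> bool:
    """True if some binary non-intercept column perfectly predicts the
    outcome within one of its levels (complete/quasi-complete separation)."""
    for col in X.columns:
        v = X[col].to_numpy()
        if col == "Intercept" or len(np.unique(v)) != 2:
            continue
        for level in np.unique(v):
            yy = y[v == level]
            if len(yy) > 0 and (yy.min() == yy.max()):
                return True
    return False


def _fit_glmm_logit(spec: ModelSpec, data: pd.DataFrame,
                    n_quad: int = 25) -> FitResult:
    """Random-intercept logistic GLMM by Gauss-Hermite quadrature ML."""
    y, Xdf = _design(spec, data)
    X = np.asarray(Xdf, dtype=float)
    groups, gidx = np.unique(np.asarray(data[spec.groups]), return_inverse=True)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    z = np.sqrt(2.0) * nodes
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    separation = detect_separation(y, Xdf)
    if separation:
        logger.warning("complete separation detected for %s: ML estimates "
                       "for the separating coefficient are unreliable",
                       spec.response)

    def negll(theta):
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta = X @ beta  # (n,)
        # per-observation loglik at each node: (n, K)
        lp = eta[:, None] + sigma * z[None, :]
        ll_obs = y[:, None] * lp - np.logaddexp(0.0, lp)
        # sum within subjects -> (G, K)
        ll_grp = np.zeros((len(groups), len(z)))
        np.add.at(ll_grp, gidx, ll_obs)
        return -float(np.sum(special.logsumexp(ll_grp + logw[None, :], axis=1)))

    theta0 = np.zeros(X.shape[1] + 1)
    res = optimize.minimize(negll, theta0, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    beta = res.x[:-1]
    llf = -float(res.fun)
    # Wald SEs from the numerical Hessian inverse (BFGS approximation)
    try:
        cov = res.hess_inv if isinstance(res.hess_inv, np.ndarray) else None
        se = np.sqrt(np.clip(np.diag(cov)[:-1], 0, np.inf)) if cov is not None else \
            np.full_like(beta, np.nan)
    except Exception:  # pragma: no cover
        se = np.full_like(beta, np.nan)
    zval = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(zval))
    rows = [{"term": t, "estimate": float(b),
             "ci_low": float(b - 1.959963984540054 * s),
             "ci_high": float(b + 1.959963984540054 * s), "p": float(pv)}
            for t, b, s, pv in zip(Xdf.columns, beta, se, p)]
    return FitResult(spec=spec, params=pd.DataFrame(rows), llf=llf,
                     n_params=len(res.x), converged=bool(res.success),
                     separation=separation, n_obs=len(y), raw=res)


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float


def lrt(null_fit: FitResult, alt_fit: FitResult) -> LRTResult:
    """Likelihood-ratio test of nested ML fits on the same data."""
    if null_fit.n_obs != alt_fit.n_obs:
        raise ValueError("fits use different numbers of observations")
    if not is_nested(null_fit.spec, alt_fit.spec):
        raise ValueError("specs are not nested")
    df = alt_fit.n_params - null_fit.n_params
    if df <= 0:
        raise ValueError("alternative model adds no parameters")
    statistic = 2.0 * (alt_fit.llf - null_fit.llf)
    if statistic < 0:
        if statistic < -1e-6:
            logger.warning("negative LRT statistic %.3g (convergence noise); "
                           "clipping to 0", statistic)
        statistic = 0.0
    return LRTResult(statistic=float(statistic), df=int(df),
                     p=float(stats.chi2.sf(statistic, df)))


def group_term_test(spec_null: ModelSpec, data: pd.DataFrame,
                    term: str = "group") -> tuple[FitResult, FitResult, LRTResult]:
    """Convenience: fit the null spec and the spec + ``term``, return both
    fits and their LRT. The fallback structure, if triggered on either
    model, is applied to both so the comparison stays nested."""
    null_fit = fit_model(spec_null, data)
    alt_spec = spec_null.with_term(term)
    if null_fit.fallback:
        alt_spec = ModelSpec(alt_spec.response, alt_spec.fixed, (),
                             alt_spec.groups, alt_spec.family)
    alt_fit = fit_model(alt_spec, data)
    if alt_fit.fallback and not null_fit.fallback:
        null_fit = fit_model(ModelSpec(spec_null.response, spec_null.fixed, (),
                                       spec_null.groups, spec_null.family), data)
    return null_fit, alt_fit, lrt(null_fit, alt_fit)


# --------------------------------------------------------------------------
# two-sample comparisons and effect sizes

@dataclass(frozen=True)
class GroupComparison:
    test: str  # student_t | welch_t | mann_whitney
    statistic: float
    df: float | None
    p: float
    effect_name: str  # d | r
    effect: float


def welch_df(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """Welch-Satterthwaite effective degrees of freedom."""
    a, b = sd1 ** 2 / n1, sd2 ** 2 / n2
    return (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))


def cohens_d(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int,
             variant: str = "pooled") -> float:
    """Cohen's d with a pooled SD; for equal group sizes the pooled SD
    reduces to sqrt((sd1^2 + sd2^2) / 2)."""
    if min(n1, n2) <= 1:
        raise ValueError("group sizes must exceed 1")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    if variant != "pooled":
        raise ValueError(f"unknown variant {variant!r}")
    sp = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    return float((m1 - m2) / sp)


def t_from_summary(m1: float, sd1: float, n1: int, m2: float, sd2: float,
                   n2: int, equal_var: bool = True) -> tuple[float, float]:
    """(t, df) recomputed from printed group summaries."""
    if equal_var:
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        return float(t), float(n1 + n2 - 2)
    t = (m1 - m2) / np.sqrt(sd1 ** 2 / n1 + sd2 ** 2 / n2)
    return float(t), welch_df(sd1, n1, sd2, n2)


def mann_whitney_r(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with normal-approximation Z (tie-corrected) and the
    effect size r = |Z| / sqrt(N)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    allv = np.concatenate([x, y])
    _, counts = np.unique(allv, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    zstat = (u - n1 * n2 / 2.0) / sigma
    return u, float(zstat), float(abs(zstat) / np.sqrt(n))


def compare_groups(x, y, alpha: float = 0.05) -> GroupComparison:
    """Dispatch a two-sample comparison on the data's own diagnostics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(len(x), len(y)) < 3:
        raise ValueError("each group needs at least 3 observations")
    non_normal = (stats.shapiro(x).pvalue < alpha
                  or stats.shapiro(y).pvalue < alpha)
    if non_normal:
        u, zstat, r = mann_whitney_r(x, y)
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        return GroupComparison("mann_whitney", u, None, p, "r", r)
    d = cohens_d(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))
    if stats.bartlett(x, y).pvalue < alpha:
        res = stats.ttest_ind(x, y, equal_var=False)
        df = welch_df(x.std(ddof=1), len(x), y.std(ddof=1), len(y))
        return GroupComparison("welch_t", float(res.statistic), df,
                               float(res.pvalue), "d", d)
    res = stats.ttest_ind(x, y, equal_var=True)
    return GroupComparison("student_t", float(res.statistic),
                           float(len(x) + len(y) - 2), float(res.pvalue), "d", d)


def pearson_cor(x, y, conf: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """Product-moment correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    zcrit = stats.norm.ppf(0.5 + conf / 2)
    zr = np.arctanh(r)
    half = zcrit / np.sqrt(len(x) - 3)
    return float(r), (float(np.tanh(zr - half)), float(np.tanh(zr + half))), float(p)


def adjust_pvalues(ps, method: str = "bh") -> np.ndarray:
    """Multiple-comparison adjustment; Benjamini-Hochberg step-up by default."""
    ps = np.asarray(ps, dtype=float)
    if np.any((ps < 0) | (ps > 1)) or np.any(~np.isfinite(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni",
                 "holm": "holm"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(ps, method=sm_method)[1]
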