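"""Count-model statistics for vessel-day catch.

Daily legal-catch counts are modelled with log-linear count GLMs over
categorical time/area/technique/fisherman factors.  Two families are
supported: Poisson, and the NB2 negative binomial with variance
mu + mu^2/theta (theta estimated by maximum likelihood unless fixed).
Model comparison tools mirror standard fisheries CPUE-standardisation
practice: a boundary-corrected likelihood-ratio test for overdispersion,
Vuong's non-nested test between Poisson and negative binomial fits,
sequential ANOVA (analysis-of-deviance) term tests at a shared
dispersion, and z-tests on single coefficients.

Factor reference levels are taken in order of first appearance in the
data.  Fitting is delegated to statsmodels; this module owns the design
checks, the shared-dispersion nesting logic, and the test statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.special import gammaln

from .errors import SeparationError


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float | None
    p_value: float
    direction: str | None = None
    extra: dict = field(default_factory=dict)

    def __repr__(self):
        d = f", df={self.df}" if self.df is not None else ""
        return f"TestResult({self.name}: stat={self.statistic:.4g}{d}, p={self.p_value:.4g})"


@dataclass
class GLMFit:
    family: str                      # "poisson" | "negbin"
    terms: tuple[str, ...]
    formula: str
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    theta: float | None
    llf: float
    loglik_obs: np.ndarray
    deviance: float
    df_resid: int
    aic: float
    delta_aic_vs_null: float | None
    fitted: np.ndarray
    n_obs: int
    data: pd.DataFrame
    response: str
    _glm_result: object = None       # fixed-dispersion GLM handle for predictions

    def predict_mean(self, newdata: pd.DataFrame, alpha_level: float = 0.05):
        """Fitted mean on the response scale with a (1-alpha) interval,
        from the normal approximation on the linear predictor."""
        pred = self._glm_result.get_prediction(newdata)
        sf = pred.summary_frame(alpha=alpha_level)
        return sf[["mean", "mean_ci_lower", "mean_ci_upper"]]


def _first_appearance_categorical(data: pd.DataFrame, cols) -> pd.DataFrame:
    out = data.copy()
    for c in cols:
        if out[c].dtype == object or isinstance(out[c].dtype, pd.CategoricalDtype):
            cats = list(dict.fromkeys(out[c]))
            out[c] = pd.Categorical(out[c], categories=cats)
    return out


def _factor_columns(terms) -> list[str]:
    cols = []
    for t in terms:
        for c in t.split(":"):
            if c not in cols:
                cols.append(c)
    return cols


def check_separation(data: pd.DataFrame, response: str, terms) -> None:
    """Raise :class:`SeparationError` if any cell of the finest factor
    crossing has an all-zero response (ML estimate would diverge)."""
    cols = _factor_columns(terms)
    if not cols:
        return
    cell_max = data.groupby(cols, observed=True)[response].max()
    bad = cell_max[cell_max == 0]
    if len(bad):
        raise SeparationError(list(bad.index))


def _loglik_obs(y, mu, alpha: float | None) -> np.ndarray:
    """Per-observation log-likelihood; ``alpha=None`` means Poisson,
    otherwise NB2 with Var = mu + alpha mu^2."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    if alpha is None or alpha == 0:
        return y * np.log(mu) - mu - gammaln(y + 1)
    inv = 1.0 / alpha
    return (gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - inv * np.log1p(alpha * mu))


def fit_count_glm(
    data: pd.DataFrame,
    response: str = "legal_catch",
    terms: tuple[str, ...] = (),
    family: str = "negbin",
    theta: float | None = None,
    compute_delta_aic: bool = True,
) -> GLMFit:
    """Fit a log-linear count GLM.

    ``terms`` are additive factor names, with ``:`` marking interactions
    (e.g. ``("month", "area", "month:area")``).  For the negative
    binomial, theta is estimated by ML when not supplied.  Raises
    :class:`SeparationError` when a factor cell's responses are all zero.
    """
    if family not in ("poisson", "negbin"):
        raise ValueError("family must be 'poisson' or 'negbin'")
    check_separation(data, response, terms)
    cols = _factor_columns(terms)
    df = _first_appearance_categorical(data[[response, *cols]].reset_index(drop=True), cols)
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{response} ~ {rhs}"
    y = df[response].to_numpy(float)

    if family == "poisson":
        res = smf.glm(formula, df, family=sm.families.Poisson()).fit()
        alpha = None
        params = res.params
        glm_res = res
        llf = float(res.llf)
    else:
        if theta is None:
            pois = smf.glm(formula, df, family=sm.families.Poisson()).fit()
            start = np.append(pois.params.to_numpy(), 0.1)
            with warnings.catch_warnings():
                # the dispersion boundary (alpha -> 0) routinely degrades
                # the hessian; only the ML point estimate is used here
                warnings.simplefilter("ignore")
                nb = smf.negativebinomial(formula, df).fit(
                    start_params=start, method="bfgs", maxiter=500, disp=0)
            alpha = float(max(nb.params["alpha"], 1e-10))
            params = nb.params.drop("alpha")
        else:
            alpha = 1.0 / theta
            params = None
        glm_res = smf.glm(
            formula, df, family=sm.families.NegativeBinomial(alpha=alpha)
        ).fit()
        if params is None:
            params = glm_res.params
        llf = float(_loglik_obs(y, glm_res.fittedvalues.to_numpy(), alpha).sum())

    mu = glm_res.fittedvalues.to_numpy()
    ll_obs = _loglik_obs(y, mu, alpha)
    k = len(params) + (1 if family == "negbin" and theta is None else 0)
    aic = 2 * k - 2 * llf
    bse = glm_res.bse[params.index]
    z = params / bse
    fit = GLMFit(
        family=family, terms=tuple(terms), formula=formula,
        params=params, bse=bse, zvalues=z,
        pvalues=pd.Series(2 * stats.norm.sf(np.abs(z)), index=params.index),
        theta=(None if alpha is None else 1.0 / alpha),
        llf=llf, loglik_obs=ll_obs,
        deviance=float(glm_res.deviance), df_resid=int(glm_res.df_resid),
        aic=aic, delta_aic_vs_null=None,
        fitted=mu, n_obs=len(df), data=df, response=response,
        _glm_result=glm_res,
    )
    if compute_delta_aic and terms:
        null = fit_count_glm(data, response, (), family,
                             theta=theta, compute_delta_aic=False)
        fit.delta_aic_vs_null = fit.aic - null.aic
    return fit


def overdispersion_lrt(poisson_fit: GLMFit, negbin_fit: GLMFit) -> TestResult:
    """Likelihood-ratio test for overdispersion (Poisson vs NB2).

    statistic = 2 (l_NB - l_Poisson), referred to chi-square df 1.  Since
    theta lies on the boundary under the null, the mixture-corrected
    (halved) p-value is reported as primary; the raw chi-square p is kept
    alongside.
    """
    stat = 2.0 * (negbin_fit.llf - poisson_fit.llf)
    # on the theta boundary the NB refit can land a hair below Poisson
    if stat < -1e-3:
        raise ArithmeticError(
            f"negative-binomial log-likelihood below Poisson by {-stat/2:.3g}; "
            "dispersion fit did not converge")
    stat = max(stat, 0.0)
    p_raw = float(stats.chi2.sf(stat, 1))
    p_halved = 0.5 * p_raw if stat > 0 else 1.0
    return TestResult("overdispersion_lrt", float(stat), 1, p_halved,
                      extra={"p_raw": p_raw, "p_halved": p_halved})


def vuong_test(fit_a: GLMFit, fit_b: GLMFit) -> TestResult:
    """Vuong's non-nested model comparison on per-observation likelihoods.

    m_i = l_a,i - l_b,i; statistic = mean(m) sqrt(n) / sd(m) (population
    sd), two-sided normal p.  Negative values favour ``fit_b``.
    """
    m = fit_a.loglik_obs - fit_b.loglik_obs
    n = len(m)
    sd = float(np.std(m))
    if sd == 0:
        return TestResult("vuong", np.nan, None, np.nan,
                          direction="undefined (identical fits)")
    z = float(np.mean(m) * np.sqrt(n) / sd)
    p = float(2 * stats.norm.sf(abs(z)))
    direction = "favors_a" if z > 0 else "favors_b" if z < 0 else "neutral"
    return TestResult("vuong", z, None, p, direction=direction)


def fit_nested_sequence(
    data: pd.DataFrame,
    terms_sequence,
    response: str = "legal_catch",
    family: str = "negbin",
) -> list[GLMFit]:
    """Fit a nested model sequence with shared dispersion.

    ``terms_sequence`` is e.g. ``[(), ("month",), ("month", "area"),
    ("month", "area", "month:area")]``.  For the negative binomial, theta
    is estimated once on the largest model and held fixed in every fit so
    the analysis-of-deviance decomposition is coherent.
    """
    seq = [tuple(t) for t in terms_sequence]
    for a, b in zip(seq, seq[1:]):
        if not set(a) <= set(b):
            raise ValueError(f"sequence not nested: {a} not within {b}")
    theta = None
    if family == "negbin":
        full = fit_count_glm(data, response, seq[-1], "negbin",
                             compute_delta_aic=False)
        theta = full.theta
    return [fit_count_glm(data, response, t, family, theta=theta,
                          compute_delta_aic=False) for t in seq]


def anova_terms(fits: list[GLMFit]) -> list[TestResult]:
    """Sequential analysis of deviance over a nested fit sequence.

    For each added term: deviance decrease, df added, and a chi-square
    p-value at that df (NaN when df = 0).
    """
    results = []
    for prev, cur in zip(fits, fits[1:]):
        if prev.family != cur.family:
            raise ValueError("fits mix families")
        if not set(prev.terms) <= set(cur.terms):
            raise ValueError(f"fits not nested: {prev.terms} vs {cur.terms}")
        added = [t for t in cur.terms if t not in prev.terms]
        df = prev.df_resid - cur.df_resid
        if df < 0:
            raise ValueError("degrees of freedom increased along the sequence")
        drop = prev.deviance - cur.deviance
        p = float(stats.chi2.sf(max(drop, 0.0), df)) if df > 0 else np.nan
        results.append(TestResult(
            "+".join(added) or "(none)", float(drop), df, p))
    return results


def technique_comparison(
    data: pd.DataFrame,
    response: str = "legal_catch",
    technique_col: str = "technique",
) -> tuple[GLMFit, TestResult, pd.DataFrame]:
    """Retention vs non-retention CPUE within one area.

    Negative binomial fit with the sampling technique as the only factor;
    z-test on the technique coefficient; per-technique mean CPUE with 95%
    intervals on the response scale.
    """
    levels = list(dict.fromkeys(data[technique_col].dropna()))
    if len(levels) < 2:
        raise ValueError(f"need both techniques, found {levels}")
    fit = fit_count_glm(data, response, (technique_col,), "negbin",
                        compute_delta_aic=False)
    coef_name = [i for i in fit.params.index if i != "Intercept"][0]
    test = TestResult(
        f"technique[{levels[1]} vs {levels[0]}]",
        float(fit.zvalues[coef_name]), None, float(fit.pvalues[coef_name]),
        direction=("higher" if fit.params[coef_name] > 0 else "lower"),
        extra={"coef": float(fit.params[coef_name]),
               "se": float(fit.bse[coef_name])},
    )
    newdata = pd.DataFrame({technique_col: pd.Categorical(levels, categories=levels)})
    means = fit.predict_mean(newdata)
    means.insert(0, technique_col, levels)
    means.insert(1, "n_days", [int((data[technique_col] == l).sum()) for l in levels])
    return fit, test, means.reset_index(drop=True)


def success_day_chisq(success, technique=None, *, table=None) -> TestResult:
    """2x2 chi-square on successful (>=1 fish) vs zero-catch days by
    technique, with Yates continuity correction.

    Pass per-day flags (``success`` boolean, ``technique`` labels) or a
    prebuilt 2x2 ``table``.  The corrected statistic/p are primary; the
    uncorrected statistic is co-reported.  Empty margins give NaN.
    """
    if table is None:
        tab = pd.crosstab(np.asarray(technique), np.asarray(success, bool))
        if tab.shape != (2, 2):
            return TestResult("success_day_chisq", np.nan, 1, np.nan,
                              direction="undefined (empty margin)")
        table = tab.to_numpy(float)
    t = np.asarray(table, float)
    a, b, c, d = t.ravel()
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return TestResult("success_day_chisq", np.nan, 1, np.nan,
                          direction="undefined (empty margin)")
    raw = n * (a * d - b * c) ** 2 / denom
    corrected = n * max(abs(a * d - b * c) - n / 2, 0.0) ** 2 / denom
    p = float(stats.chi2.sf(corrected, 1))
    return TestResult("success_day_chisq", float(corrected), 1, p,
                      extra={"statistic_uncorrected": float(raw),
                             "p_uncorrected": float(stats.chi2.sf(raw, 1))})


def fisherman_effect(
    data: pd.DataFrame,
    response: str = "legal_catch",
    fisherman_col: str = "vessel_id",
    alpha_level: float = 0.05,
) -> tuple[GLMFit, pd.DataFrame, dict]:
    """Negative binomial model with an individual-fisherman factor only.

    Each fisherman is z-tested against the (first-appearance) reference
    level at the uncorrected ``alpha_level``.  The summary carries an
    explicit multiple-testing caveat: with F fishermen, about 5% of the
    F-1 uncorrected tests are expected significant under the null.
    """
    levels = list(dict.fromkeys(data[fisherman_col].dropna()))
    if len(levels) < 2:
        raise ValueError("need at least two fishermen")
    fit = fit_count_glm(data, response, (fisherman_col,), "negbin",
                        compute_delta_aic=True)
    rows = []
    for name in fit.params.index:
        if name == "Intercept":
            continue
        level = name.split("T.")[-1].rstrip("]")
        rows.append({
            "fisherman": level,
            "coef": float(fit.params[name]),
            "z": float(fit.zvalues[name]),
            "p_value": float(fit.pvalues[name]),
            "significant": bool(fit.pvalues[name] < alpha_level),
            "direction": "higher" if fit.params[name] > 0 else "lower",
        })
    per = pd.DataFrame(rows)
    sig = per[per["significant"]]
    summary = {
        "reference": levels[0],
        "n_fishermen": len(levels),
        "n_tested": len(per),
        "n_significant_higher": int((sig["direction"] == "higher").sum()),
        "n_significant_lower": int((sig["direction"] == "lower").sum()),
        "caveat": ("per-fisherman p-values are uncorrected for multiple "
                   "testing; ~5% of comparisons are expected significant "
                   "by chance at alpha=0.05"),
    }
    return fit, per, summary
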