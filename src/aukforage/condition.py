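"""Chick growth modelling and adult body condition.

Growth over the linear window (age 4-14 d) is modelled with random-intercept
linear mixed models fitted by maximum likelihood (ML, not REML, since the
candidates differ in their fixed effects).  Candidates span all combinations
of age and year, and selection follows a parsimony-tempered AIC rule: among
models within 2 AIC units of the best, keep the one with the fewest
parameters.  The parameter count k includes the fixed effects plus the
random-intercept and residual variances, and AIC = 2k - 2 logL.

Adult body condition is the residual of a pooled ordinary regression of mass
on wing and head-bill length (a size-corrected mass index); years are
compared with an F-test on those residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

DEFAULT_CANDIDATES = (
    (),
    ("age",),
    ("year",),
    ("age", "year"),
    ("age", "year", "age:year"),
)


@dataclass
class ModelFit:
    fixed_terms: tuple
    formula: str
    k: int
    log_likelihood: float
    aic: float
    coefficients: pd.Series = field(repr=False)
    coefficient_se: pd.Series = field(repr=False)
    random_intercept_var: float
    residual_var: float
    converged: bool
    result: object = field(default=None, repr=False)


def _formula(terms: tuple) -> str:
    parts = []
    for t in terms:
        if t == "year":
            parts.append("C(year)")
        elif t == "age:year":
            parts.append("age:C(year)")
        else:
            parts.append(t)
    return "mass ~ " + (" + ".join(parts) if parts else "1")


def fit_growth_models(records: pd.DataFrame,
                      candidate_fixed_sets=DEFAULT_CANDIDATES,
                      age_window: tuple[float, float] = (4, 14)) -> list[ModelFit]:
    """Fit a random-intercept LMM (grouping: chick) per candidate fixed-effect
    set, by ML.  Records outside the linear age window are dropped; a fit
    that fails to converge is flagged and later excluded from selection."""
    df = records[(records.age >= age_window[0]) & (records.age <= age_window[1])].copy()
    if df.chick_id.nunique() < 2 or len(df) < 4:
        raise ValueError("need >= 2 observations for >= 2 chicks inside the window")
    single_year = df.year.nunique() < 2 if "year" in df.columns else True
    fits = []
    for terms in candidate_fixed_sets:
        if single_year and any("year" in t for t in terms):
            continue
        formula = _formula(tuple(terms))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm(formula, df, groups=df["chick_id"]).fit(
                    reml=False, method="bfgs", maxiter=200)
            converged = bool(res.converged) and np.isfinite(res.llf)
        except Exception:
            res, converged = None, False
        if res is None:
            fits.append(ModelFit(tuple(terms), formula, 0, np.nan, np.nan,
                                 pd.Series(dtype=float), pd.Series(dtype=float),
                                 np.nan, np.nan, False))
            continue
        k = len(res.fe_params) + 2  # + random-intercept var + residual var
        llf = float(res.llf)
        fits.append(ModelFit(
            fixed_terms=tuple(terms), formula=formula, k=k,
            log_likelihood=llf, aic=2.0 * k - 2.0 * llf,
            coefficients=res.fe_params, coefficient_se=res.bse_fe,
            random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
            residual_var=float(res.scale), converged=converged, result=res))
    return fits


def select_model(fits: list[ModelFit]) -> ModelFit:
    """AIC selection with the parsimony rule: among converged fits within
    2 AIC of the minimum, return the one with the fewest parameters (ties on
    k broken by lower AIC)."""
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged fits to select from")
    best = min(f.aic for f in ok)
    shortlist = [f for f in ok if f.aic - best <= 2.0]
    return min(shortlist, key=lambda f: (f.k, f.aic))


def selection_table(fits: list[ModelFit]) -> pd.DataFrame:
    """Model-comparison table (K, AIC, deltaAIC) sorted by AIC."""
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    best = min(f.aic for f in ok) if ok else np.nan
    rows = [{"fixed_terms": " + ".join(f.fixed_terms) or "intercept only",
             "K": f.k, "logLik": f.log_likelihood, "AIC": f.aic,
             "dAIC": f.aic - best, "converged": f.converged}
            for f in fits]
    return pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)


def body_condition(morphs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Size-corrected body-condition index and between-year comparison.

    Pools all years into one OLS of mass on wing and head-bill length; the
    condition index is the residual.  The headline test is the one-way F on
    residual mass across years (df = n - 2 for two years); a full
    covariate-adjusted ANCOVA F for year is also returned.
    """
    required = {"mass", "wing", "headbill", "year"}
    if required - set(morphs.columns):
        raise ValueError(f"missing columns: {sorted(required - set(morphs.columns))}")
    df = morphs.dropna(subset=list(required)).copy()
    counts = df.groupby("year").size()
    if (counts < 3).any():
        raise ValueError("need at least 3 birds per year")
    r = np.corrcoef(df.wing, df.headbill)[0, 1]
    if abs(r) > 0.999:
        raise ValueError("wing and head-bill are collinear (|r| > 0.999)")
    size_fit = smf.ols("mass ~ wing + headbill", df).fit()
    df["condition"] = size_fit.resid
    # residual-mass ~ year one-way F (the conventional residual-index test)
    res_fit = smf.ols("condition ~ C(year)", df).fit()
    an = sm.stats.anova_lm(res_fit, typ=2)
    F = float(an.loc["C(year)", "F"])
    p = float(an.loc["C(year)", "PR(>F)"])
    df_num = int(an.loc["C(year)", "df"])
    df_den = int(an.loc["Residual", "df"])
    # covariate-adjusted alternative
    adj = sm.stats.anova_lm(smf.ols("mass ~ wing + headbill + C(year)", df).fit(),
                            typ=2)
    stats = {
        "F": F, "df_num": df_num, "df_den": df_den, "p": p,
        "ancova_adjusted_F": float(adj.loc["C(year)", "F"]),
        "ancova_adjusted_p": float(adj.loc["C(year)", "PR(>F)"]),
        "mean_condition_by_year": df.groupby("year")["condition"].mean().to_dict(),
        "size_model": size_fit,
    }
    out_cols = [c for c in ("bird_id", "year", "mass", "wing", "headbill",
                            "condition") if c in df.columns]
    return df[out_cols], stats
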