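"""Gender x Income x Education moderated regression with simple slopes.

The omnibus model is an OLS fit of the standardized outcome (the IAT D
score, or any explicit difference measure) on gender (women = -0.5,
men = +0.5), z-scored income and education, and all their products:

    y = b0 + bG*G + bI*I + bE*E + bGI*GI + bGE*GE + bIE*IE + bGIE*GIE + e

Under this coding bGI equals the men-minus-women income-slope difference
and bG the gender difference at mean income and education. Interactions
are decomposed into simple effects -- linear combinations c'b of the
omnibus coefficients with se = sqrt(c' Cov(b) c) and unchanged residual
df -- evaluated by convention at +-1.5 SD of the moderator.

Multicollinearity is checked via variance inflation factors; if any VIF
exceeds the threshold (10), income is residualized on education and the
model refit (the pre-registered orthogonalization contingency).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from . import config as cfg

__all__ = ["ModelFit", "standardize", "build_design", "fit_omnibus",
           "estimate_contrast", "simple_effects", "SIMPLE_EFFECT_CONTRASTS",
           "contrast_vector"]

TERMS = cfg.OMNIBUS_TERMS


def standardize(values) -> np.ndarray:
    """z-scores: mean 0, sample SD 1 (ddof=1), on the analysis sample."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("standardize requires at least 2 distinct values")
    return (x - x.mean()) / x.std(ddof=1)


def build_design(gender_code, income_z, education_z) -> np.ndarray:
    """Design matrix with columns in OMNIBUS_TERMS order."""
    g = np.asarray(gender_code, dtype=float)
    i = np.asarray(income_z, dtype=float)
    e = np.asarray(education_z, dtype=float)
    return np.column_stack(
        [np.ones_like(g), g, i, e, g * i, g * e, i * e, g * i * e]
    )


@dataclasses.dataclass
class ModelFit:
    terms: tuple
    b: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    t: np.ndarray
    df: int
    p: np.ndarray
    vif: np.ndarray  # NaN for the intercept
    n: int
    cov: np.ndarray
    orthogonalized: bool = False

    def coef(self, term: str) -> float:
        return float(self.b[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "b": self.b,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "t": self.t,
                "df": self.df,
                "p": self.p,
                "vif": self.vif,
            }
        )


def _fit_ols(X: np.ndarray, y: np.ndarray, orthogonalized: bool) -> ModelFit:
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        collinear = [
            (TERMS[1 + a], TERMS[1 + b])
            for a in range(k - 1)
            for b in range(a + 1, k - 1)
            if abs(corr[a, b]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")
    model = sm.OLS(y, X).fit()
    ci = model.conf_int(0.05)
    vif = np.full(k, np.nan)
    for j in range(1, k):
        vif[j] = variance_inflation_factor(X, j)
    return ModelFit(
        terms=TERMS,
        b=np.asarray(model.params),
        se=np.asarray(model.bse),
        ci_low=ci[:, 0],
        ci_high=ci[:, 1],
        t=np.asarray(model.tvalues),
        df=int(model.df_resid),
        p=np.asarray(model.pvalues),
        vif=vif,
        n=n,
        cov=np.asarray(model.cov_params()),
        orthogonalized=orthogonalized,
    )


def fit_omnibus(
    data: pd.DataFrame,
    outcome: str = "d",
    vif_threshold: float = cfg.VIF_THRESHOLD,
    standardize_outcome: bool = True,
    already_standardized: bool = False,
) -> ModelFit:
    """Fit the full-interaction omnibus model on an analysis table.

    Expects columns gender ('f'/'m'), income_level, education_level and
    the outcome column; income/education/outcome are z-scored on this
    sample unless already standardized. Requires >= 20 complete cases and
    both genders. Applies the orthogonalization contingency if any VIF
    exceeds the threshold.
    """
    cols = ["gender", "income_level", "education_level", outcome]
    sub = data[cols].dropna()
    if len(sub) < 20:
        raise ValueError(f"need >= 20 complete cases, got {len(sub)}")
    if set(sub["gender"].unique()) != {"f", "m"}:
        raise ValueError("both genders must be present in the analysis sample")
    g = sub["gender"].map(cfg.GENDER_CODES).to_numpy(float)
    if already_standardized:
        iz = sub["income_level"].to_numpy(float)
        ez = sub["education_level"].to_numpy(float)
    else:
        iz = standardize(sub["income_level"].to_numpy(float))
        ez = standardize(sub["education_level"].to_numpy(float))
    y = sub[outcome].to_numpy(float)
    if standardize_outcome and not already_standardized:
        y = standardize(y)
    X = build_design(g, iz, ez)
    fit = _fit_ols(X, y, orthogonalized=False)
    if np.nanmax(fit.vif) > vif_threshold:
        # orthogonalization contingency: replace income by its residual
        # from a regression on education, rebuild products, refit
        resid = iz - np.polyval(np.polyfit(ez, iz, 1), ez)
        X = build_design(g, standardize(resid), ez)
        fit = _fit_ols(X, y, orthogonalized=True)
    return fit


def estimate_contrast(fit: ModelFit, c, name: str = "", **at) -> dict:
    """Estimate, se, CI, t, df, p for the linear combination c'b."""
    c = np.asarray(c, dtype=float)
    b = float(c @ fit.b)
    se = float(np.sqrt(c @ fit.cov @ c))
    t = b / se
    p = 2 * stats.t.sf(abs(t), fit.df)
    tcrit = stats.t.ppf(0.975, fit.df)
    return {
        "effect": name,
        "b": b,
        "se": se,
        "ci_low": b - tcrit * se,
        "ci_high": b + tcrit * se,
        "t": t,
        "df": fit.df,
        "p": float(p),
        **at,
    }


def contrast_vector(
    kind: str, gender: str | None = None, income_z: float = 0.0,
    education_z: float = 0.0,
) -> np.ndarray:
    """Contrast for a supported simple effect of the omnibus model.

    kinds: 'income_slope' (per gender, at education_z), 'education_slope'
    (per gender, at income_z), 'gender_difference' (at income_z and
    education_z), 'gender_x_income' (at education_z),
    'gender_x_education' (at income_z), 'income_x_education' -- plus the
    raw coefficients via kind == one of the term names.
    """
    c = np.zeros(len(TERMS))

    def idx(t):
        return TERMS.index(t)

    if kind in TERMS:
        c[idx(kind)] = 1.0
        return c
    gcode = None if gender is None else cfg.GENDER_CODES[gender]
    if kind == "income_slope":
        if gcode is None:
            raise ValueError("income_slope requires a gender")
        c[idx("I")] = 1.0
        c[idx("GI")] = gcode
        c[idx("IE")] = education_z
        c[idx("GIE")] = gcode * education_z
    elif kind == "education_slope":
        if gcode is None:
            raise ValueError("education_slope requires a gender")
        c[idx("E")] = 1.0
        c[idx("GE")] = gcode
        c[idx("IE")] = income_z
        c[idx("GIE")] = gcode * income_z
    elif kind == "gender_difference":
        c[idx("G")] = 1.0
        c[idx("GI")] = income_z
        c[idx("GE")] = education_z
        c[idx("GIE")] = income_z * education_z
    elif kind == "gender_x_education":
        c[idx("GE")] = 1.0
        c[idx("GIE")] = income_z
    elif kind == "gender_x_income":
        c[idx("GI")] = 1.0
        c[idx("GIE")] = education_z
    elif kind == "education_main":
        c[idx("E")] = 1.0
        c[idx("IE")] = income_z
    elif kind == "income_main":
        c[idx("I")] = 1.0
        c[idx("IE")] = education_z
    else:
        raise ValueError(f"unsupported simple-effect kind {kind!r}")
    return c


#: the standard decomposition battery: name -> contrast_vector arguments
SIMPLE_EFFECT_CONTRASTS = {
    "income_slope_men": dict(kind="income_slope", gender="m"),
    "income_slope_women": dict(kind="income_slope", gender="f"),
    "gender_difference_low_income": dict(
        kind="gender_difference", income_z=-cfg.EVAL_POINT_SD
    ),
    "gender_difference_mean_income": dict(kind="gender_difference"),
    "gender_difference_high_income": dict(
        kind="gender_difference", income_z=+cfg.EVAL_POINT_SD
    ),
    "gender_x_education_low_income": dict(
        kind="gender_x_education", income_z=-cfg.EVAL_POINT_SD
    ),
    "gender_x_education_high_income": dict(
        kind="gender_x_education", income_z=+cfg.EVAL_POINT_SD
    ),
    "education_slope_women_low_income": dict(
        kind="education_slope", gender="f", income_z=-cfg.EVAL_POINT_SD
    ),
    "education_slope_men_low_income": dict(
        kind="education_slope", gender="m", income_z=-cfg.EVAL_POINT_SD
    ),
    "education_slope_women_high_income": dict(
        kind="education_slope", gender="f", income_z=+cfg.EVAL_POINT_SD
    ),
    "education_slope_men_high_income": dict(
        kind="education_slope", gender="m", income_z=+cfg.EVAL_POINT_SD
    ),
    "education_main_high_income": dict(
        kind="education_main", income_z=+cfg.EVAL_POINT_SD
    ),
}


def simple_effects(fit: ModelFit, effects: dict | None = None) -> pd.DataFrame:
    """Evaluate a battery of simple effects on a fitted omnibus model."""
    effects = effects or SIMPLE_EFFECT_CONTRASTS
    rows = []
    for name, spec in effects.items():
        c = contrast_vector(**spec)
        rows.append(
            estimate_contrast(
                fit,
                c,
                name=name,
                gender=spec.get("gender", ""),
                income_z=spec.get("income_z", 0.0),
                education_z=spec.get("education_z", 0.0),
            )
        )
    return pd.DataFrame(rows)
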