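"""Monte-Carlo power and sensitivity analysis for the omnibus model.

Each replicate draws a participant-level dataset from the study
conditions (gender ratio, correlated 5-point income/education z-scored
within sample, outcome = X @ beta + normal residual), fits the
full-interaction OLS model, and evaluates a battery of coefficient and
simple-effect contrasts two-sided at alpha. Power for a test is the
proportion of replicates with p < alpha.

The residual SD is calibrated so the design-expected standard error of
the Gender x Income coefficient at the pilot design (n = 175) matches the
printed pilot value (0.055); the pilot estimates are reported on the
standardized-outcome scale without a residual SD, and t-based
decisions are invariant to outcome rescaling, so this calibration pins
down the one free noise parameter.

Sensitivity analysis reruns the battery with one generating coefficient
shrunk by a grid of factors and reports the largest shrink that keeps
power at or above 0.80.
"""

from __future__ import annotations

import dataclasses
import functools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import config as cfg
from .cohort import latent_correlation_for_observed, ordinal_thresholds
from .regression import TERMS, build_design, contrast_vector, standardize

__all__ = [
    "PowerConfig",
    "PowerResult",
    "DEFAULT_POWER_TESTS",
    "calibrate_residual_sd",
    "simulate_design",
    "simulate_dataset",
    "estimate_power",
    "sensitivity",
]

#: the battery mirroring the hypothesis tests: omnibus interactions,
#: income slope per gender, education slope per gender at +-1.5 SD income,
#: the education main effect and Gender x Education at high income, and
#: the gender main effect.
DEFAULT_POWER_TESTS = {
    "gender_x_income": dict(kind="GI"),
    "gender_x_income_x_education": dict(kind="GIE"),
    "income_slope_men": dict(kind="income_slope", gender="m"),
    "income_slope_women": dict(kind="income_slope", gender="f"),
    "education_slope_men_low_income": dict(
        kind="education_slope", gender="m", income_z=-cfg.EVAL_POINT_SD
    ),
    "education_slope_women_low_income": dict(
        kind="education_slope", gender="f", income_z=-cfg.EVAL_POINT_SD
    ),
    "education_slope_men_high_income": dict(
        kind="education_slope", gender="m", income_z=+cfg.EVAL_POINT_SD
    ),
    "education_slope_women_high_income": dict(
        kind="education_slope", gender="f", income_z=+cfg.EVAL_POINT_SD
    ),
    "gender_x_education_low_income": dict(
        kind="gender_x_education", income_z=-cfg.EVAL_POINT_SD
    ),
    "gender_x_education_high_income": dict(
        kind="gender_x_education", income_z=+cfg.EVAL_POINT_SD
    ),
    "education_main_high_income": dict(
        kind="education_main", income_z=+cfg.EVAL_POINT_SD
    ),
    "gender_main": dict(kind="G"),
}


@dataclasses.dataclass
class PowerConfig:
    coef_vector: dict = dataclasses.field(
        default_factory=lambda: dict(cfg.PILOT_COEFS)
    )
    prop_women: float = cfg.PILOT_PROP_WOMEN
    income_education_corr: float = cfg.PILOT_R_INCOME_EDUCATION
    income_marginals: tuple = cfg.PILOT_INCOME_COUNTS
    education_marginals: tuple = cfg.PILOT_EDUCATION_COUNTS
    residual_sd: float | None = None  # None -> calibrate against PILOT_SE_GI
    n_per_dataset: int = cfg.STAGE1_N
    n_reps: int = cfg.N_REPS_DEFAULT
    alpha: float = cfg.ALPHA
    tests: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_POWER_TESTS))
    shrink_factors: tuple = ()
    standardize_outcome: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if any(not 0.0 <= s <= 1.0 for s in self.shrink_factors):
            raise ValueError("shrink factors must lie in [0, 1]")


@dataclasses.dataclass
class PowerResult:
    test: str
    power: float
    mc_se: float
    n_significant: int
    n_reps: int
    n_per_dataset: int
    shrink_factor: float = 1.0


@functools.lru_cache(maxsize=32)
def _cached_latent_rho(target_r: float, income_marginals: tuple,
                       education_marginals: tuple) -> float:
    return latent_correlation_for_observed(
        target_r, income_marginals, education_marginals
    )


def simulate_design(
    n: int,
    rng: np.random.Generator,
    prop_women: float = cfg.PILOT_PROP_WOMEN,
    income_education_corr: float = cfg.PILOT_R_INCOME_EDUCATION,
    income_marginals: tuple = cfg.PILOT_INCOME_COUNTS,
    education_marginals: tuple = cfg.PILOT_EDUCATION_COUNTS,
) -> np.ndarray:
    """One design matrix draw: +-0.5 gender codes and within-sample
    z-scored correlated 5-point income/education, with all products."""
    g = np.where(rng.random(n) < prop_women, -0.5, +0.5)
    rho = _cached_latent_rho(
        float(income_education_corr), tuple(income_marginals),
        tuple(education_marginals),
    )
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    income = np.searchsorted(ordinal_thresholds(income_marginals), z[:, 0]) + 1
    education = np.searchsorted(ordinal_thresholds(education_marginals), z[:, 1]) + 1
    return build_design(g, standardize(income), standardize(education))


def _config_design(config: PowerConfig, n: int, rng: np.random.Generator):
    return simulate_design(
        n,
        rng,
        prop_women=config.prop_women,
        income_education_corr=config.income_education_corr,
        income_marginals=config.income_marginals,
        education_marginals=config.education_marginals,
    )


def calibrate_residual_sd(
    target_se: float = cfg.PILOT_SE_GI,
    n: int = cfg.PILOT_N,
    n_reps: int = 400,
    seed: int = 0,
    config: PowerConfig | None = None,
) -> float:
    """Residual SD such that the design-expected se of the GI coefficient
    at the pilot design equals target_se.

    se(bGI) = sigma * sqrt[(X'X)^-1_GI,GI]; the bracket is averaged over
    seeded design draws at the pilot n, and sigma solved directly.
    """
    config = config or PowerConfig()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCA1B)))
    j = TERMS.index("GI")
    factors = np.empty(n_reps)
    for r in range(n_reps):
        X = _config_design(config, n, rng)
        factors[r] = np.sqrt(np.linalg.inv(X.T @ X)[j, j])
    return float(target_se / factors.mean())


def simulate_dataset(
    config: PowerConfig, rng: np.random.Generator, residual_sd: float,
    beta: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one analysis-ready (X, y) pair from the generating model."""
    X = _config_design(config, config.n_per_dataset, rng)
    if beta is None:
        beta = np.array([config.coef_vector[t] for t in TERMS])
    y = X @ beta + rng.normal(0.0, residual_sd, size=len(X))
    if config.standardize_outcome:
        y = standardize(y)
    return X, y


def _fit_and_pvalues(
    X: np.ndarray, y: np.ndarray, contrasts: np.ndarray
) -> np.ndarray:
    """Two-sided p-values for rows of `contrasts` from one OLS fit."""
    n, k = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = resid @ resid / df
    est = contrasts @ beta
    var = np.einsum("ij,jk,ik->i", contrasts, xtx_inv, contrasts) * sigma2
    t = est / np.sqrt(var)
    return 2 * stats.t.sf(np.abs(t), df)


def estimate_power(
    config: PowerConfig,
    beta_override: np.ndarray | None = None,
    shrink_factor: float = 1.0,
) -> list[PowerResult]:
    """Run the Monte-Carlo battery; deterministic for a fixed seed.

    Per-rep generators are spawned from the master seed so replicates are
    independent and reproducible. Singular replicates are redrawn (and
    counted); with continuous noise these are essentially impossible.
    """
    names = list(config.tests)
    contrasts = np.array([contrast_vector(**config.tests[t]) for t in names])
    residual_sd = (
        config.residual_sd
        if config.residual_sd is not None
        else calibrate_residual_sd(seed=config.seed, config=config)
    )
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_reps)
    n_sig = np.zeros(len(names), dtype=int)
    n_redrawn = 0
    for child in children:
        rng = np.random.default_rng(child)
        for _attempt in range(10):
            X, y = simulate_dataset(config, rng, residual_sd, beta_override)
            if np.linalg.matrix_rank(X) == X.shape[1]:
                break
            n_redrawn += 1
        p = _fit_and_pvalues(X, y, contrasts)
        n_sig += p < config.alpha
    results = []
    for name, k in zip(names, n_sig):
        power = k / config.n_reps
        results.append(
            PowerResult(
                test=name,
                power=float(power),
                mc_se=float(np.sqrt(power * (1 - power) / config.n_reps)),
                n_significant=int(k),
                n_reps=config.n_reps,
                n_per_dataset=config.n_per_dataset,
                shrink_factor=shrink_factor,
            )
        )
    if n_redrawn:
        logging.getLogger(__name__).info(
            "%d singular replicates redrawn", n_redrawn
        )
    return results


def power_frame(results: list[PowerResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def sensitivity(
    config: PowerConfig,
    target_test: str,
    shrink_factors=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    power_floor: float = 0.80,
) -> tuple[pd.DataFrame, float | None]:
    """Power curve for one coefficient shrunk by each factor in the grid.

    target_test must name a raw coefficient test (e.g. the three-way
    interaction). Returns the curve and the largest shrink keeping power
    >= power_floor (None if none does).
    """
    spec = config.tests.get(target_test)
    if spec is None or spec.get("kind") not in TERMS:
        raise ValueError(
            f"target_test must name a coefficient test, got {target_test!r}"
        )
    term = spec["kind"]
    beta0 = np.array([config.coef_vector[t] for t in TERMS])
    j = TERMS.index(term)
    rows = []
    for s in shrink_factors:
        beta = beta0.copy()
        beta[j] *= 1.0 - s
        sub = dataclasses.replace(config, tests={target_test: spec})
        for res in estimate_power(sub, beta_override=beta, shrink_factor=float(s)):
            rows.append({**dataclasses.asdict(res), "shrink": float(s)})
    curve = pd.DataFrame(rows)
    ok = curve[curve["power"] >= power_floor]
    largest = float(ok["shrink"].max()) if len(ok) else None
    return curve, largest
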