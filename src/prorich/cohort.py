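"""Synthetic trial-level cohort generator.

Emulates the structure of a web-administered rich--poor evaluative IAT
study: a seven-block task (20-trial dual-task practice blocks, 40-trial
critical blocks, counterbalanced pairing order), five-point income and
education scales correlated at r = 0.22, a roughly 115:60 women:men gender
ratio, and item-level explicit ratings for fourteen self-report measures.
Group-level differences in the generated D scores follow a configurable
vector of omnibus regression coefficients so that the downstream
moderated-regression and power machinery can be validated against known
truth.

Latencies are lognormal with a hard 150 ms floor. A participant's true D
is encoded as a multiplicative (log-additive) slowdown on blocks where the
poor category shares a key with the positive attribute; the slowdown is
solved numerically from lognormal moments so the expected scored D matches
the target. Careless-responding archetypes (fast responder, high error,
ultra slow) are explicit named generators so each exclusion criterion has
a dedicated fixture.
"""

from __future__ import annotations

import dataclasses
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import config as cfg

__all__ = [
    "CohortConfig",
    "LatencyModel",
    "ordinal_thresholds",
    "latent_correlation_for_observed",
    "generate_demographics",
    "generate_iat_trials",
    "generate_explicit_items",
    "generate_cohort",
    "write_cohort",
    "shift_for_target_d",
    "CARELESS_ARCHETYPES",
]


def _check_prop(name: str, value: float) -> None:
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a proportion in [0, 1], got {value!r}")


@dataclasses.dataclass
class CohortConfig:
    """Study-condition parameters for a synthetic cohort.

    Defaults reproduce the pilot-sample characteristics: n = 175 with 115
    women, income-education correlation 0.22, and the omnibus coefficient
    vector reconstructed from the pilot simple effects (gender coded
    women = -0.5, men = +0.5).
    """

    n_participants: int = cfg.PILOT_N
    prop_women: float = cfg.PILOT_PROP_WOMEN
    income_education_corr: float = cfg.PILOT_R_INCOME_EDUCATION
    coef_vector: dict = dataclasses.field(
        default_factory=lambda: dict(cfg.PILOT_COEFS)
    )
    residual_sd: float | None = None  # None -> calibrated (see power module)
    careless_rate: float = 0.0
    missing_income_rate: float = 0.0
    missing_education_rate: float = 0.0
    income_marginals: tuple = cfg.PILOT_INCOME_COUNTS
    education_marginals: tuple = cfg.PILOT_EDUCATION_COUNTS
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_participants) <= 0:
            raise ValueError(
                f"n_participants must be positive, got {self.n_participants!r}"
            )
        _check_prop("prop_women", self.prop_women)
        _check_prop("careless_rate", self.careless_rate)
        _check_prop("missing_income_rate", self.missing_income_rate)
        _check_prop("missing_education_rate", self.missing_education_rate)
        r = self.income_education_corr
        if not np.isfinite(r) or not -1.0 < r < 1.0:
            raise ValueError(
                f"income_education_corr must lie strictly inside (-1, 1), got {r!r}"
            )
        if self.residual_sd is not None and (
            not np.isfinite(self.residual_sd) or self.residual_sd <= 0
        ):
            raise ValueError(f"residual_sd must be positive, got {self.residual_sd!r}")
        missing = set(cfg.OMNIBUS_TERMS) - set(self.coef_vector)
        if missing:
            raise ValueError(f"coef_vector missing terms: {sorted(missing)}")


@dataclasses.dataclass
class LatencyModel:
    """Lognormal latency model for a single participant's IAT trials."""

    log_mean_base: float = np.log(800.0)  # log-ms location (~800 ms median)
    log_sd: float = 0.35  # log-ms scale
    incompatible_shift: float = 0.0  # additive log-ms shift on poor+good blocks
    error_prob_base: float = 0.05
    error_prob_incompatible: float = 0.08

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError(f"log_sd must be positive, got {self.log_sd!r}")
        for name in ("error_prob_base", "error_prob_incompatible"):
            _check_prop(name, getattr(self, name))


# ---------------------------------------------------------------------------
# Ordinal income / education with a controlled observed correlation
# ---------------------------------------------------------------------------


def ordinal_thresholds(marginal_counts) -> np.ndarray:
    """Interior standard-normal cutpoints reproducing the marginal frequencies."""
    p = np.asarray(marginal_counts, dtype=float)
    p = p / p.sum()
    return stats.norm.ppf(np.cumsum(p)[:-1])


def _discretized_pearson_r(rho: float, thr_x: np.ndarray, thr_y: np.ndarray) -> float:
    """Exact Pearson correlation of two 5-level discretizations of a
    standard bivariate normal with latent correlation *rho*."""
    ax = np.concatenate(([-np.inf], thr_x, [np.inf]))
    ay = np.concatenate(([-np.inf], thr_y, [np.inf]))
    mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])

    def F(u, v):
        if u == -np.inf or v == -np.inf:
            return 0.0
        uu = min(u, 8.0)
        vv = min(v, 8.0)
        return float(mvn.cdf([uu, vv]))

    levels = np.arange(1, len(ax))
    px = np.diff(stats.norm.cdf(ax))
    py = np.diff(stats.norm.cdf(ay))
    ex, ey = levels @ px, levels @ py
    vx = (levels**2) @ px - ex**2
    vy = (levels**2) @ py - ey**2
    exy = 0.0
    for i in range(len(levels)):
        for j in range(len(levels)):
            pij = (
                F(ax[i + 1], ay[j + 1])
                - F(ax[i], ay[j + 1])
                - F(ax[i + 1], ay[j])
                + F(ax[i], ay[j])
            )
            exy += levels[i] * levels[j] * pij
    return (exy - ex * ey) / np.sqrt(vx * vy)


def latent_correlation_for_observed(
    target_r: float,
    income_marginals=cfg.PILOT_INCOME_COUNTS,
    education_marginals=cfg.PILOT_EDUCATION_COUNTS,
) -> float:
    """Latent bivariate-normal correlation whose 5-level discretization has
    observed Pearson correlation *target_r* (inverts the attenuation)."""
    if target_r == 0.0:
        return 0.0
    thr_x = ordinal_thresholds(income_marginals)
    thr_y = ordinal_thresholds(education_marginals)

    def gap(rho):
        return _discretized_pearson_r(rho, thr_x, thr_y) - target_r

    lo, hi = sorted((0.0, np.sign(target_r) * 0.999))
    return float(optimize.brentq(gap, lo, hi, xtol=1e-6))


def draw_ordinal_pair(
    n: int,
    rng: np.random.Generator,
    observed_r: float,
    income_marginals=cfg.PILOT_INCOME_COUNTS,
    education_marginals=cfg.PILOT_EDUCATION_COUNTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n correlated (income, education) pairs on the 1..5 scales."""
    rho = latent_correlation_for_observed(
        observed_r, income_marginals, education_marginals
    )
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    income = np.searchsorted(ordinal_thresholds(income_marginals), z[:, 0]) + 1
    education = np.searchsorted(ordinal_thresholds(education_marginals), z[:, 1]) + 1
    return income.astype(int), education.astype(int)


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

_EPOCH = datetime(2005, 6, 1, 9, 0, 0)


def generate_demographics(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Participant demographics table with the configured structure.

    Returns columns participant_id, gender ('f'/'m'), income_level,
    education_level (1-5, NaN at the configured missingness rates) and a
    strictly increasing ISO-8601 timestamp. The hidden (pre-missingness)
    ordinal values are carried in income_true / education_true for use by
    the outcome model; writers drop them.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(config.n_participants)
    gender = np.where(rng.random(n) < config.prop_women, "f", "m")
    income, education = draw_ordinal_pair(
        n,
        rng,
        config.income_education_corr,
        config.income_marginals,
        config.education_marginals,
    )
    miss_i = rng.random(n) < config.missing_income_rate
    miss_e = rng.random(n) < config.missing_education_rate
    ts = [(_EPOCH + timedelta(minutes=7 * i)).isoformat() for i in range(n)]
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i + 1:05d}" for i in range(n)],
            "gender": gender,
            "income_level": pd.array(income, dtype="Int64"),
            "education_level": pd.array(education, dtype="Int64"),
            "timestamp": ts,
            "income_true": income,
            "education_true": education,
        }
    )
    df.loc[miss_i, "income_level"] = pd.NA
    df.loc[miss_e, "education_level"] = pd.NA
    return df


# ---------------------------------------------------------------------------
# IAT trials
# ---------------------------------------------------------------------------


def _lognormal_moments(mu: float, sigma: float) -> tuple[float, float]:
    m = np.exp(mu + sigma**2 / 2)
    v = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
    return m, v


def shift_for_target_d(d_target: float, model: LatencyModel) -> float:
    """Log-space slowdown on incompatible blocks whose expected D equals
    d_target, from lognormal moments (error-free approximation).

    D ~ (m2 - m1) / pooled SD where m1, m2 are the compatible and
    incompatible means and the pooled SD is that of the pooled trials of
    both blocks. Monotone in the shift, so solvable by bracketing.
    """
    if not np.isfinite(d_target):
        raise ValueError(f"true_d_target must be finite, got {d_target!r}")
    mu, sig = model.log_mean_base, model.log_sd

    def d_of(delta):
        m1, v1 = _lognormal_moments(mu, sig)
        m2, v2 = _lognormal_moments(mu + delta, sig)
        pooled_var = (v1 + v2) / 2 + (m2 - m1) ** 2 / 4
        return (m2 - m1) / np.sqrt(pooled_var)

    if d_target == 0.0:
        return 0.0
    # the pooled-SD denominator makes D saturate near +-2 as the shift
    # grows; clamp targets into the attainable range
    d_target = float(np.clip(d_target, d_of(-5.0) * 0.999, d_of(5.0) * 0.999))
    lo, hi = sorted((0.0, np.sign(d_target) * 5.0))
    return float(optimize.brentq(lambda d: d_of(d) - d_target, lo, hi, xtol=1e-10))


def _block_pairings(order_condition: str) -> dict[int, str]:
    if order_condition == "congruent_first":
        first, second = "rich_good", "poor_good"
    elif order_condition == "incongruent_first":
        first, second = "poor_good", "rich_good"
    else:
        raise ValueError(f"unknown order_condition {order_condition!r}")
    return {1: "single_task", 2: "single_task", 3: first, 4: first,
            5: "single_task", 6: second, 7: second}


def generate_iat_trials(
    participant_id: str,
    latency_model: LatencyModel,
    true_d_target: float,
    rng: np.random.Generator,
    order_condition: str = "congruent_first",
    attribute_set: int = 1,
    archetype: str | None = None,
) -> pd.DataFrame:
    """Seven blocks of trials for one participant.

    The pairing role of each block (rich+good vs poor+good) is recorded
    independently of presentation order; counterbalancing only changes
    which physical block carries which role. Positive true_d_target means
    faster responding when rich shares a key with good.
    """
    model = latency_model
    delta = shift_for_target_d(true_d_target, model)
    pairings = _block_pairings(order_condition)
    rows = []
    for block in range(1, 8):
        n = cfg.BLOCK_SIZES[block]
        pairing = pairings[block]
        shift = delta if pairing == "poor_good" else 0.0
        lat = np.exp(rng.normal(model.log_mean_base + shift, model.log_sd, size=n))
        lat = np.maximum(lat, cfg.MIN_LATENCY_MS)
        p_err = (
            model.error_prob_incompatible
            if pairing == "poor_good"
            else model.error_prob_base
        )
        err = (rng.random(n) < p_err).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "block": block,
                    "trial_index": np.arange(n),
                    "latency_ms": lat,
                    "error": err,
                    "pairing": pairing,
                    "order_condition": order_condition,
                    "attribute_set": attribute_set,
                }
            )
        )
    trials = pd.concat(rows, ignore_index=True)
    if archetype is not None:
        trials = CARELESS_ARCHETYPES[archetype](trials, rng)
    trials["latency_ms"] = trials["latency_ms"].round().astype(int)
    return trials


# --- careless archetypes: each reliably trips one exclusion criterion ------


def _fast_responder(trials: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """>=35% of responses under 300 ms in a practice block (criterion 1)."""
    out = trials.copy()
    mask = (out["block"] == 3) & (out["trial_index"] < 8)  # 8/20 = 40%
    out.loc[mask, "latency_ms"] = rng.integers(160, 290, size=int(mask.sum())).astype(
        float
    )
    return out


def _high_error(trials: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """>=50% error rate in a practice block (criterion 4)."""
    out = trials.copy()
    mask = (out["block"] == 6) & (out["trial_index"] < 12)  # 12/20 = 60%
    out.loc[mask, "error"] = 1
    return out


def _ultra_slow(trials: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """>=10% of critical-block responses over 10 000 ms (criterion 8)."""
    out = trials.copy()
    mask = (out["block"].isin(cfg.CRITICAL_BLOCKS)) & (out["trial_index"] < 5)
    # 10/80 pooled critical trials above the ceiling
    out.loc[mask, "latency_ms"] = rng.integers(10500, 14000, size=int(mask.sum())).astype(
        float
    )
    return out


CARELESS_ARCHETYPES = {
    "fast_responder": _fast_responder,
    "high_error": _high_error,
    "ultra_slow": _ultra_slow,
}


# ---------------------------------------------------------------------------
# Explicit measures
# ---------------------------------------------------------------------------

# per-measure generation recipe: (scale lo, scale hi, item plan)
# item plans: 'per_target' -> k items each for rich and poor;
# 'both' -> k items on a single bipolar/mean scale (no rich/poor split);
# 'monopolar' -> pos and neg items for each target (ambivalence).
_MEASURE_PLANS = {
    1: ("personal_evaluations", 1, 10, "per_target", 1),
    2: ("others_evaluations", -3, 3, "both", (3, 4)),
    3: ("cultural_evaluations", 1, 10, "per_target", 1),
    4: ("internal_pressure", 1, 6, "per_target", 1),
    5: ("others_pressure", 1, 6, "per_target", 2),
    6: ("cultural_pressure", 1, 6, "per_target", 2),
    7: ("ambivalence", 1, 6, "monopolar", 1),
    9: ("relative_preference", -3, 3, "both", 1),
    10: ("gut_reactions", 1, 10, "per_target", 1),
    11: ("actual_feelings", 1, 10, "per_target", 1),
    12: ("polarity", 1, 6, "both", 2),
    13: ("identity", 1, 6, "per_target", 1),
    14: ("self_concept_centrality", 1, 6, "per_target", 1),
}

#: default mean of each final measure (post reverse-coding, rich-minus-poor
#: difference where applicable); pilot-sample descriptive means.
DEFAULT_MEASURE_OFFSETS = {
    1: 0.706, 2: -1.022, 3: -2.988, 4: 0.691, 5: -0.141, 6: 0.031,
    7: 0.034, 9: -0.019, 10: 0.327, 11: 0.594, 12: 2.680, 13: 0.051,
    14: 0.945,
}

#: measures whose raw responses are negated before analysis
REVERSE_CODED_MEASURES = (2, 9)


def _clipped_round(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return np.clip(np.rint(x), lo, hi).astype(int)


def generate_explicit_items(
    participant_id: str,
    rng: np.random.Generator,
    offsets: dict | None = None,
    item_sd: float = 1.2,
) -> pd.DataFrame:
    """Item-level explicit ratings for measures 1-14 for one participant.

    Offsets are expressed on the final measure scale; for difference
    measures the rich-vs-poor offset is split symmetrically about the
    scale midpoint, and reverse-coded measures are generated so the
    post-coding mean matches the offset.
    """
    offsets = {**DEFAULT_MEASURE_OFFSETS, **(offsets or {})}
    rows = []
    for code, (name, lo, hi, plan, k) in _MEASURE_PLANS.items():
        off = offsets.get(code, 0.0)
        mid = (lo + hi) / 2
        if plan == "per_target":
            n_items = k
            for target, sign in (("rich", +0.5), ("poor", -0.5)):
                vals = rng.normal(mid + sign * off, item_sd, size=n_items)
                for j, v in enumerate(_clipped_round(vals, lo, hi)):
                    rows.append((participant_id, code, f"{name}_{target}_{j + 1}",
                                 target, v))
        elif plan == "both":
            n_items = int(rng.integers(k[0], k[1] + 1)) if isinstance(k, tuple) else k
            centre = -off if code in REVERSE_CODED_MEASURES else off
            base = mid if code == 12 else 0.0  # polarity is a plain mean
            if code == 12:
                centre = off  # offset already on the 1-6 scale
                base = 0.0
            vals = rng.normal(base + centre, item_sd, size=n_items)
            for j, v in enumerate(_clipped_round(vals, lo, hi)):
                rows.append((participant_id, code, f"{name}_{j + 1}", "both", v))
        elif plan == "monopolar":
            # ambivalence: generate pos/neg intensities; the offset nudges
            # the rich-minus-poor ambivalence difference upward via a
            # slightly higher minimum intensity for the rich target.
            for target, sign in (("rich", +0.5), ("poor", -0.5)):
                pos = rng.normal(4.0 + sign * off * 3, item_sd)
                neg = rng.normal(3.0 + sign * off * 3, item_sd)
                rows.append((participant_id, code, f"{name}_{target}_pos",
                             target, _clipped_round(np.array([pos]), lo, hi)[0]))
                rows.append((participant_id, code, f"{name}_{target}_neg",
                             target, _clipped_round(np.array([neg]), lo, hi)[0]))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "measure_code", "item_code", "target", "response"],
    )


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


def _design_row(gender_code: float, iz: float, ez: float) -> np.ndarray:
    g, i, e = gender_code, iz, ez
    return np.array([1.0, g, i, e, g * i, g * e, i * e, g * i * e])


def generate_cohort(
    config: CohortConfig,
    latency_model: LatencyModel | None = None,
    measure_offsets: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate the three cohort tables: trials, demographics, explicit.

    True D per participant is the omnibus linear predictor (on z-scored
    income/education and +-0.5 gender) plus normal residual noise, then
    encoded into trial latencies. Careless participants are drawn at the
    configured rate and assigned a random archetype.
    """
    rng = np.random.default_rng(config.seed)
    if latency_model is None:
        latency_model = LatencyModel()
    demog = generate_demographics(config, rng)
    n = len(demog)

    iz = _zscore_or_zero(demog["income_true"].to_numpy(float))
    ez = _zscore_or_zero(demog["education_true"].to_numpy(float))
    gcode = demog["gender"].map(cfg.GENDER_CODES).to_numpy(float)
    beta = np.array([config.coef_vector[t] for t in cfg.OMNIBUS_TERMS])
    X = np.column_stack(
        [np.ones(n), gcode, iz, ez, gcode * iz, gcode * ez, iz * ez, gcode * iz * ez]
    )
    sd = 1.0 if config.residual_sd is None else config.residual_sd
    true_d = X @ beta + rng.normal(0.0, sd, size=n)

    careless = rng.random(n) < config.careless_rate
    archetype_names = sorted(CARELESS_ARCHETYPES)
    archetypes = rng.choice(archetype_names, size=n)

    order = np.where(rng.random(n) < 0.5, "congruent_first", "incongruent_first")
    attr = np.where(rng.random(n) < 157 / 175, 1, 2)

    trial_tables = []
    explicit_tables = []
    for i, pid in enumerate(demog["participant_id"]):
        trial_tables.append(
            generate_iat_trials(
                pid,
                latency_model,
                float(true_d[i]),
                rng,
                order_condition=str(order[i]),
                attribute_set=int(attr[i]),
                archetype=str(archetypes[i]) if careless[i] else None,
            )
        )
        explicit_tables.append(generate_explicit_items(pid, rng, measure_offsets))

    demog_out = demog.drop(columns=["income_true", "education_true"])
    return {
        "trials": pd.concat(trial_tables, ignore_index=True),
        "demographics": demog_out,
        "explicit": pd.concat(explicit_tables, ignore_index=True),
        "truth": pd.DataFrame(
            {"participant_id": demog["participant_id"], "true_d": true_d,
             "careless": careless}
        ),
    }


def _zscore_or_zero(x: np.ndarray) -> np.ndarray:
    s = np.std(x, ddof=1)
    if s == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / s


def write_cohort(tables: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    """Write trials.csv, demographics.csv and explicit.csv (UTF-8, headers)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("trials", "demographics", "explicit"):
        tables[name].to_csv(outdir / f"{name}.csv", index=False)
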