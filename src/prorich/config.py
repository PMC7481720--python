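"""Shared constants and flat key-value configuration.

Every analysis constant (latency cutoffs, error penalty, exclusion
thresholds, simple-slope evaluation points, alpha, replication counts) is
surfaced here so a run can be reconfigured from a single flat config file.
Defaults are the values used throughout the rich--poor IAT analysis.
"""

from __future__ import annotations

from pathlib import Path

import yaml

# ---------------------------------------------------------------------------
# IAT task structure
# ---------------------------------------------------------------------------

#: trials per block; blocks 1, 2 introduce categories, block 5 is the key
#: transition block, 3/6 are 20-trial dual-task practice blocks, 4/7 the
#: 40-trial critical blocks.
BLOCK_SIZES = {1: 20, 2: 20, 3: 20, 4: 40, 5: 20, 6: 20, 7: 40}

SCORED_BLOCKS = (3, 4, 6, 7)
PRACTICE_BLOCKS = (3, 6)
CRITICAL_BLOCKS = (4, 7)

#: latency ceiling: trials strictly above this are dropped before scoring
MAX_LATENCY_MS = 10_000
#: fast-response cutoff used by the careless-responding criteria
FAST_LATENCY_MS = 300
#: penalty added to the block mean when replacing an error latency
ERROR_PENALTY_MS = 600
#: hard floor for generated latencies
MIN_LATENCY_MS = 150

# ---------------------------------------------------------------------------
# Participant-level exclusion thresholds (inclusive percentages)
# ---------------------------------------------------------------------------

EXCLUSION_THRESHOLDS_PCT = {
    "c1": 35,  # fast responses in any one practice block
    "c2": 25,  # fast responses in any one critical block
    "c3": 10,  # fast responses pooled over critical blocks
    "c4": 50,  # error rate in any one practice block
    "c5": 40,  # error rate pooled over practice blocks
    "c6": 40,  # error rate in any one critical block
    "c7": 30,  # error rate pooled over critical blocks
    "c8": 10,  # >10 s responses pooled over critical blocks
}

# ---------------------------------------------------------------------------
# Regression / power analysis
# ---------------------------------------------------------------------------

#: model terms of the full-interaction omnibus model, in canonical order
OMNIBUS_TERMS = ("intercept", "G", "I", "E", "GI", "GE", "IE", "GIE")

#: gender contrast coding: the interaction coefficient then equals the
#: men-minus-women slope difference and the gender term the difference at
#: mean income/education.
GENDER_CODES = {"f": -0.5, "m": +0.5}

#: simple slopes are evaluated this many SD above/below the mean
EVAL_POINT_SD = 1.5

ALPHA = 0.05
N_REPS_DEFAULT = 1000
VIF_THRESHOLD = 10.0

# ---------------------------------------------------------------------------
# Pilot-sample characteristics (the study conditions the generator emulates)
# ---------------------------------------------------------------------------

PILOT_N = 175
PILOT_N_WOMEN = 115
PILOT_PROP_WOMEN = 115 / 175
PILOT_R_INCOME_EDUCATION = 0.22

#: marginal counts of the 5-point income / education scales in the pilot
#: analysis sample (n = 175)
PILOT_INCOME_COUNTS = (35, 42, 39, 42, 17)
PILOT_EDUCATION_COUNTS = (2, 11, 54, 71, 37)

#: omnibus coefficients on the standardized-outcome scale, reconstructed
#: from the pilot simple effects under the +-0.5 gender coding
PILOT_COEFS = {
    "intercept": 0.0,
    "G": 0.084,
    "I": 0.040,
    "E": 0.111,
    "GI": 0.132,
    "GE": 0.0455,
    "IE": -0.036,
    "GIE": -0.089,
}

#: printed standard error of the Gender x Income coefficient at the pilot
#: design; the generator's residual SD is calibrated against it
PILOT_SE_GI = 0.055

#: sample sizes per simulated dataset for the projected (stage 1) and the
#: observed final-sample (stage 2) power runs
STAGE1_N = 1000
STAGE2_N = 767

# pre-exclusion pilot accounting: 274 entered, 46 tripped the IAT criteria,
# then 49 / 4 / 0 were missing income / education / gender, leaving 175
PILOT_PREEXCLUSION_N = 274
PILOT_EXCLUSION_COUNTS = {
    "iat_criteria": 46,
    "missing_income": 49,
    "missing_education": 4,
    "missing_gender": 0,
}


DEFAULT_CONFIG = {
    "seed": None,  # mandatory: must be set in the file or on the CLI
    "n_participants": PILOT_N,
    "prop_women": PILOT_PROP_WOMEN,
    "income_education_corr": PILOT_R_INCOME_EDUCATION,
    "residual_sd": None,  # None -> calibrate against PILOT_SE_GI
    "careless_rate": 0.0,
    "missing_income_rate": 0.0,
    "missing_education_rate": 0.0,
    "max_latency_ms": MAX_LATENCY_MS,
    "fast_latency_ms": FAST_LATENCY_MS,
    "error_penalty_ms": ERROR_PENALTY_MS,
    "eval_point_sd": EVAL_POINT_SD,
    "alpha": ALPHA,
    "n_reps": N_REPS_DEFAULT,
    "power_n": STAGE1_N,
    "vif_threshold": VIF_THRESHOLD,
}
# coefficient defaults are flattened as coef_<term>
DEFAULT_CONFIG.update({f"coef_{k}": v for k, v in PILOT_COEFS.items()})


def load_config(path: str | Path) -> dict:
    """Read a flat key-value config file (YAML mapping of scalars)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must be a flat key-value mapping")
    for key, value in raw.items():
        if isinstance(value, (dict, list)):
            raise ValueError(f"config key {key!r} is nested; config must be flat")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(raw)
    if cfg.get("seed") is None:
        raise ValueError("config must set an integer 'seed'")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def coef_vector_from_config(cfg: dict) -> dict:
    return {term: float(cfg[f"coef_{term}"]) for term in OMNIBUS_TERMS}
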