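"""Improved-algorithm IAT D scoring.

The D score summarises the latency cost of responding when the poor
category shares a key with the positive attribute, relative to the
rich+positive pairing, scaled by a pooled latency SD so it behaves like a
Cohen's d. The algorithm, applied to the four dual-categorization blocks:

1. use all trials from blocks 3, 4, 6 and 7;
2. drop trials with latencies exceeding 10 000 ms (strictly above);
3. compute each block's mean of correct latencies;
4. compute one pooled SD over all retained trials (correct and incorrect)
   of blocks 3+6 and another over blocks 4+7 -- before any replacement;
5. replace each error latency by its block's correct mean + 600 ms;
6. compute each block's adjusted mean;
7. form the differences (poor+good block - rich+good block) within the
   practice pair (3/6) and the critical pair (4/7);
8. divide each difference by its pooled SD;
9. average the two quotients.

Signs follow pairing roles, not presentation order, so counterbalancing
the block order leaves the expected score unchanged. Positive D means
faster responding when rich is paired with good (pro-rich bias).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import config as cfg

__all__ = ["DScore", "UndefinedScoreError", "DegenerateInputError",
           "score_iat", "score_cohort", "write_scores"]


class UndefinedScoreError(ValueError):
    """A scored block is empty (or has no correct trial) after exclusions."""


class DegenerateInputError(ValueError):
    """All latencies of a block pair are identical: pooled SD is zero."""


@dataclasses.dataclass
class DScore:
    d: float
    quotient_practice: float
    quotient_critical: float
    pooled_sd_36: float
    pooled_sd_47: float
    n_trials_over_10s_removed: int


def _pair_quotient(
    trials: pd.DataFrame, blocks: tuple[int, int], max_latency_ms: float,
    penalty_ms: float,
) -> tuple[float, float]:
    """Adjusted-mean difference (poor_good - rich_good) over pooled SD for
    one block pair. Returns (quotient, pooled_sd)."""
    sub = trials[trials["block"].isin(blocks)]
    retained = sub[sub["latency_ms"] <= max_latency_ms]

    adjusted_means: dict[int, float] = {}
    pairing_of: dict[int, str] = {}
    for block in blocks:
        blk = retained[retained["block"] == block]
        if len(blk) < 2:
            raise UndefinedScoreError(
                f"block {block} has {len(blk)} trials after the "
                f"{max_latency_ms:g} ms exclusion; need at least 2"
            )
        correct = blk.loc[blk["error"] == 0, "latency_ms"]
        if correct.empty:
            raise UndefinedScoreError(f"block {block} has no correct trials")
        mean_correct = float(correct.mean())
        lat = blk["latency_ms"].to_numpy(float).copy()
        lat[blk["error"].to_numpy() == 1] = mean_correct + penalty_ms
        adjusted_means[block] = float(lat.mean())
        pairing = blk["pairing"].unique()
        if len(pairing) != 1:
            raise ValueError(f"block {block} has mixed pairing labels: {pairing}")
        pairing_of[block] = pairing[0]

    pooled_sd = float(np.std(retained["latency_ms"].to_numpy(float), ddof=1))
    if pooled_sd == 0.0:
        raise DegenerateInputError(
            f"all latencies identical in blocks {blocks}; pooled SD is zero"
        )

    roles = set(pairing_of.values())
    if roles != {"rich_good", "poor_good"}:
        raise ValueError(
            f"blocks {blocks} must carry one rich_good and one poor_good "
            f"pairing, got {pairing_of}"
        )
    poor_block = next(b for b, p in pairing_of.items() if p == "poor_good")
    rich_block = next(b for b, p in pairing_of.items() if p == "rich_good")
    diff = adjusted_means[poor_block] - adjusted_means[rich_block]
    return diff / pooled_sd, pooled_sd


def score_iat(
    trials: pd.DataFrame,
    max_latency_ms: float = cfg.MAX_LATENCY_MS,
    penalty_ms: float = cfg.ERROR_PENALTY_MS,
) -> DScore:
    """Score one participant's trials (blocks 3, 4, 6, 7 required)."""
    scored = trials[trials["block"].isin(cfg.SCORED_BLOCKS)]
    missing = set(cfg.SCORED_BLOCKS) - set(scored["block"].unique())
    if missing:
        raise UndefinedScoreError(f"missing scored blocks: {sorted(missing)}")
    n_removed = int((scored["latency_ms"] > max_latency_ms).sum())
    q_practice, sd36 = _pair_quotient(
        scored, cfg.PRACTICE_BLOCKS, max_latency_ms, penalty_ms
    )
    q_critical, sd47 = _pair_quotient(
        scored, cfg.CRITICAL_BLOCKS, max_latency_ms, penalty_ms
    )
    return DScore(
        d=(q_practice + q_critical) / 2.0,
        quotient_practice=q_practice,
        quotient_critical=q_critical,
        pooled_sd_36=sd36,
        pooled_sd_47=sd47,
        n_trials_over_10s_removed=n_removed,
    )


def score_cohort(trials: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Score every participant in a trials table; one row per participant."""
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        s = score_iat(sub, **kwargs)
        rows.append(
            {
                "participant_id": pid,
                "d": s.d,
                "quotient_practice": s.quotient_practice,
                "quotient_critical": s.quotient_critical,
                "pooled_sd_36": s.pooled_sd_36,
                "pooled_sd_47": s.pooled_sd_47,
                "n_trials_over_10s_removed": s.n_trials_over_10s_removed,
            }
        )
    return pd.DataFrame(rows)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)
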