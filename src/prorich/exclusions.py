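"""Participant-level exclusion cascade with audit logging.

Order of attribution: duplicate IDs (keep the earliest record), then the
eight careless-responding criteria evaluated on the raw administered
trials, then demographic completeness in the fixed order income ->
education -> gender. All criteria are always evaluated; only the
first-matching attribution (for the accounting log) follows this order.

The eight latency/error criteria, all inclusive (>=) at the printed
thresholds and computed as exact rationals to avoid floating-point
boundary artifacts:

1. >= 35% of responses under 300 ms in any one practice block;
2. >= 25% under 300 ms in any one critical block;
3. >= 10% under 300 ms pooled over critical blocks;
4. >= 50% error rate in any one practice block;
5. >= 40% error rate pooled over practice blocks;
6. >= 40% error rate in any one critical block;
7. >= 30% error rate pooled over critical blocks;
8. >= 10% of responses over 10 000 ms pooled over critical blocks.

"Practice blocks" are the dual-categorization practice blocks (3 and 6 by
default) and "critical blocks" the 40-trial blocks (4 and 7); both sets
are configurable.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

from . import config as cfg

__all__ = [
    "deduplicate",
    "apply_iat_criteria",
    "apply_demographic_exclusions",
    "run_cascade",
    "summarize_cascade",
]

CRITERIA = tuple(f"c{i}" for i in range(1, 9))
DEMOGRAPHIC_ORDER = ("missing_income", "missing_education", "missing_gender")


def deduplicate(participants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep one record per participant_id: the earliest by timestamp.

    Returns (kept, dropped). Raises on unparseable timestamps, naming the
    offending row.
    """
    ts = pd.to_datetime(participants["timestamp"], errors="coerce")
    if ts.isna().any():
        bad = participants.loc[ts.isna()].iloc[0]
        raise ValueError(
            f"unparseable timestamp {bad['timestamp']!r} for participant "
            f"{bad['participant_id']!r}"
        )
    order = participants.assign(_ts=ts).sort_values(
        ["participant_id", "_ts"], kind="mergesort"
    )
    kept = order.drop_duplicates("participant_id", keep="first")
    dropped = order.loc[~order.index.isin(kept.index)]
    return (
        kept.drop(columns="_ts").sort_index(),
        dropped.drop(columns="_ts").sort_index(),
    )


def _frac(count: int, total: int) -> Fraction:
    return Fraction(int(count), int(total))


def _block_stats(trials: pd.DataFrame, fast_ms: float, slow_ms: float):
    """Per-block (n, n_fast, n_error, n_slow) counts."""
    out = {}
    for block, blk in trials.groupby("block"):
        n = len(blk)
        if n == 0:
            raise ValueError(f"block {block} has zero trials")
        out[int(block)] = (
            n,
            int((blk["latency_ms"] < fast_ms).sum()),
            int((blk["error"] == 1).sum()),
            int((blk["latency_ms"] > slow_ms).sum()),
        )
    return out


def apply_iat_criteria(
    trials: pd.DataFrame,
    practice_blocks=cfg.PRACTICE_BLOCKS,
    critical_blocks=cfg.CRITICAL_BLOCKS,
    thresholds_pct: dict | None = None,
    fast_ms: float = cfg.FAST_LATENCY_MS,
    slow_ms: float = cfg.MAX_LATENCY_MS,
) -> pd.DataFrame:
    """Evaluate criteria 1-8 for every participant in a trials table.

    Returns one row per participant with boolean columns c1..c8 and the
    underlying proportions (as floats, for reporting; decisions use exact
    rationals).
    """
    thr = {k: Fraction(v, 100) for k, v in (thresholds_pct or cfg.EXCLUSION_THRESHOLDS_PCT).items()}
    needed = set(practice_blocks) | set(critical_blocks)
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        present = set(sub["block"].unique())
        missing = needed - present
        if missing:
            raise ValueError(
                f"participant {pid!r} is missing blocks {sorted(missing)}"
            )
        stats = _block_stats(sub[sub["block"].isin(needed)], fast_ms, slow_ms)
        prac = [stats[b] for b in practice_blocks]
        crit = [stats[b] for b in critical_blocks]

        fast_prac = [_frac(f, n) for n, f, _, _ in prac]
        fast_crit = [_frac(f, n) for n, f, _, _ in crit]
        err_prac = [_frac(e, n) for n, _, e, _ in prac]
        err_crit = [_frac(e, n) for n, _, e, _ in crit]
        fast_crit_pooled = _frac(sum(f for _, f, _, _ in crit), sum(n for n, *_ in crit))
        err_prac_pooled = _frac(sum(e for _, _, e, _ in prac), sum(n for n, *_ in prac))
        err_crit_pooled = _frac(sum(e for _, _, e, _ in crit), sum(n for n, *_ in crit))
        slow_crit_pooled = _frac(sum(s for *_, s in crit), sum(n for n, *_ in crit))

        flags = {
            "c1": max(fast_prac) >= thr["c1"],
            "c2": max(fast_crit) >= thr["c2"],
            "c3": fast_crit_pooled >= thr["c3"],
            "c4": max(err_prac) >= thr["c4"],
            "c5": err_prac_pooled >= thr["c5"],
            "c6": max(err_crit) >= thr["c6"],
            "c7": err_crit_pooled >= thr["c7"],
            "c8": slow_crit_pooled >= thr["c8"],
        }
        rows.append(
            {
                "participant_id": pid,
                **flags,
                "fast_prop_practice_max": float(max(fast_prac)),
                "fast_prop_critical_max": float(max(fast_crit)),
                "fast_prop_critical_pooled": float(fast_crit_pooled),
                "error_rate_practice_max": float(max(err_prac)),
                "error_rate_practice_pooled": float(err_prac_pooled),
                "error_rate_critical_max": float(max(err_crit)),
                "error_rate_critical_pooled": float(err_crit_pooled),
                "slow_prop_critical_pooled": float(slow_crit_pooled),
            }
        )
    return pd.DataFrame(rows)


def apply_demographic_exclusions(participants: pd.DataFrame) -> pd.DataFrame:
    """Flag missing demographics, attributed in the order income ->
    education -> gender (a participant missing several counts under the
    first). An income response of 'I don't know' counts as missing."""
    inc = participants["income_level"]
    missing_income = inc.isna() | inc.astype("string").str.lower().isin(
        ["dk", "i don't know", "dont_know"]
    ).fillna(False)
    missing_education = participants["education_level"].isna()
    missing_gender = (
        participants["gender"].isna()
        | ~participants["gender"].astype("string").isin(["f", "m"])
    )
    first = np.select(
        [missing_income, missing_education, missing_gender],
        list(DEMOGRAPHIC_ORDER),
        default="none",
    )
    return pd.DataFrame(
        {
            "participant_id": participants["participant_id"].to_numpy(),
            "missing_income": missing_income.to_numpy(),
            "missing_education": missing_education.to_numpy(),
            "missing_gender": missing_gender.to_numpy(),
            "demographic_exclusion": first,
        }
    )


def run_cascade(
    trials: pd.DataFrame,
    demographics: pd.DataFrame,
    **criteria_kwargs,
) -> pd.DataFrame:
    """Full exclusion report: one row per input demographic record.

    Columns: per-criterion flags and statistics, all_matching_criteria,
    first_matching_criterion (duplicate_id, c1..c8, missing_income,
    missing_education, missing_gender or none) and excluded.
    """
    kept, dropped = deduplicate(demographics)
    iat = apply_iat_criteria(
        trials[trials["participant_id"].isin(kept["participant_id"])],
        **criteria_kwargs,
    )
    demo = apply_demographic_exclusions(kept)
    report = kept[["participant_id"]].merge(iat, on="participant_id", how="left")
    report = report.merge(demo, on="participant_id", how="left")

    crit_flags = report[list(CRITERIA)].fillna(False).astype(bool)
    demo_flags = report[list(DEMOGRAPHIC_ORDER)].fillna(False).astype(bool)
    all_flags = pd.concat([crit_flags, demo_flags], axis=1)

    def first_match(row):
        for name in CRITERIA + DEMOGRAPHIC_ORDER:
            if row[name]:
                return name
        return "none"

    report["all_matching_criteria"] = all_flags.apply(
        lambda r: ";".join(n for n in r.index if r[n]), axis=1
    )
    report["first_matching_criterion"] = all_flags.apply(first_match, axis=1)

    if len(dropped):
        dup = pd.DataFrame(
            {
                "participant_id": dropped["participant_id"].to_numpy(),
                "all_matching_criteria": "duplicate_id",
                "first_matching_criterion": "duplicate_id",
            }
        )
        report = pd.concat([report, dup], ignore_index=True)
    report["excluded"] = report["first_matching_criterion"] != "none"
    return report


def summarize_cascade(report: pd.DataFrame) -> pd.DataFrame:
    """Accounting summary in the study's reporting order: duplicates, the
    IAT criteria as a single group, then income, education, gender."""
    first = report["first_matching_criterion"]
    n_in = len(report)
    rows = [("input", n_in)]
    rows.append(("duplicate_id", int((first == "duplicate_id").sum())))
    rows.append(("iat_criteria", int(first.isin(CRITERIA).sum())))
    for name in DEMOGRAPHIC_ORDER:
        rows.append((name, int((first == name).sum())))
    rows.append(("retained", int((first == "none").sum())))
    return pd.DataFrame(rows, columns=["stage", "n"])
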