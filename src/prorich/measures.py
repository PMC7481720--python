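"""Explicit self-report measures: difference scores, ambivalence,
descriptive t-tests and correlations with the IAT D score.

Fourteen measures are scored from item-level ratings. Most are
rich-minus-poor difference scores after averaging multi-item components
within each target; others' evaluations (2) and relative preference (9)
are reverse-coded; polarity (12) is the plain mean of its two items (and
is tested against its scale midpoint 3.5 rather than 0); the monopolar
ambivalence measure (7/8) applies the index

    ambivalence = min(pos, neg) / (6 + max(pos, neg) - min(pos, neg))

to each target before differencing, giving greater weight to intense than
to mild mixed evaluations. Measures 15-18 are parsed but never scored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ambivalence",
    "build_measures",
    "one_sample_test",
    "correlate_with_d",
    "table3",
    "table4",
    "MEASURE_NAMES",
]

MEASURE_NAMES = {
    1: "personal_evaluations",
    2: "others_evaluations",
    3: "cultural_evaluations",
    4: "internal_pressure",
    5: "others_pressure",
    6: "cultural_pressure",
    7: "ambivalence",
    9: "relative_preference",
    10: "gut_reactions",
    11: "actual_feelings",
    12: "polarity",
    13: "identity",
    14: "self_concept_centrality",
}

REVERSE_CODED = (2, 9)
#: measures that are a plain mean of their items (no rich/poor differencing)
MEAN_ONLY = (12,)
#: the null value each measure is tested against (scale midpoint for polarity)
TEST_MU = {code: 0.0 for code in MEASURE_NAMES}
TEST_MU[12] = 3.5
#: item-level codes present in the data but never analysed
UNSCORED_MEASURES = (15, 16, 17, 18)

_AMBIVALENCE_SCALE = 6


def ambivalence(positive: float, negative: float) -> float:
    """Ambivalence index of a (positive, negative) monopolar rating pair.

    min/(6 + max - min); symmetric in its arguments; ranges from 1/11
    (one intense, one absent) to 1 (both maximal).
    """
    for name, v in (("positive", positive), ("negative", negative)):
        if not (1 <= v <= _AMBIVALENCE_SCALE):
            raise ValueError(f"{name} rating must lie in [1, 6], got {v!r}")
    lo, hi = min(positive, negative), max(positive, negative)
    return lo / (_AMBIVALENCE_SCALE + hi - lo)


def _ambivalence_difference(items: pd.DataFrame) -> tuple[float, int] | None:
    """Ambivalence_rich - Ambivalence_poor from monopolar items, or None
    if either target lacks a pos/neg pair."""
    out = {}
    n_used = 0
    for target in ("rich", "poor"):
        sub = items[items["target"] == target]
        pos = sub.loc[sub["item_code"].str.endswith("_pos"), "response"]
        neg = sub.loc[sub["item_code"].str.endswith("_neg"), "response"]
        if pos.empty or neg.empty:
            return None
        out[target] = ambivalence(float(pos.mean()), float(neg.mean()))
        n_used += len(pos) + len(neg)
    return out["rich"] - out["poor"], n_used


def build_measures(items: pd.DataFrame) -> pd.DataFrame:
    """Score measures 1-14 from an item-level table.

    Expects columns participant_id, measure_code, item_code, target
    ('rich'/'poor'/'both') and response. Multi-item components are
    averaged within target before differencing; participants missing all
    items of a measure get no row for it. Unknown measure codes (other
    than the explicitly unscored 15-18) raise.
    """
    unknown = set(items["measure_code"].unique()) - set(MEASURE_NAMES) - set(
        UNSCORED_MEASURES
    )
    if unknown:
        raise ValueError(f"unknown measure codes: {sorted(unknown)}")
    rows = []
    scored = items[items["measure_code"].isin(MEASURE_NAMES)]
    for (pid, code), sub in scored.groupby(["participant_id", "measure_code"],
                                           sort=True):
        code = int(code)
        if code == 7:
            res = _ambivalence_difference(sub)
            if res is None:
                continue
            value, n_used = res
        elif code in MEAN_ONLY:
            value = float(sub["response"].mean())
            n_used = len(sub)
        else:
            rich = sub.loc[sub["target"] == "rich", "response"]
            poor = sub.loc[sub["target"] == "poor", "response"]
            if code in REVERSE_CODED and sub["target"].eq("both").all():
                value = -float(sub["response"].mean())
                n_used = len(sub)
            else:
                if rich.empty or poor.empty:
                    continue
                value = float(rich.mean()) - float(poor.mean())
                if code in REVERSE_CODED:
                    value = -value
                n_used = len(rich) + len(poor)
        rows.append(
            {
                "participant_id": pid,
                "measure_code": code,
                "value": value,
                "n_items_used": n_used,
            }
        )
    return pd.DataFrame(rows, columns=["participant_id", "measure_code", "value",
                                       "n_items_used"])


def one_sample_test(values, mu: float = 0.0) -> dict:
    """Two-sided one-sample t-test with a 95% CI; df = n - 1."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise ValueError(f"one_sample_test needs at least 2 values, got {n}")
    if np.std(x, ddof=1) == 0.0:
        # degenerate constant vector: t is 0 when the constant equals the
        # null value, infinite otherwise
        m = float(np.mean(x))
        t = 0.0 if m == mu else np.inf * np.sign(m - mu)
        return {"mean": m, "ci_low": m, "ci_high": m, "t": t, "df": n - 1,
                "p": 1.0 if m == mu else 0.0, "n": n}
    res = stats.ttest_1samp(x, popmean=mu)
    ci = res.confidence_interval(0.95)
    return {
        "mean": float(np.mean(x)),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "t": float(res.statistic),
        "df": n - 1,
        "p": float(res.pvalue),
        "n": n,
    }


def correlate_with_d(measure_values, d_scores) -> dict:
    """Pearson correlation on pairwise-complete cases; two-sided p."""
    x = np.asarray(measure_values, dtype=float)
    y = np.asarray(d_scores, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"correlate_with_d needs at least 3 complete pairs, got {n}")
    r, p = stats.pearsonr(x[ok], y[ok])
    return {"r": float(r), "n": n, "p": float(p)}


def table3(measures: pd.DataFrame) -> pd.DataFrame:
    """Per-measure descriptives: mean, 95% CI, t, df, p (one-sample tests
    against 0, or 3.5 for polarity)."""
    rows = []
    for code in sorted(measures["measure_code"].unique()):
        vals = measures.loc[measures["measure_code"] == code, "value"]
        res = one_sample_test(vals, mu=TEST_MU[int(code)])
        rows.append({"measure_code": int(code),
                     "measure": MEASURE_NAMES[int(code)], **res})
    return pd.DataFrame(rows)


def table4(measures: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Per-measure Pearson correlation with the IAT D score."""
    merged = measures.merge(
        scores[["participant_id", "d"]], on="participant_id", how="inner"
    )
    rows = []
    for code in sorted(merged["measure_code"].unique()):
        sub = merged[merged["measure_code"] == code]
        res = correlate_with_d(sub["value"], sub["d"])
        rows.append({"measure_code": int(code),
                     "measure": MEASURE_NAMES[int(code)], **res})
    return pd.DataFrame(rows)
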