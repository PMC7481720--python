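"""Exclusion cascade: trip/boundary fixture pairs for every criterion,
deduplication, demographic ordering and the pilot accounting fixture."""


import pandas as pd
import pytest

from prorich.exclusions import (
    apply_demographic_exclusions,
    apply_iat_criteria,
    deduplicate,
    run_cascade,
    summarize_cascade,
)

from conftest import full_block_trials

# (criterion, kwargs tripping it, kwargs one trial below threshold)
# practice blocks have 20 trials, critical blocks 40 (80 pooled)
CRITERION_FIXTURES = [
    ("c1", dict(fast={3: 7}), dict(fast={3: 6})),          # 35% of 20 = 7
    ("c2", dict(fast={4: 10}), dict(fast={4: 9})),         # 25% of 40 = 10
    ("c3", dict(fast={4: 4, 7: 4}), dict(fast={4: 4, 7: 3})),  # 10% of 80 = 8
    ("c4", dict(errors={6: 10}), dict(errors={6: 9})),     # 50% of 20 = 10
    ("c5", dict(errors={3: 8, 6: 8}), dict(errors={3: 8, 6: 7})),  # 40% of 40
    ("c6", dict(errors={4: 16}), dict(errors={4: 15})),    # 40% of 40 = 16
    ("c7", dict(errors={4: 12, 7: 12}), dict(errors={4: 12, 7: 11})),  # 30% of 80
    ("c8", dict(slow={4: 4, 7: 4}), dict(slow={4: 4, 7: 3})),  # 10% of 80 = 8
]


@pytest.mark.parametrize("criterion,trip,boundary", CRITERION_FIXTURES)
def test_each_criterion_trips_and_respects_boundary(criterion, trip, boundary):
    tripping = full_block_trials(participant_id="trip", **trip)
    below = full_block_trials(participant_id="below", **boundary)
    report = apply_iat_criteria(pd.concat([tripping, below], ignore_index=True))
    report = report.set_index("participant_id")
    assert report.loc["trip", criterion]
    assert not report.loc["below", criterion]
    # a fixture engineered for one criterion must not trip any other
    others = [c for c, *_ in CRITERION_FIXTURES if c != criterion]
    # c2-level fast counts necessarily trip the laxer pooled c3; allow the
    # documented implications, nothing else
    implied = {"c2": {"c3"}, "c4": {"c5"}, "c6": {"c7"}}
    allowed = implied.get(criterion, set())
    for other in others:
        if other not in allowed:
            assert not report.loc["trip", other], (criterion, other)


def test_criterion7_boundary_29_percent_not_excluded():
    """A pooled critical error rate just below 30% survives; exactly 30%
    (inclusive threshold) does not."""
    ok = full_block_trials(participant_id="ok", errors={4: 12, 7: 11})  # 23/80
    out = full_block_trials(participant_id="out", errors={4: 12, 7: 12})  # 24/80
    rep = apply_iat_criteria(pd.concat([ok, out], ignore_index=True))
    rep = rep.set_index("participant_id")
    assert not rep.loc["ok", "c7"] and rep.loc["out", "c7"]


def test_criterion8_pooled_not_per_block():
    """4 of 40 slow trials in one critical block is 10% of that block but
    only 5% pooled: retained. 8 of 80 pooled is excluded."""
    pooled_ok = full_block_trials(participant_id="a", slow={4: 4})
    pooled_out = full_block_trials(participant_id="b", slow={4: 4, 7: 4})
    rep = apply_iat_criteria(pd.concat([pooled_ok, pooled_out],
                                       ignore_index=True))
    rep = rep.set_index("participant_id")
    assert not rep.loc["a", "c8"]
    assert rep.loc["b", "c8"]


def _demog(rows):
    return pd.DataFrame(
        rows,
        columns=["participant_id", "gender", "income_level", "education_level",
                 "timestamp"],
    )


class TestDeduplicate:
    def test_earliest_record_kept(self):
        d = _demog([("p1", "f", 2, 3, "2005-06-02T10:00:00"),
                    ("p1", "f", 2, 3, "2005-06-01T10:00:00")])
        kept, dropped = deduplicate(d)
        assert len(kept) == 1 and len(dropped) == 1
        assert kept.iloc[0]["timestamp"] == "2005-06-01T10:00:00"

    def test_no_duplicates_identity(self):
        d = _demog([("p1", "f", 2, 3, "2005-06-01T10:00:00"),
                    ("p2", "m", 4, 5, "2005-06-01T11:00:00")])
        kept, dropped = deduplicate(d)
        pd.testing.assert_frame_equal(kept, d)
        assert dropped.empty

    def test_triplicate_leaves_one_survivor(self):
        d = _demog([("p1", "f", 2, 3, f"2005-06-0{i}T10:00:00")
                    for i in (3, 1, 2)])
        kept, dropped = deduplicate(d)
        assert len(kept) == 1 and len(dropped) == 2
        assert kept.iloc[0]["timestamp"].startswith("2005-06-01")

    def test_unparseable_timestamp_names_row(self):
        d = _demog([("pX", "f", 2, 3, "not-a-time")])
        with pytest.raises(ValueError, match="pX"):
            deduplicate(d)


class TestDemographicOrder:
    def test_missing_both_counts_under_income(self):
        d = _demog([("p1", "f", None, None, "2005-06-01T10:00:00")])
        rep = apply_demographic_exclusions(d)
        assert rep.iloc[0]["demographic_exclusion"] == "missing_income"

    def test_complete_retained(self):
        d = _demog([("p1", "m", 3, 4, "2005-06-01T10:00:00")])
        rep = apply_demographic_exclusions(d)
        assert rep.iloc[0]["demographic_exclusion"] == "none"

    def test_dont_know_income_is_missing(self):
        d = _demog([("p1", "m", "dk", 4, "2005-06-01T10:00:00")])
        rep = apply_demographic_exclusions(d)
        assert rep.iloc[0]["demographic_exclusion"] == "missing_income"


def _pilot_style_cohort():
    """274 participants engineered to the pilot accounting: 46 trip IAT
    criteria, then 49 missing income, 4 missing education, 0 missing
    gender, leaving 175."""
    rows = []
    trials = []
    ts = pd.date_range("2005-06-01", periods=274, freq="7min")
    for i in range(274):
        pid = f"p{i:04d}"
        if i < 46:  # IAT-criterion exclusions (cycle through archetypes)
            kind = i % 3
            kwargs = [dict(fast={3: 7}), dict(errors={4: 16}),
                      dict(slow={4: 4, 7: 4})][kind]
            trials.append(full_block_trials(participant_id=pid, **kwargs))
            income, edu = 3, 3
        else:
            trials.append(full_block_trials(participant_id=pid))
            # next 49 missing income (some also missing education, which
            # must still count under income), next 4 missing education only
            if i < 46 + 49:
                income = None
                edu = None if i % 5 == 0 else 3
            elif i < 46 + 49 + 4:
                income, edu = 3, None
            else:
                income, edu = (i % 5) + 1, ((i + 2) % 5) + 1
        rows.append((pid, "f" if i % 3 else "m", income, edu,
                     ts[i].isoformat()))
    return pd.concat(trials, ignore_index=True), _demog(rows)


def test_pilot_accounting_fixture_yields_175():
    trials, demog = _pilot_style_cohort()
    report = run_cascade(trials, demog)
    summary = summarize_cascade(report).set_index("stage")["n"]
    assert summary["input"] == 274
    assert summary["iat_criteria"] == 46
    assert summary["missing_income"] == 49
    assert summary["missing_education"] == 4
    assert summary["missing_gender"] == 0
    assert summary["retained"] == 175


def test_cascade_conservation_and_idempotence():
    trials, demog = _pilot_style_cohort()
    report = run_cascade(trials, demog)
    counts = report["first_matching_criterion"].value_counts()
    assert counts.sum() == len(demog)
    assert counts.get("none", 0) + counts.drop("none").sum() == len(demog)
    again = run_cascade(trials, demog)
    pd.testing.assert_frame_equal(report, again)


def test_duplicate_rows_attributed_as_duplicate_id():
    trials, demog = _pilot_style_cohort()
    dup = demog.iloc[[100]].assign(timestamp="2005-06-03T00:00:00")
    report = run_cascade(trials, pd.concat([demog, dup], ignore_index=True))
    assert (report["first_matching_criterion"] == "duplicate_id").sum() == 1
    assert len(report) == len(demog) + 1


def test_missing_block_raises():
    trials = full_block_trials()
    with pytest.raises(ValueError, match="missing blocks"):
        apply_iat_criteria(trials[trials["block"] != 7])
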