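"""Synthetic cohort generator: demographic structure, correlation
calibration, latency/D-score monotonicity, counterbalancing and
determinism."""

import numpy as np
import pandas as pd
import pytest

from prorich import config as cfg
from prorich.cohort import (
    CohortConfig,
    LatencyModel,
    generate_cohort,
    generate_demographics,
    generate_explicit_items,
    generate_iat_trials,
    latent_correlation_for_observed,
    shift_for_target_d,
    write_cohort,
)
from prorich.exclusions import apply_iat_criteria
from prorich.measures import build_measures
from prorich.scoring import score_iat


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(n_participants=0), "n_participants"),
            (dict(prop_women=1.2), "prop_women"),
            (dict(income_education_corr=1.0), "income_education_corr"),
            (dict(income_education_corr=np.nan), "income_education_corr"),
            (dict(careless_rate=-0.1), "careless_rate"),
            (dict(residual_sd=-1.0), "residual_sd"),
        ],
    )
    def test_invalid_values_rejected_by_name(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            CohortConfig(**kwargs)

    def test_latency_model_validation(self):
        with pytest.raises(ValueError, match="log_sd"):
            LatencyModel(log_sd=0.0)


class TestDemographics:
    def test_pilot_gender_ratio(self):
        df = generate_demographics(CohortConfig(seed=11))
        n_women = (df["gender"] == "f").sum()
        # 115 expected of 175; 3 binomial SDs ~ 19
        assert abs(n_women - 115) <= 19

    def test_unique_ids_and_increasing_timestamps(self):
        df = generate_demographics(CohortConfig(n_participants=50, seed=2))
        assert df["participant_id"].is_unique
        ts = pd.to_datetime(df["timestamp"])
        assert ts.is_monotonic_increasing and ts.is_unique

    def test_zero_correlation_case(self):
        df = generate_demographics(
            CohortConfig(n_participants=2000, income_education_corr=0.0, seed=3)
        )
        r = np.corrcoef(df["income_level"].astype(float),
                        df["education_level"].astype(float))[0, 1]
        assert abs(r) <= 2 / np.sqrt(2000)

    def test_discretized_correlation_calibrated_to_target(self):
        """Latent correlation is inflated to undo discretization
        attenuation: the observed 5-level correlation lands on 0.22."""
        rho = latent_correlation_for_observed(0.22)
        assert rho > 0.22  # attenuation means latent > observed
        df = generate_demographics(CohortConfig(n_participants=10_000, seed=4))
        r = np.corrcoef(df["income_level"].astype(float),
                        df["education_level"].astype(float))[0, 1]
        assert r == pytest.approx(0.22, abs=0.03)

    def test_missingness_rates_match_config(self):
        n = 4000
        df = generate_demographics(
            CohortConfig(n_participants=n, missing_income_rate=0.18,
                         missing_education_rate=0.015, seed=5)
        )
        p_inc = df["income_level"].isna().mean()
        p_edu = df["education_level"].isna().mean()
        assert abs(p_inc - 0.18) <= 3 * np.sqrt(0.18 * 0.82 / n)
        assert abs(p_edu - 0.015) <= 3 * np.sqrt(0.015 * 0.985 / n)

    def test_marginal_frequencies_follow_pilot_distribution(self):
        df = generate_demographics(CohortConfig(n_participants=20_000, seed=6))
        obs = df["income_level"].value_counts(normalize=True).sort_index()
        expected = np.array(cfg.PILOT_INCOME_COUNTS) / 175
        np.testing.assert_allclose(obs.to_numpy(), expected, atol=0.02)


class TestIatTrials:
    def test_block_structure(self, rng):
        trials = generate_iat_trials("p1", LatencyModel(), 0.4, rng)
        sizes = trials.groupby("block").size().to_dict()
        assert sizes == cfg.BLOCK_SIZES
        assert (trials["latency_ms"] > 0).all()
        assert set(trials["error"].unique()) <= {0, 1}

    def test_pairing_roles_cover_both_mappings(self, rng):
        for order in ("congruent_first", "incongruent_first"):
            trials = generate_iat_trials("p1", LatencyModel(), 0.0, rng,
                                         order_condition=order)
            scored = trials[trials["block"].isin(cfg.SCORED_BLOCKS)]
            assert set(scored["pairing"]) == {"rich_good", "poor_good"}
            by_block = scored.groupby("block")["pairing"].nunique()
            assert (by_block == 1).all()

    def test_zero_shift_scores_near_zero_on_average(self, rng):
        model = LatencyModel(error_prob_base=0.0, error_prob_incompatible=0.0)
        ds = [
            score_iat(generate_iat_trials(f"p{i}", model, 0.0, rng)).d
            for i in range(120)
        ]
        assert abs(np.mean(ds)) <= 3 * np.std(ds) / np.sqrt(len(ds))

    def test_mean_scored_d_increases_with_shift(self, rng):
        """Calibration curve: mean scored D is strictly increasing over a
        grid of target effect sizes (error-free latencies)."""
        model = LatencyModel(error_prob_base=0.0, error_prob_incompatible=0.0)
        means = []
        for target in (0.0, 0.4, 0.8):
            ds = [
                score_iat(generate_iat_trials(f"p{i}", model, target, rng)).d
                for i in range(500)
            ]
            means.append(np.mean(ds))
        assert means[0] < means[1] < means[2]
        # and the encoded targets are recovered to first order
        assert means[1] == pytest.approx(0.4, abs=0.1)
        assert means[2] == pytest.approx(0.8, abs=0.1)

    def test_counterbalancing_does_not_change_expected_d(self, rng):
        model = LatencyModel(error_prob_base=0.0, error_prob_incompatible=0.0)
        d_by_order = {}
        for order in ("congruent_first", "incongruent_first"):
            ds = [
                score_iat(
                    generate_iat_trials(f"p{i}", model, 0.5, rng,
                                        order_condition=order)
                ).d
                for i in range(300)
            ]
            d_by_order[order] = (np.mean(ds), np.std(ds) / np.sqrt(300))
        (m1, se1), (m2, se2) = d_by_order.values()
        assert abs(m1 - m2) <= 3 * np.hypot(se1, se2)

    def test_shift_solver_monotone_and_signed(self):
        model = LatencyModel()
        assert shift_for_target_d(0.0, model) == 0.0
        assert shift_for_target_d(0.5, model) > 0
        assert shift_for_target_d(-0.5, model) < 0
        with pytest.raises(ValueError):
            shift_for_target_d(np.inf, model)

    @pytest.mark.parametrize(
        "archetype,criterion",
        [("fast_responder", "c1"), ("high_error", "c4"), ("ultra_slow", "c8")],
    )
    def test_each_archetype_trips_its_criterion(self, rng, archetype, criterion):
        trials = generate_iat_trials("p1", LatencyModel(), 0.3, rng,
                                     archetype=archetype)
        report = apply_iat_criteria(trials).iloc[0]
        assert report[criterion]


class TestExplicitItems:
    def test_items_on_documented_scales(self, rng):
        items = generate_explicit_items("p1", rng)
        assert set(items["measure_code"]).issubset(set(range(1, 15)))
        m1 = items[items["measure_code"] == 1]["response"]
        assert m1.between(1, 10).all()
        m2 = items[items["measure_code"] == 2]["response"]
        assert m2.between(-3, 3).all()
        m7 = items[items["measure_code"] == 7]["response"]
        assert m7.between(1, 6).all()

    def test_zero_offsets_give_zero_mean_differences(self, rng):
        zero = {code: 0.0 for code in range(1, 15)}
        items = pd.concat(
            [generate_explicit_items(f"p{i}", rng, offsets=zero)
             for i in range(400)]
        )
        scores = build_measures(items)
        m1 = scores[scores["measure_code"] == 1]["value"]
        assert abs(m1.mean()) <= 3 * m1.std() / np.sqrt(len(m1))

    def test_configured_offset_recovered(self, rng):
        """A +0.7 rich-vs-poor offset on the 1-10 personal-evaluation
        scale is recovered in the mean difference at n = 700."""
        items = pd.concat(
            [generate_explicit_items(f"p{i}", rng, offsets={1: 0.7})
             for i in range(700)]
        )
        scores = build_measures(items)
        m1 = scores[scores["measure_code"] == 1]["value"]
        assert m1.mean() == pytest.approx(0.7, abs=0.1)

    def test_ambivalence_defined_for_all_participants(self, rng):
        items = pd.concat(
            [generate_explicit_items(f"p{i}", rng) for i in range(50)]
        )
        amb = build_measures(items).query("measure_code == 7")["value"]
        assert len(amb) == 50
        assert np.isfinite(amb).all()
        assert amb.between(-1, 1, inclusive="neither").all()


class TestDeterminism:
    def test_same_seed_reproduces_byte_identical_tables(self, tmp_path):
        config = CohortConfig(n_participants=12, careless_rate=0.2,
                              missing_income_rate=0.1, seed=99)
        for sub in ("a", "b"):
            write_cohort(generate_cohort(config), tmp_path / sub)
        for name in ("trials", "demographics", "explicit"):
            a = (tmp_path / "a" / f"{name}.csv").read_bytes()
            b = (tmp_path / "b" / f"{name}.csv").read_bytes()
            assert a == b, name

    def test_different_seeds_differ(self):
        t1 = generate_cohort(CohortConfig(n_participants=5, seed=1))
        t2 = generate_cohort(CohortConfig(n_participants=5, seed=2))
        assert not t1["trials"]["latency_ms"].equals(t2["trials"]["latency_ms"])
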