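"""Synthetic survey generator: reproducibility, calibration, ground truth."""

import numpy as np
import pandas as pd
import pytest

from healthineq import (
    ConfigurationError,
    CovariateSpec,
    RankedSample,
    SimulationConfig,
    concentration_index,
    generate_lpm_population,
    generate_population,
    lpm_ground_truth,
    make_lms_fixture,
)
from healthineq.models import FactorSpec, build_design, fit_lpm
from healthineq.decomposition import decompose_design
from healthineq.synthetic import DEFAULT_COVARIATES


def _no_gradient_config(n, seed):
    """All SES channels off: no direct rank gradient, no covariate latent
    effects, and covariates independent of the wealth rank."""
    flat = {
        sex: tuple(
            CovariateSpec(s.name, s.categories, s.base_logits, tuple(0.0 for _ in s.rank_slopes))
            for s in specs
        )
        for sex, specs in DEFAULT_COVARIATES.items()
    }
    return SimulationConfig(
        n=n, seed=seed, gradient_strength=0.0, covariate_specs=flat, latent_effects={}
    )


class TestConfigValidation:
    def test_nonpositive_n_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n=0)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.7])
    def test_invalid_prevalence_rejected(self, p):
        with pytest.raises(ConfigurationError):
            SimulationConfig(prevalence_targets={"thinness": p, "stunting": 0.3})

    def test_bad_weight_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(weight_scheme="bootstrap")


class TestGeneratePopulation:
    def test_same_seed_byte_identical(self):
        a = generate_population(SimulationConfig(n=500, seed=42))
        b = generate_population(SimulationConfig(n=500, seed=42))
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_different_seed_differs(self):
        a = generate_population(SimulationConfig(n=500, seed=1))
        b = generate_population(SimulationConfig(n=500, seed=2))
        assert not a["wealth_score"].equals(b["wealth_score"])

    def test_prevalence_targets_achieved(self):
        cfg = SimulationConfig(
            n=20_000, seed=5, prevalence_targets={"thinness": 0.25, "stunting": 0.3}
        )
        df = generate_population(cfg)
        assert 0.24 <= df["thinness"].mean() <= 0.26
        assert 0.29 <= df["stunting"].mean() <= 0.31

    def test_quintiles_balanced_under_equal_weights(self):
        df = generate_population(SimulationConfig(n=5003, seed=9))
        counts = df["wealth_quintile"].value_counts()
        assert set(counts.index) == {1, 2, 3, 4, 5}
        assert counts.max() - counts.min() <= 1

    def test_flags_consistent_with_z_scores(self):
        df = generate_population(SimulationConfig(n=2000, seed=13))
        np.testing.assert_array_equal(df["thinness"], (df["z_bmi_age"] < -2).astype(int))
        np.testing.assert_array_equal(df["stunting"], (df["z_height_age"] <= -2).astype(int))
        np.testing.assert_array_equal(df["both"], df["thinness"] & df["stunting"])

    def test_no_ses_dependence_gives_near_zero_index(self):
        df = generate_population(_no_gradient_config(n=20_000, seed=17))
        for outcome in ("thinness", "stunting"):
            c = concentration_index(
                RankedSample.from_scores(
                    df[outcome].to_numpy(float), df["wealth_score"].to_numpy()
                )
            )
            assert abs(c) <= 0.02

    def test_gradient_concentrates_outcomes_among_poor(self):
        df = generate_population(SimulationConfig(n=20_000, seed=19))
        for outcome in ("thinness", "stunting", "both"):
            c = concentration_index(
                RankedSample.from_scores(
                    df[outcome].to_numpy(float), df["wealth_score"].to_numpy()
                )
            )
            assert -0.25 <= c <= -0.04

    def test_tie_fraction_produces_duplicate_scores(self):
        df = generate_population(SimulationConfig(n=1000, seed=23, tie_fraction=0.2))
        assert df["wealth_score"].duplicated().any()
        untied = generate_population(SimulationConfig(n=1000, seed=23))
        assert not untied["wealth_score"].duplicated().any()

    def test_variable_weights_positive_mean_one(self):
        df = generate_population(SimulationConfig(n=1000, seed=29, weight_scheme="variable"))
        assert (df["weight"] > 0).all()
        assert df["weight"].mean() == pytest.approx(1.0)

    def test_sex_split_matches_ratio(self):
        df = generate_population(SimulationConfig(n=20_000, seed=31, sex_ratio=0.29))
        assert df["sex"].eq("boy").mean() == pytest.approx(0.29, abs=0.01)


class TestLPMPopulation:
    def test_all_zero_betas_yield_null_contributions(self):
        df = generate_lpm_population(
            alpha=0.3,
            betas={"a": 0.0, "b": 0.0},
            covariate_dists={"a": ("rank_indicator", 0.8, 1.0), "b": ("bernoulli_rank", 0.0, 1.0)},
            n=50_000,
            seed=3,
        )
        X = df[["a", "b"]].rename(columns={"a": "a:1", "b": "b:1"})
        res = decompose_design(df["outcome"].to_numpy(float), X, df["wealth_score"].to_numpy())
        for row in res.rows:
            assert abs(row.absolute_contribution) <= 0.01

    def test_ols_recovers_generator_coefficient(self):
        beta = 0.2
        df = generate_lpm_population(
            alpha=0.15,
            betas={"top": beta},
            covariate_dists={"top": ("rank_indicator", 0.8, 1.0)},
            n=20_000,
            seed=7,
        )
        X = df[["top"]].rename(columns={"top": "wealth:top"})
        fit = fit_lpm(df["outcome"].to_numpy(float), X)
        est = fit.betas["wealth:top"]
        # binomial standard error of a difference in proportions
        n1 = int(df["top"].sum())
        n0 = len(df) - n1
        p1, p0 = 0.35, 0.15
        se = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
        assert abs(est - beta) < 3 * se

    def test_dominant_factor_percentage_recovered(self):
        # one wealth dummy engineered to carry ~80% of the explained index
        alpha, betas = 0.36, {"wealth_top": -0.22, "other": -0.13}
        dists = {
            "wealth_top": ("rank_indicator", 0.8, 1.0),
            "other": ("bernoulli_rank", -1.0, 2.0),
        }
        df = generate_lpm_population(alpha, betas, dists, n=50_000, seed=11)
        truth = lpm_ground_truth(df, alpha, betas).set_index("covariate")
        X = df[list(betas)].rename(columns={k: f"{k}:1" for k in betas})
        res = decompose_design(df["outcome"].to_numpy(float), X, df["wealth_score"].to_numpy())
        est = {r.factor: r.pct_contribution for r in res.rows}
        assert abs(est["wealth_top"] - truth.loc["wealth_top", "pct"]) <= 5.0

    def test_infeasible_alpha_rejected(self):
        with pytest.raises(ConfigurationError, match="infeasible"):
            generate_lpm_population(1.4, {"a": 0.1}, {"a": ("rank_indicator", 0.5, 1.0)}, 100, 0)

    def test_high_clip_rate_warns(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            generate_lpm_population(
                0.9, {"a": 0.5}, {"a": ("rank_indicator", 0.5, 1.0)}, 2000, 0
            )

    def test_deterministic_given_seed(self):
        kw = dict(
            alpha=0.2,
            betas={"a": 0.1},
            covariate_dists={"a": ("bernoulli_rank", 0.0, 1.0)},
            n=500,
            seed=99,
        )
        assert generate_lpm_population(**kw).equals(generate_lpm_population(**kw))


class TestLMSFixture:
    def test_anchor_row_round_trip(self):
        fx = make_lms_fixture()
        row = fx[(fx.sex == "boy") & (fx.age_months == 120) & (fx.indicator == "bmi_age")]
        assert row[["L", "M", "S"]].iloc[0].tolist() == [1.0, 16.0, 0.1]

    def test_no_duplicate_keys_and_log_branch_present(self):
        fx = make_lms_fixture()
        assert not fx.duplicated(subset=["sex", "age_months", "indicator"]).any()
        assert (fx["L"] == 0).any()
        assert fx["sex"].nunique() == 2
        assert fx["age_months"].nunique() >= 5
        assert set(fx["indicator"]) == {"bmi_age", "height_age"}

    def test_schema_validation_rejects_missing_column(self):
        from healthineq import DomainError, load_reference

        with pytest.raises(DomainError):
            load_reference(make_lms_fixture().drop(columns=["S"]))
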