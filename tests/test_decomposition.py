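"""Wagstaff regression-based decomposition of the concentration index."""

import numpy as np
import pandas as pd
import pytest

from healthineq import (
    DomainError,
    FactorSpec,
    covariate_ci,
    elasticity,
    format_decomposition_table,
    fractional_rank,
    wagstaff_decompose,
)
from healthineq.decomposition import decompose_design, round_half_away


class TestElasticity:
    def test_zero_coefficient_gives_zero(self):
        assert elasticity(0.0, 0.4, 0.2) == 0.0

    def test_direct_arithmetic(self):
        assert elasticity(0.5, 0.4, 0.2) == pytest.approx(1.0)

    def test_outcome_identical_to_covariate_has_unit_elasticity(self):
        assert elasticity(1.0, 0.37, 0.37) == pytest.approx(1.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(DomainError):
            elasticity(0.5, 0.4, 0.0)


class TestCovariateCI:
    def test_top_quintile_dummy_tends_to_point_eight(self):
        n = 20_000
        ranks = (np.arange(n) + 0.5) / n
        x = (ranks > 0.8).astype(float)
        assert covariate_ci(x, ranks) == pytest.approx(0.8, abs=0.02)

    def test_bottom_quintile_dummy_mirrors_to_minus_point_eight(self):
        n = 20_000
        ranks = (np.arange(n) + 0.5) / n
        x = (ranks < 0.2).astype(float)
        assert covariate_ci(x, ranks) == pytest.approx(-0.8, abs=0.02)

    def test_constant_dummy_has_zero_index(self):
        ranks = (np.arange(100) + 0.5) / 100
        assert covariate_ci(np.ones(100), ranks) == pytest.approx(0.0, abs=1e-12)


def _random_dataset(rng, n=1000, n_factors=3):
    records = {}
    specs = []
    for j in range(n_factors):
        k = int(rng.integers(2, 5))
        cats = [f"c{i}" for i in range(k)]
        records[f"f{j}"] = rng.choice(cats, size=n)
        specs.append(FactorSpec(f"f{j}", tuple(cats)))
    frame = pd.DataFrame(records)
    scores = rng.standard_normal(n)
    ranks = fractional_rank(scores)
    latent = 0.8 * (ranks - 0.5) + rng.standard_normal(n)
    y = (latent < np.quantile(latent, 0.3)).astype(float)
    if y.sum() == 0:
        y[0] = 1.0
    weights = rng.random(n) + 0.2
    return y, frame, specs, scores, weights


class TestAddingUpIdentity:
    def test_exact_on_random_datasets(self, rng):
        for _ in range(25):
            y, frame, specs, scores, weights = _random_dataset(rng)
            res = wagstaff_decompose(y, frame, specs, scores, weights)
            assert abs(res.calculated_ci + res.residual - res.actual_ci) < 1e-10
            # the two residual routes are algebraically equal
            assert abs(res.residual - res.residual_from_error) < 1e-10

    def test_percentages_sum_to_hundred_before_rounding(self, rng):
        y, frame, specs, scores, weights = _random_dataset(rng)
        res = wagstaff_decompose(y, frame, specs, scores, weights)
        assert sum(r.pct_contribution for r in res.rows) == pytest.approx(100.0, abs=1e-8)
        assert res.group_totals.sum() == pytest.approx(100.0, abs=1e-8)


class TestDecompositionStructure:
    def test_intercept_only_model_is_all_residual(self, rng):
        n = 500
        scores = rng.standard_normal(n)
        y = (rng.random(n) < 0.3).astype(float)
        res = decompose_design(y, pd.DataFrame(index=range(n)), scores)
        assert res.calculated_ci == 0.0
        assert res.residual == pytest.approx(res.actual_ci, abs=1e-12)

    def test_noiseless_single_covariate_fully_explained(self, rng):
        n = 400
        scores = rng.standard_normal(n)
        ranks = fractional_rank(scores)
        frame = pd.DataFrame({"top": np.where(ranks > 0.75, "yes", "no")})
        y = (frame["top"] == "yes").to_numpy(dtype=float)
        res = wagstaff_decompose(y, frame, [FactorSpec("top", ("no", "yes"))], scores)
        assert len(res.rows) == 1
        assert res.rows[0].absolute_contribution == pytest.approx(res.actual_ci, abs=1e-10)
        assert res.residual == pytest.approx(0.0, abs=1e-10)

    def test_sign_coherence(self, rng):
        # covariate concentrated among the rich with a positive effect on a
        # positive-mean outcome contributes positively
        n = 2000
        scores = rng.standard_normal(n)
        ranks = fractional_rank(scores)
        frame = pd.DataFrame({"rich": np.where(ranks > 0.8, "yes", "no")})
        p = 0.1 + 0.4 * (frame["rich"] == "yes").to_numpy(float)
        y = (rng.random(n) < p).astype(float)
        res = wagstaff_decompose(y, frame, [FactorSpec("rich", ("no", "yes"))], scores)
        row = res.rows[0]
        assert row.covariate_ci > 0
        assert row.elasticity > 0
        assert row.absolute_contribution > 0

    def test_contributions_invariant_to_factor_order(self, rng):
        y, frame, specs, scores, weights = _random_dataset(rng, n=600)
        a = wagstaff_decompose(y, frame, specs, scores, weights)
        b = wagstaff_decompose(y, frame, list(reversed(specs)), scores, weights)
        for row in a.rows:
            match = [r for r in b.rows if (r.factor, r.category) == (row.factor, row.category)]
            assert len(match) == 1
            assert match[0].absolute_contribution == pytest.approx(
                row.absolute_contribution, abs=1e-10
            )

    def test_empty_category_row_flagged_not_crashing(self, rng):
        n = 200
        scores = rng.standard_normal(n)
        frame = pd.DataFrame({"f": ["a"] * n})
        y = (rng.random(n) < 0.4).astype(float)
        res = wagstaff_decompose(y, frame, [FactorSpec("f", ("a", "b"))], scores)
        row = res.rows[0]
        assert np.isnan(row.covariate_ci)
        assert row.absolute_contribution == pytest.approx(0.0, abs=1e-12)

    def test_logit_ape_engine_tags_result_and_balances(self, rng):
        y, frame, specs, scores, weights = _random_dataset(rng, n=800)
        res = wagstaff_decompose(y, frame, specs, scores, weights, engine="logit_ape")
        assert res.engine == "logit_ape"
        # identity still holds by construction of the reported residual
        assert abs(res.calculated_ci + res.residual - res.actual_ci) < 1e-12


class TestFormatting:
    def test_half_away_from_zero_rounding(self):
        assert round_half_away(-0.02334, 3) == pytest.approx(-0.023)
        assert round_half_away(-0.0235, 3) == pytest.approx(-0.024)
        assert round_half_away(0.0235, 3) == pytest.approx(0.024)
        assert round_half_away(2.5, 0) == pytest.approx(3.0)

    def test_printed_cell_is_elasticity_times_covariate_index(self):
        # the table's absolute-contribution cell at 3 d.p.
        assert round_half_away(-0.030 * 0.778, 3) == pytest.approx(-0.023)

    def test_table_layout_and_summary_rows(self, rng):
        y, frame, specs, scores, weights = _random_dataset(rng)
        res = wagstaff_decompose(y, frame, specs, scores, weights)
        table = format_decomposition_table(res, specs)
        # reference rows blank
        refs = table[table["category"].isin([s.reference for s in specs])]
        assert (refs["elasticity"] == "").all()
        tail = table.tail(3)
        assert tail["factor"].tolist() == ["Calculated CI", "Actual CI", "Residual"]
        calc, actual, resid = (float(v) for v in tail["absolute"])
        assert resid == pytest.approx(round_half_away(res.actual_ci - res.calculated_ci, 3), abs=1.5e-3)
        assert actual - calc == pytest.approx(resid, abs=1.5e-3)

    def test_rounded_group_totals_sum_near_hundred(self, rng):
        y, frame, specs, scores, weights = _random_dataset(rng, n=3000, n_factors=4)
        res = wagstaff_decompose(y, frame, specs, scores, weights)
        rounded = [round_half_away(v, 1) for v in res.group_totals]
        assert sum(rounded) == pytest.approx(100.0, abs=0.3)
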