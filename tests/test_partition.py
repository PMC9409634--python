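import numpy as np
import pandas as pd
import pytest

from hrvpart.errors import ParameterError
from hrvpart.partition import (
    all_subsets_r2,
    partition,
    partition_by_levels,
    partition_by_orderings,
    partition_cohort,
    partition_with_repeats,
)
from hrvpart.synth import CohortGenParams, OutcomeSpec, generate_cohort


def _refit_r2(y, X, cols):
    """Independent OLS refit (design-matrix lstsq, not moment algebra)."""
    if not cols:
        return 0.0
    A = np.column_stack([np.ones(len(y))] + [X[:, j] for j in cols])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))


class TestAllSubsetsR2:
    def test_single_predictor_closed_form(self, rng):
        x = rng.standard_normal(100)
        y = 2 * x + rng.standard_normal(100)
        r2 = all_subsets_r2(y, x)
        assert r2[frozenset()] == 0.0
        assert r2[frozenset({0})] == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-10)

    def test_orthogonal_predictors_are_additive(self, rng):
        n = 256
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = x1 + 0.5 * x2 + 0.3 * rng.standard_normal(n)
        r2 = all_subsets_r2(y, np.column_stack([x1, x2]))
        assert r2[frozenset({0, 1})] == pytest.approx(
            r2[frozenset({0})] + r2[frozenset({1})], abs=1e-10
        )

    def test_matches_independent_refit_oracle(self, rng):
        n, k = 150, 3
        L = rng.standard_normal((k, k))
        X = rng.standard_normal((n, k)) @ L  # correlated design
        y = X @ rng.standard_normal(k) + rng.standard_normal(n)
        r2 = all_subsets_r2(y, X)
        for subset, val in r2.items():
            assert val == pytest.approx(_refit_r2(y, X, sorted(subset)), abs=1e-10)

    def test_too_many_predictors_rejected(self, rng):
        with pytest.raises(ParameterError, match="12"):
            all_subsets_r2(rng.standard_normal(50), rng.standard_normal((50, 13)))

    def test_singular_subset_uses_pseudoinverse_with_warning(self, rng):
        x = rng.standard_normal(60)
        X = np.column_stack([x, x])  # exactly collinear
        y = x + rng.standard_normal(60)
        with pytest.warns(UserWarning, match="singular|pseudo"):
            r2 = all_subsets_r2(y, X)
        assert np.isfinite(r2[frozenset({0, 1})])


class TestPartition:
    def test_single_predictor_trivial_decomposition(self, rng):
        x = rng.standard_normal(80)
        y = x + rng.standard_normal(80)
        res = partition(y, x)
        assert res.independent[0] == pytest.approx(res.r2_full, abs=1e-12)
        assert res.joint[0] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_predictors_have_no_joint_part(self, rng):
        n = 200
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = x1 - x2 + 0.5 * rng.standard_normal(n)
        res = partition(y, np.column_stack([x1, x2]))
        r2 = all_subsets_r2(y, np.column_stack([x1, x2]))
        for j in range(2):
            assert res.independent[j] == pytest.approx(r2[frozenset({j})], abs=1e-10)
            assert res.joint[j] == pytest.approx(0.0, abs=1e-10)

    def test_matches_all_orderings_oracle(self, rng):
        n, k = 200, 4
        X = rng.standard_normal((n, k)) @ rng.standard_normal((k, k))
        y = X @ rng.standard_normal(k) + rng.standard_normal(n)
        a = partition(y, X)
        b = partition_by_orderings(y, X)
        np.testing.assert_allclose(a.independent, b.independent, atol=1e-10)

    def test_three_routes_agree(self, rng):
        """Subset weights = level averaging = ordering average."""
        n, k = 150, 5
        X = rng.standard_normal((n, k)) @ rng.standard_normal((k, k))
        y = X @ rng.standard_normal(k) + rng.standard_normal(n)
        a = partition(y, X)
        b = partition_by_levels(y, X)
        c = partition_by_orderings(y, X)
        np.testing.assert_allclose(a.independent, b.independent, atol=1e-10)
        np.testing.assert_allclose(a.independent, c.independent, atol=1e-10)
        np.testing.assert_allclose(a.joint, b.joint, atol=1e-10)

    @pytest.mark.parametrize("k", range(1, 9))
    def test_conservation_sum_i_equals_full_r2(self, k, rng):
        n = 120
        X = rng.standard_normal((n, k)) @ rng.standard_normal((k, k))
        y = X @ rng.standard_normal(k) + rng.standard_normal(n)
        res = partition(y, X)
        assert res.independent.sum() == pytest.approx(res.r2_full, abs=1e-9)
        # I_j + J_j equals the univariate R² of each predictor
        r2 = all_subsets_r2(y, X)
        for j in range(k):
            assert res.independent[j] + res.joint[j] == pytest.approx(
                r2[frozenset({j})], abs=1e-9
            )

    def test_percentage_conventions(self, rng):
        X = rng.standard_normal((100, 3))
        y = X @ np.array([1.0, 0.5, 0.0]) + rng.standard_normal(100)
        res = partition(y, X)
        assert res.i_pct_of_r2.sum() == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_allclose(res.i_pct_absolute, 100 * res.independent)


class TestPartitionWithRepeats:
    def test_repeat_average_equals_single_run(self, rng):
        n, k = 150, 10
        X = rng.standard_normal((n, k)) @ rng.standard_normal((k, k))
        y = X @ rng.standard_normal(k) + rng.standard_normal(n)
        single = partition(y, X)
        repeated = partition_with_repeats(y, X, repeats=10, seed=3)
        np.testing.assert_allclose(repeated.independent, single.independent, atol=1e-9)
        assert repeated.repeats == 10

    def test_seed_is_inert_by_order_invariance(self, rng):
        X = rng.standard_normal((80, 4))
        y = X @ np.ones(4) + rng.standard_normal(80)
        a = partition_with_repeats(y, X, repeats=5, seed=1)
        b = partition_with_repeats(y, X, repeats=5, seed=2)
        np.testing.assert_allclose(a.independent, b.independent, atol=1e-12)


class TestPartitionCohort:
    def test_null_valve_effect_contribution_shrinks_with_n(self):
        """With no effects at all, the valve I is chance-level and decays."""
        spec = OutcomeSpec(
            valve_var="ava", valve_effect=0.0, covariate_effects={
                "age": 0.0, "sbp": 0.0, "mbf": 0.0, "d_mean_nn": 0.0,
            }, noise_sd=0.3,
        )
        means = []
        for n_total in (100, 500, 2000):
            props = np.array([22, 73, 32]) / 127.0
            npg = tuple(np.maximum(1, np.round(props * n_total)).astype(int))
            vals = []
            for seed in range(5):
                df, _ = generate_cohort(
                    CohortGenParams(n_per_group=npg, seed=seed,
                                    outcomes={"d_alpha1": spec})
                )
                row = partition_cohort(
                    df, "d_alpha1", ["ava", "age", "sbp", "mbf", "d_mean_nn"]
                )
                vals.append(row["valve_i_pct_absolute"])
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
        assert means[2] <= 1.0

    def test_row_reports_both_conventions_and_full_r2(self, rng):
        df, _ = generate_cohort(CohortGenParams(seed=0))
        spec_preds = ["ava", "age", "sbp", "mbf", "d_mean_nn"]
        row = partition_cohort(df, "d_alpha1", spec_preds)
        assert row["valve_parameter"] == "ava"
        assert set(row["covariables"]) == {"age", "sbp", "mbf", "d_mean_nn"}
        sub = df[["d_alpha1"] + spec_preds].dropna()
        r2 = all_subsets_r2(sub["d_alpha1"], sub[spec_preds])
        assert row["r2_combined"] == pytest.approx(
            r2[frozenset(range(len(spec_preds)))], abs=1e-12
        )

    def test_missing_columns_rejected(self, rng):
        df = pd.DataFrame({"d_alpha1": rng.standard_normal(30)})
        with pytest.raises(ParameterError):
            partition_cohort(df, "d_alpha1", ["nope"])
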