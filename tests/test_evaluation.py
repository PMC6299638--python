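import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sf6dbayes import evaluation, published
from sf6dbayes.cohort import CohortConfig
from sf6dbayes.evaluation import (
    adjusted_r_squared,
    holdout_validate,
    mean_abs_error,
    predict_state,
    qq_coordinates,
    r_squared,
    rmse,
    select_holdout_states,
)
from sf6dbayes.state_space import PITS

PUBLISHED_DIFFS = np.array(
    [true - mean for true, mean, _ in published.HOLDOUT_TABLE.values()]
)


class TestScalarMetrics:
    def test_r_squared_examples(self):
        y = np.array([0.1, 0.4, 0.9])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
        assert r_squared([0.0, 1.0], [1.0, 0.0]) == pytest.approx(-3.0)

    def test_r_squared_degenerate_inputs(self):
        with pytest.raises(ValueError, match="identical"):
            r_squared([0.5, 0.5], [0.4, 0.6])
        with pytest.raises(ValueError, match="at least 2"):
            r_squared([0.5], [0.4])

    def test_adjusted_r_squared_published_rows(self):
        # published goodness-of-fit column, n=3518, p=25 (p=26 with 'most')
        for model, r2 in published.PUBLISHED_R2.items():
            adj = adjusted_r_squared(r2, 3518, published.MODEL_P[model])
            assert round(adj, 3) == published.PUBLISHED_ADJ_R2[model]

    def test_adjusted_r_squared_edges(self):
        assert adjusted_r_squared(1.0, 100, 5) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="n > p"):
            adjusted_r_squared(0.5, 10, 9)

    def test_rmse_examples(self):
        assert rmse([0.2, 0.4], [0.2, 0.4]) == 0.0
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(2.5 * np.sqrt(2))
        with pytest.raises(ValueError):
            rmse([], [])

    def test_published_holdout_differences(self):
        # hand-recomputed from the printed 4-dp hold-out table
        zero = np.zeros(12)
        assert rmse(PUBLISHED_DIFFS, zero) == pytest.approx(0.100881, abs=1e-6)
        assert mean_abs_error(PUBLISHED_DIFFS, zero) == pytest.approx(
            0.084842, abs=1e-6
        )

    def test_mean_abs_error_symmetry(self):
        assert mean_abs_error([0.1, -0.1], [0.0, 0.0]) == pytest.approx(0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        y=hnp.arrays(float, 10, elements=st.floats(-1, 1)),
        yhat=hnp.arrays(float, 10, elements=st.floats(-1, 1)),
    )
    def test_r2_rmse_consistency(self, y, yhat):
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            return
        lhs = r_squared(y, yhat)
        rhs = 1 - len(y) * rmse(y, yhat) ** 2 / ss_tot
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_metrics_invariant_to_record_order(self):
        rng = np.random.default_rng(30)
        y, yhat = rng.random(50), rng.random(50)
        perm = rng.permutation(50)
        assert r_squared(y, yhat) == pytest.approx(r_squared(y[perm], yhat[perm]))
        assert rmse(y, yhat) == pytest.approx(rmse(y[perm], yhat[perm]))
        assert mean_abs_error(y, yhat) == pytest.approx(
            mean_abs_error(y[perm], yhat[perm])
        )


class TestStatePrediction:
    def test_unity_constraint_exact(self, m4_draws_replica):
        summary = predict_state(m4_draws_replica, "111111")
        assert np.all(summary.draws == 1.0)
        assert summary.mean == 1.0 and summary.sd == 0.0
        assert summary.ci_low == summary.ci_high == 1.0

    def test_shifting_coefficients_moves_prediction(self, m4_draws_replica):
        import copy

        base = predict_state(m4_draws_replica, "645655").mean
        shifted = copy.deepcopy(m4_draws_replica)
        j = shifted.column_names.index("PF6")
        shifted.coef[:, :, j] -= 0.1
        assert predict_state(shifted, "645655").mean == pytest.approx(base - 0.1)

    def test_summary_internally_consistent(self, m4_draws_replica):
        s = predict_state(m4_draws_replica, "645655")
        assert s.ci_low <= s.mean <= s.ci_high
        assert s.sd > 0

    def test_predictions_calibrated_against_generator_truth(
        self, untruncated_analysed, m4_draws_untruncated
    ):
        """On model-class data the population-mean predictions sit within
        3 posterior SDs of the generating truth for nearly every state."""
        from sf6dbayes.cohort import _state_mean_utility

        config = CohortConfig(truncate=False)
        rng = np.random.default_rng(31)
        states = [
            s for s in untruncated_analysed.design_states if s.code != "111111"
        ]
        probe = [states[i] for i in rng.choice(len(states), 50, replace=False)]
        hits = 0
        for state in probe:
            summary = predict_state(m4_draws_untruncated, state)
            truth = _state_mean_utility(state, config)
            hits += abs(summary.mean - truth) < 3 * summary.sd
        assert hits >= 47  # about 95% of 50


class TestHoldout:
    def test_replica_holdout_structure(self, replica_analysed, small_config):
        held = select_holdout_states(replica_analysed, 12, seed=4)
        assert len(held) == 12
        assert PITS not in {s.code for s in held}
        result = holdout_validate(replica_analysed, "M4", small_config, held)
        assert result.n_training_states == 237
        table = result.table()
        assert len(table) == 12
        np.testing.assert_allclose(
            table["difference"],
            table["true_sample_mean"] - table["predicted_mean"],
        )

    def test_difference_arithmetic_matches_published_row(self):
        true, mean, _ = published.HOLDOUT_TABLE["112111"]
        assert true - mean == pytest.approx(-0.0492)

    def test_unvalued_state_rejected(self, replica_analysed, small_config):
        from sf6dbayes.state_space import enumerate_states

        valued = {r.state.code for r in replica_analysed.records}
        absent = next(s.code for s in enumerate_states() if s.code not in valued)
        with pytest.raises(ValueError, match="no observed valuations"):
            holdout_validate(replica_analysed, "M4", small_config, [absent])

    def test_standardized_errors_near_standard_normal(
        self, untruncated_analysed, small_config
    ):
        """On model-class data the hold-out z-scores behave like N(0,1)
        (bounds pre-calibrated by simulation for m=12)."""
        held = select_holdout_states(untruncated_analysed, 12, seed=4)
        result = holdout_validate(untruncated_analysed, "M4", small_config, held)
        z = result.standardized_errors
        assert abs(z.mean()) < 0.6
        assert 0.5 < z.std(ddof=1) < 1.6

    def test_respondent_conditional_mode_tightens_sd(
        self, untruncated_analysed, small_config
    ):
        held = select_holdout_states(untruncated_analysed, 4, seed=6)
        marg = holdout_validate(untruncated_analysed, "M4", small_config, held)
        cond = holdout_validate(
            untruncated_analysed, "M4", small_config, held,
            respondent_conditional=True,
        )
        # knowing the valuers' random effects removes the sigma_u component
        assert np.mean([s.sd for s in cond.summaries]) < np.mean(
            [s.sd for s in marg.summaries]
        )

    def test_qq_coordinates_convention(self):
        from scipy import stats

        errs = [0.3, -1.2, 0.8, -0.1]
        theo, ordered = qq_coordinates(errs)
        np.testing.assert_allclose(ordered, sorted(errs))
        np.testing.assert_allclose(theo, stats.norm.ppf((np.arange(1, 5) - 0.5) / 4))


class TestModelComparison:
    def test_random_effects_models_dominate_pooled(
        self, replica_analysed, small_config
    ):
        table = evaluation.compare_models(
            replica_analysed, ["M1", "M2", "M3", "M4"], small_config
        )
        assert list(table.index) == ["M1", "M2", "M3", "M4"]
        for model in ("M2", "M3", "M4"):
            assert table.loc[model, "r2"] > table.loc["M1", "r2"]
            assert table.loc[model, "rmse"] < table.loc["M1", "rmse"]

    def test_adjusted_column_consistent_with_formula(
        self, replica_analysed, small_config
    ):
        table = evaluation.compare_models(
            replica_analysed, ["M1", "M4"], small_config
        )
        for model, row in table.iterrows():
            assert row["adjusted_r2"] == pytest.approx(
                adjusted_r_squared(row["r2"], int(row["n"]), int(row["p"]))
            )

    def test_single_pooled_model_row(self, replica_analysed, small_config):
        table = evaluation.compare_models(replica_analysed, ["M1"], small_config)
        assert len(table) == 1 and table.loc["M1", "p"] == 25

    def test_empty_spec_list_rejected(self, replica_analysed, small_config):
        with pytest.raises(ValueError, match="at least one"):
            evaluation.compare_models(replica_analysed, [], small_config)


def test_state_series_ordering(replica_analysed, m4_draws_replica):
    series = evaluation.state_series(replica_analysed, m4_draws_replica)
    assert (series["predicted_mean"].diff().dropna() >= 0).all()
    assert set(series.columns) == {
        "state", "n_observed", "observed_mean", "predicted_mean", "error"
    }
    assert series["n_observed"].sum() == 3518
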