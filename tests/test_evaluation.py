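import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bodycomp import (
    CVPlan,
    ExperimentConfig,
    aggregate,
    argmin_view,
    asymptotic_sweep,
    make_splits,
    rmse_percent,
    run_plaplace_experiment,
)
from bodycomp.synthetic_cohort import default_cohort_spec, generate_cohort


@pytest.fixture(scope="module")
def small_cohort():
    spec = default_cohort_spec()
    spec.group_sizes = {"male": 60, "female": 60}
    return generate_cohort(spec, seed=9)


class TestRmsePercent:
    def test_perfect_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse_percent(y, y) == 0.0

    def test_worked_example(self):
        assert rmse_percent([2.0, 2.0], [1.0, 1.0]) == pytest.approx(50.0)

    def test_zero_prediction_gives_hundred(self):
        y = np.array([3.0, -1.0, 2.0])
        assert rmse_percent(y, np.zeros(3)) == pytest.approx(100.0)

    def test_all_zero_truth_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rmse_percent([0.0, 0.0], [1.0, 1.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(20) + 3
        pred = y + rng.standard_normal(20)
        for s in (c, -c):
            assert rmse_percent(s * y, s * pred) == pytest.approx(rmse_percent(y, pred))


class TestSplits:
    @pytest.mark.parametrize("K,expected", [(2, 50.0), (3, 100 / 3), (4, 25.0),
                                            (5, 20.0), (10, 10.0), (20, 5.0)])
    def test_modified_mode_training_fractions(self, K, expected):
        plan = CVPlan(K=K, mode="modified", repeats=1, seed=0)
        assert plan.training_percent == pytest.approx(expected)
        splits = make_splits(515, plan, run=0)
        assert len(splits) == K
        for train, test in splits:
            assert abs(len(train) - 515 / K) <= 1

    def test_standard_mode_80_20(self):
        splits = make_splits(515, CVPlan(K=5, mode="standard", seed=0), run=0)
        for train, test in splits:
            assert abs(len(train) / 515 - 0.8) < 1 / 515 + 1e-12

    def test_partition_integrity(self):
        for mode in ("standard", "modified"):
            for train, test in make_splits(53, CVPlan(K=4, mode=mode, seed=1), run=2):
                assert np.intersect1d(train, test).size == 0
                assert np.union1d(train, test).size == 53

    def test_k2_modes_agree_on_fraction(self):
        s_std = make_splits(4, CVPlan(K=2, mode="standard", seed=0), run=0)
        s_mod = make_splits(4, CVPlan(K=2, mode="modified", seed=0), run=0)
        assert all(len(tr) == 2 for tr, _ in s_std + s_mod)

    def test_runs_re_randomize_folds(self):
        a = make_splits(100, CVPlan(K=5, seed=3), run=0)
        b = make_splits(100, CVPlan(K=5, seed=3), run=1)
        assert not all(np.array_equal(x[0], y[0]) for x, y in zip(a, b))

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            make_splits(3, CVPlan(K=4), run=0)


class TestExperiment:
    def test_cartesian_bookkeeping(self, small_cohort):
        config = ExperimentConfig(
            target="ALM", dataset="combined", variant="plap1",
            p_grid=(2.0, 3.0, 4.0), k_grid=(5, 10),
            cv=CVPlan(K=5, mode="standard", repeats=2, seed=0),
        )
        results = run_plaplace_experiment(small_cohort, config)
        assert len(results) == 3 * 2 * 2 * 5
        assert (results.rmse_percent >= 0).all()

    def test_constant_target_gives_zero_rmse(self, small_cohort):
        cohort = small_cohort.copy()
        cohort.frame["ALM"] = 20.0
        config = ExperimentConfig(
            p_grid=(2.0,), k_grid=(5,), cv=CVPlan(K=3, mode="modified", repeats=1, seed=0)
        )
        results = run_plaplace_experiment(cohort, config)
        np.testing.assert_allclose(results.rmse_percent, 0.0, atol=1e-8)

    def test_reproducible_given_config(self, small_cohort):
        config = ExperimentConfig(p_grid=(2.0, 3.0), k_grid=(6,),
                                  cv=CVPlan(K=4, mode="modified", repeats=2, seed=5))
        a = run_plaplace_experiment(small_cohort, config)
        b = run_plaplace_experiment(small_cohort, config)
        pd.testing.assert_frame_equal(a, b)

    def test_plap2_uses_ten_features_and_runs(self, small_cohort):
        config = ExperimentConfig(
            variant="plap2", p_grid=(2.0,), k_grid=(6,),
            cv=CVPlan(K=3, mode="modified", repeats=1, seed=1),
        )
        results = run_plaplace_experiment(small_cohort, config)
        assert len(results) == 3
        assert (results.variant == "plap2").all()

    def test_aggregate_is_mean_over_runs_and_folds(self, small_cohort):
        config = ExperimentConfig(p_grid=(2.0,), k_grid=(6,),
                                  cv=CVPlan(K=3, mode="modified", repeats=2, seed=2))
        results = run_plaplace_experiment(small_cohort, config)
        agg = aggregate(results)
        assert len(agg) == 1
        assert agg.rmse_percent.iloc[0] == pytest.approx(results.rmse_percent.mean())

    def test_argmin_breaks_ties_toward_smaller_p_then_k(self):
        rows = []
        for p in (2.0, 3.0):
            for k in (5, 10):
                rows.append(dict(target="ALM", dataset="combined", variant="plap1",
                                 p=p, k=k, training_percent=20.0, run=0, fold=0,
                                 rmse_percent=1.0))
        best = argmin_view(pd.DataFrame(rows))
        assert best.p.iloc[0] == 2.0 and best.k.iloc[0] == 5


class TestAsymptoticSweep:
    def test_single_p_single_row_per_k(self, small_cohort):
        table = asymptotic_sweep(small_cohort, k_values=(6,), p_values=(3.0,),
                                 training_percent=25.0, repeats=1, seed=0)
        assert len(table) == 1
        assert np.isnan(table.delta.iloc[0])

    def test_non_increasing_p_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            asymptotic_sweep(small_cohort, p_values=(10.0, 3.0))
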