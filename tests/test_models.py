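"""MLR, RBF network training/prediction, dual-RBF ensemble, tuning fitness."""

import numpy as np
import pytest

from caco2qspr.models import (
    MATLAB_SPREAD_FACTOR,
    ModelSpec,
    RBFModel,
    RBFTrainConfig,
    dual_rbf_train,
    fit_model,
    fitness_balanced,
    fitness_robustness_only,
    mlr_fit,
    rbf_predict,
    rbf_train,
    tune_hyperparams,
)
from caco2qspr.optimizer import OptimizerConfig
from tests.conftest import make_table


class TestMLR:
    def test_exact_linear_fit(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        t = make_table(X, 2.0 * X[:, 0] + 1.0)
        m = mlr_fit(t)
        assert m.coefficients[0] == pytest.approx(2.0, abs=1e-10)
        assert m.intercept == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        m = mlr_fit(make_table(X, y))
        A = np.column_stack([X, np.ones(50)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(m.coefficients, beta[:5], atol=1e-8)
        assert m.intercept == pytest.approx(beta[5], abs=1e-8)

    def test_wide_design_takes_ridge_path_with_warning(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.normal(size=(4, 6)), rng.normal(size=4))
        with pytest.warns(UserWarning, match="ridge"):
            m = mlr_fit(t)
        assert np.all(np.isfinite(m.coefficients))


class TestRBFPredict:
    def test_at_center_phi_is_one(self):
        m = RBFModel(centers=np.array([[1.0, 2.0]]), spread=1.0,
                     weights=np.array([3.0]), output_bias=0.0)
        assert rbf_predict(m, np.array([[1.0, 2.0]]))[0] == pytest.approx(3.0)

    def test_far_field_decays_to_bias(self):
        m = RBFModel(centers=np.array([[0.0]]), spread=1.0,
                     weights=np.array([5.0]), output_bias=0.7)
        assert rbf_predict(m, np.array([[100.0]]))[0] == pytest.approx(0.7)

    def test_two_node_hand_computation_matlab_convention(self):
        # distances 0 and 1 from x, weights (1, 2), bias 0.5, delta 1
        m = RBFModel(centers=np.array([[0.0], [1.0]]), spread=1.0,
                     weights=np.array([1.0, 2.0]), output_bias=0.5)
        expected = 0.5 + 1.0 * 1.0 + 2.0 * np.exp(-(MATLAB_SPREAD_FACTOR * 1.0) ** 2)
        assert rbf_predict(m, np.array([[0.0]]))[0] == pytest.approx(expected, abs=1e-12)

    def test_half_activation_at_one_spread(self):
        m = RBFModel(centers=np.array([[0.0]]), spread=2.0,
                     weights=np.array([1.0]), output_bias=0.0)
        # 0.8326 ~ sqrt(ln 2), so the activation halves at one spread
        assert rbf_predict(m, np.array([[2.0]]))[0] == pytest.approx(0.5, abs=1e-4)

    def test_classic_convention(self):
        m = RBFModel(centers=np.array([[0.0]]), spread=1.5, weights=np.array([1.0]),
                     output_bias=0.0, activation_convention="classic")
        d = 2.0
        assert rbf_predict(m, np.array([[d]]))[0] == pytest.approx(
            np.exp(-d**2 / (2 * 1.5**2)), abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        from caco2qspr.datatable import InputError

        m = RBFModel(centers=np.array([[0.0, 1.0]]), spread=1.0,
                     weights=np.array([1.0]), output_bias=0.0)
        with pytest.raises(InputError):
            rbf_predict(m, np.array([[1.0]]))


class TestRBFTrain:
    def generic(self, n=25, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        return make_table(X, y)

    def test_zero_goal_interpolates(self):
        t = self.generic()
        m = rbf_train(t, RBFTrainConfig(spread=1.0, mse_goal=0.0))
        mse = np.mean((m.predict(t.X) - t.y) ** 2)
        assert mse <= 1e-8

    def test_goal_above_variance_keeps_bias_only(self):
        t = self.generic()
        goal = float(np.var(t.y)) * 1.01
        m = rbf_train(t, RBFTrainConfig(spread=1.0, mse_goal=goal))
        assert m.k == 0
        assert m.output_bias == pytest.approx(float(np.mean(t.y)))

    def test_deterministic_center_order(self):
        t = self.generic()
        cfg = RBFTrainConfig(spread=1.0, mse_goal=0.01)
        a = rbf_train(t, cfg)
        b = rbf_train(t, cfg)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_centers_are_training_points_and_capped(self):
        t = self.generic()
        m = rbf_train(t, RBFTrainConfig(spread=1.0, mse_goal=0.0, max_neurons=5))
        assert m.k <= 5
        for c in m.centers:
            assert any(np.allclose(c, row) for row in t.X)

    def test_training_mse_non_increasing_with_neurons(self):
        t = self.generic(n=20, seed=2)
        mses = []
        for k in range(1, 10):
            m = rbf_train(t, RBFTrainConfig(spread=1.5, mse_goal=0.0, max_neurons=k))
            mses.append(float(np.mean((m.predict(t.X) - t.y) ** 2)))
        assert all(b <= a + 1e-12 for a, b in zip(mses, mses[1:]))


class TestDualRBF:
    def test_identical_members_equal_single(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.normal(size=(30, 2)), rng.normal(size=30))
        dual = dual_rbf_train(t, (2.0, 0.01, 2.0, 0.01))
        single = rbf_train(t, RBFTrainConfig(spread=2.0, mse_goal=0.01))
        np.testing.assert_allclose(dual.predict(t.X), single.predict(t.X))

    def test_prediction_is_exact_member_mean(self):
        rng = np.random.default_rng(4)
        t = make_table(rng.normal(size=(30, 2)), rng.normal(size=30))
        dual = dual_rbf_train(t, (3.0, 0.02, 1.0, 0.005))
        pa = dual.member_a.predict(t.X)
        pb = dual.member_b.predict(t.X)
        np.testing.assert_array_equal(dual.predict(t.X), 0.5 * (pa + pb))

    def test_reference_hyperparameters_accepted_and_echoed(self):
        # the hyperparameter set reported for the published dual-RBF model
        hyper = (6.5400, 0.0296, 1.7100, 0.0101)
        rng = np.random.default_rng(5)
        t = make_table(rng.normal(size=(40, 3)), rng.normal(size=40))
        dual = dual_rbf_train(t, hyper)
        assert dual.hyper == hyper
        assert dual.member_a.spread == 6.5400
        assert dual.member_b.spread == 1.7100

    def test_ensemble_never_worse_than_worst_member(self, noisy_table):
        table, _ = noisy_table
        train = table.subset_rows(range(150))
        test = table.subset_rows(range(150, table.n))
        dual = dual_rbf_train(train, (4.0, 0.02, 1.5, 0.01))
        def rm(model):
            return float(np.sqrt(np.mean((model.predict(test.X) - test.y) ** 2)))
        assert rm(dual) <= max(rm(dual.member_a), rm(dual.member_b)) + 1e-12


class TestFitnessAndTuning:
    def test_floor_guards_negative_cv_r2(self):
        f = fitness_robustness_only(-0.3)
        assert f == pytest.approx(1.0 / 1e-4)
        assert np.isfinite(f)

    def test_balanced_fitness_lower_bound_is_two(self):
        assert fitness_balanced(1.0, 1.0) == pytest.approx(2.0)

    def test_tuned_dual_rbf_beats_random_draws(self):
        from caco2qspr.synthetic import SyntheticSpec, generate
        from caco2qspr.validation import cross_validate, r_squared

        def balanced_of(table, spec):
            model = fit_model(table, spec)
            r2 = r_squared(table.y, model.predict(table.X), strict=False)
            rcv, _ = cross_validate(table, spec, seed=0)
            return fitness_balanced(r2, rcv)

        wins = 0
        for seed in range(3):
            table, _ = generate(SyntheticSpec(
                n=60, p=4, support_size=3, noise_sd=0.2, nonlinear_fraction=0.5,
                seed=seed))
            opt = OptimizerConfig(population_size=8, max_iterations=8, seed=seed,
                                  bounds=[(0.1, 20.0), (1e-4, 0.1)] * 2)
            spec = tune_hyperparams(table, "dual_rbf", opt=opt, cv_seed=0)
            tuned = balanced_of(table, spec)
            rng = np.random.default_rng(seed + 100)
            draws = []
            for _ in range(10):
                pos = [rng.uniform(0.1, 20), rng.uniform(1e-4, 0.1),
                       rng.uniform(0.1, 20), rng.uniform(1e-4, 0.1)]
                draws.append(balanced_of(
                    table, ModelSpec("dual_rbf", dict(
                        zip(("delta1", "epsilon1", "delta2", "epsilon2"), pos)))))
            if tuned <= min(draws):
                wins += 1
        assert wins >= 2

    def test_mlr_family_has_no_hyperparameters(self):
        rng = np.random.default_rng(6)
        t = make_table(rng.normal(size=(20, 2)), rng.normal(size=20))
        spec = tune_hyperparams(t, "mlr")
        assert spec.family == "mlr" and spec.params == {}

    def test_model_spec_validates_family_params(self):
        with pytest.raises(ValueError):
            ModelSpec(family="rbf", params={"delta": 1.0})  # epsilon missing
        with pytest.raises(ValueError):
            ModelSpec(family="nonsense")


class TestSerialization:
    def test_native_families_round_trip(self):
        from caco2qspr.models import model_from_dict, model_to_dict

        rng = np.random.default_rng(7)
        t = make_table(rng.normal(size=(25, 2)), rng.normal(size=25))
        spec = ModelSpec("dual_rbf", {"delta1": 2.0, "epsilon1": 0.01,
                                      "delta2": 1.0, "epsilon2": 0.02})
        model = fit_model(t, spec)
        clone = model_from_dict(model_to_dict(model, spec))
        np.testing.assert_allclose(clone.predict(t.X), model.predict(t.X))
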