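"""Soft-margin SVM, three-way split, C search, bootstrap averaging."""

import numpy as np
import pytest
from scipy import optimize

import spatialp300 as sp
from spatialp300.classify import DEFAULT_C_GRID, SoftMarginLinearSVM
from conftest import make_epochs


def primal_qp_oracle(X: np.ndarray, y: np.ndarray, C: float) -> tuple[float, np.ndarray, float]:
    """Independent solve of the soft-margin primal as a smooth QP.

    Variables z = (a, b, xi); minimize 0.5|a|^2 + C sum(xi) subject to
    y_i (a.x_i + b) >= 1 - xi_i and xi >= 0, via SLSQP. Returns the optimal
    objective, weights and offset.
    """
    n, d = X.shape

    def objective(z):
        a = z[:d]
        return 0.5 * a @ a + C * z[d + 1 :].sum()

    def objective_grad(z):
        g = np.zeros_like(z)
        g[:d] = z[:d]
        g[d + 1 :] = C
        return g

    yx = y[:, None] * X

    def margin_con(z):
        return yx @ z[:d] + y * z[d] - 1.0 + z[d + 1 :]

    def margin_jac(z):
        jac = np.zeros((n, d + 1 + n))
        jac[:, :d] = yx
        jac[:, d] = y
        jac[:, d + 1 :] = np.eye(n)
        return jac

    z0 = np.zeros(d + 1 + n)
    z0[d + 1 :] = 1.0
    res = optimize.minimize(
        objective,
        z0,
        jac=objective_grad,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": margin_con, "jac": margin_jac}],
        bounds=[(None, None)] * (d + 1) + [(0.0, None)] * n,
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    assert res.success, res.message
    return res.fun, res.x[:d], res.x[d]


class TestSoftMarginSVM:
    def test_two_point_problem_has_analytic_solution(self):
        """x=-1 (y=-1), x=+1 (y=+1), large C: a=1, b=0 (midpoint separator)."""
        model = sp.train_soft_margin(np.array([[-1.0], [1.0]]), np.array([-1, 1]), C=100.0)
        assert model.coef_[0] == pytest.approx(1.0, abs=1e-6)
        assert model.intercept_ == pytest.approx(0.0, abs=1e-6)

    def test_label_flip_negates_weights(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 4))
        y = np.where(rng.random(30) < 0.5, 1, -1)
        y[:3], y[-3:] = 1, -1
        m1 = sp.train_soft_margin(X, y, C=1.0)
        m2 = sp.train_soft_margin(X, -y, C=1.0)
        np.testing.assert_allclose(m1.coef_, -m2.coef_, atol=1e-6)
        assert m1.intercept_ == pytest.approx(-m2.intercept_, abs=1e-6)

    @pytest.mark.parametrize("C", [0.01, 1.0])
    def test_objective_and_predictions_match_qp_oracle(self, C):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 5))
        y = np.where(X[:, 0] + 0.5 * rng.standard_normal(40) > 0, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        model = SoftMarginLinearSVM(C=C).fit(X, y)
        obj_oracle, a_oracle, b_oracle = primal_qp_oracle(X, y, C)
        assert model.objective(X, y) == pytest.approx(obj_oracle, abs=1e-5)
        pred_oracle = np.where(X @ a_oracle + b_oracle >= 0, 1, -1)
        np.testing.assert_array_equal(model.predict(X), pred_oracle)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            SoftMarginLinearSVM().fit(np.zeros((5, 2)), np.ones(5, int))

    def test_prediction_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        model = sp.train_soft_margin(X, np.where(X[:, 0] > 0, 1, -1), C=1.0)
        scaled = SoftMarginLinearSVM(C=1.0)
        scaled.coef_, scaled.intercept_ = 7.5 * model.coef_, 7.5 * model.intercept_
        np.testing.assert_array_equal(model.predict(X), scaled.predict(X))

    def test_boundary_value_classified_positive(self):
        model = SoftMarginLinearSVM()
        model.coef_, model.intercept_ = np.array([1.0]), 0.0
        assert model.predict(np.array([[0.0]]))[0] == 1


class TestSplitThreeWay:
    def test_counting_rule_30_targets_120_nontargets(self):
        labels = np.array([1] * 30 + [-1] * 120)
        train, csearch, test = sp.split_three_way(labels, seed=0)
        assert len(train) == 30  # 15 targets + 15 non-targets (balanced)
        assert (labels[train] == 1).sum() == 15
        assert (labels[train] == -1).sum() == 15
        assert len(csearch) == 60
        assert len(test) == 60

    def test_odd_remainder_extra_sample_goes_to_test(self):
        labels = np.array([1] * 31 + [-1] * 120)
        train, csearch, test = sp.split_three_way(labels, seed=0)
        assert len(train) == 30  # floor(31/2) = 15 per class
        assert len(csearch) == 60
        assert len(test) == 61

    def test_same_seed_gives_identical_partition(self):
        labels = np.array([1] * 20 + [-1] * 80)
        a = sp.split_three_way(labels, seed=7)
        b = sp.split_three_way(labels, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n_t = int(rng.integers(4, 40))
            n_n = int(rng.integers(n_t, 150))
            labels = rng.permutation(np.array([1] * n_t + [-1] * n_n))
            train, csearch, test = sp.split_three_way(labels, seed=trial)
            all_idx = np.concatenate([train, csearch, test])
            assert len(all_idx) == len(labels)
            assert len(set(all_idx)) == len(labels)

    def test_too_few_targets_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            sp.split_three_way(np.array([1] + [-1] * 10), seed=0)


class TestSelectC:
    def test_single_element_grid_returned(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 2))
        y = np.where(X[:, 0] > 0, 1, -1)
        best, accs = sp.select_C(X, y, X, y, c_grid=(0.5,))
        assert best == 0.5
        assert list(accs) == [0.5]

    def test_default_grid_has_19_candidates(self):
        assert len(DEFAULT_C_GRID) == 19
        assert DEFAULT_C_GRID[0] == 2.0**-16
        assert DEFAULT_C_GRID[-1] == 2.0**2

    def test_ties_resolve_to_smallest_c(self):
        """Perfectly separable data: every C is equally accurate."""
        X = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        y = np.array([-1, -1, 1, 1])
        best, accs = sp.select_C(X, y, X, y, c_grid=(0.25, 1.0, 4.0))
        assert best == 0.25
        assert all(a == 100.0 for a in accs.values())


class TestEvaluate:
    def test_constant_positive_classifier_arithmetic(self):
        model = SoftMarginLinearSVM()
        model.coef_, model.intercept_ = np.array([0.0]), 5.0
        X = np.zeros((100, 1))
        y = np.array([1] * 20 + [-1] * 80)
        rec = sp.evaluate(model, X, y)
        assert rec.target_accuracy == 100.0
        assert rec.nontarget_accuracy == 0.0
        assert rec.overall_accuracy == 20.0

    def test_perfect_separator_scores_100(self):
        X = np.array([[-1.0], [1.0], [-2.0], [2.0]])
        y = np.array([-1, 1, -1, 1])
        model = sp.train_soft_margin(X, y, C=10.0)
        rec = sp.evaluate(model, X, y)
        assert (rec.target_accuracy, rec.nontarget_accuracy, rec.overall_accuracy) == (
            100.0, 100.0, 100.0,
        )

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 3))
        y = np.where(rng.random(200) < 0.25, 1, -1)
        model = SoftMarginLinearSVM()
        model.coef_, model.intercept_ = rng.standard_normal(3), 0.1
        rec = sp.evaluate(model, X, y)
        pred = np.where(X @ model.coef_ + model.intercept_ >= 0, 1, -1)
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == -1) & (y == -1)).sum())
        assert rec.target_accuracy == pytest.approx(100.0 * tp / (y == 1).sum())
        assert rec.nontarget_accuracy == pytest.approx(100.0 * tn / (y == -1).sum())
        assert rec.overall_accuracy == pytest.approx(100.0 * (tp + tn) / 200)

    def test_missing_class_flagged_overall_still_computed(self):
        model = SoftMarginLinearSVM()
        model.coef_, model.intercept_ = np.array([1.0]), 0.0
        rec = sp.evaluate(model, np.array([[1.0], [2.0]]), np.array([1, 1]))
        assert np.isnan(rec.nontarget_accuracy)
        assert rec.overall_accuracy == 100.0


class TestBootstrapAverage:
    @staticmethod
    def noise_epochs(n=200, sd=1.0, seed=6):
        rng = np.random.default_rng(seed)
        data = rng.normal(0.0, sd, size=(n, 1, 40))
        labels = np.concatenate([np.ones(n // 2, int), -np.ones(n // 2, int)])
        return make_epochs(data, labels, window_ms=(-50.0, 110.0), channel_names=("Pz",))

    def test_k1_returns_originals(self):
        epochs = self.noise_epochs(n=20)
        out = sp.bootstrap_average(epochs, k=1, seed=0)
        np.testing.assert_array_equal(out.epochs, epochs.epochs)

    def test_class_counts_preserved_for_every_k(self):
        epochs = self.noise_epochs(n=60)
        for k in (1, 2, 5, 10):
            out = sp.bootstrap_average(epochs, k=k, seed=1)
            assert (out.labels == 1).sum() == 30
            assert (out.labels == -1).sum() == 30

    def test_pool_smaller_than_k_rejected(self):
        epochs = self.noise_epochs(n=10)
        with pytest.raises(ValueError, match="pool"):
            sp.bootstrap_average(epochs, k=6, seed=0)

    def test_targets_averaged_within_direction(self):
        """Target replicates only mix trials that share a stimulus direction."""
        data = np.zeros((8, 1, 40))
        data[:4] = 1.0  # direction 30 targets
        data[4:] = -1.0  # direction 90 targets
        labels = np.ones(8, int)
        dirs = np.array([30] * 4 + [90] * 4)
        epochs = make_epochs(data, labels, window_ms=(-50.0, 110.0),
                             directions=dirs, channel_names=("Pz",))
        out = sp.bootstrap_average(epochs, k=3, seed=2)
        np.testing.assert_allclose(np.abs(out.epochs), 1.0, atol=1e-12)

    def test_variance_shrinks_by_factor_k(self):
        """k-averaged pure-noise epochs have variance ~ sigma^2 / k (3-sigma)."""
        epochs = self.noise_epochs(n=2000, sd=1.0)
        n_values = 1000 * 40  # replicate samples entering the estimate
        for k in (2, 5, 10):
            out = sp.bootstrap_average(epochs, k=k, seed=3)
            nontgt = out.epochs[out.labels == -1]
            var = nontgt.var()
            expected = 1.0 / k
            se = expected * np.sqrt(2.0 / (n_values - 1))
            assert abs(var - expected) < 3 * se


class TestRunExperiment:
    def test_zero_amplitude_erp_classifies_at_chance(self):
        """No signal: balanced accuracy within Monte-Carlo error of 50%."""
        proto = sp.ProtocolConfig(sessions=4, trials_per_session=100)
        erp = sp.ErpModel().scaled(0.0)
        recs = sp.simulate_subject(proto, erp, sp.NoiseModel(artifact_rate=0.0), seed=21)
        epochs, _ = sp.preprocess_sessions(recs)
        res = sp.run_experiment(
            epochs.kept(), sp.SplitConfig(n_repetitions=5, seed=3), k_range=(1,),
        )
        balanced = 0.5 * (res.target_accuracy + res.nontarget_accuracy)
        # each repetition's balanced accuracy has SE ~ 4%; mean of 5 reps ~ 1.8%
        assert abs(balanced.mean() - 50.0) < 3 * 1.8

    def test_same_seed_reproduces_accuracy_table(self, synthetic_subject):
        epochs, _ = synthetic_subject
        cfg = sp.SplitConfig(n_repetitions=2, seed=9)
        a = sp.run_experiment(epochs, cfg, k_range=(1, 2))
        b = sp.run_experiment(epochs, cfg, k_range=(1, 2))
        assert a.equals(b)

    def test_strong_signal_gives_high_accuracy_with_averaging(self, synthetic_subject):
        epochs, _ = synthetic_subject
        res = sp.run_experiment(
            epochs, sp.SplitConfig(n_repetitions=2, seed=4), k_range=(10,),
        )
        assert res.overall_accuracy.mean() > 80.0
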