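import numpy as np
import pytest

from alfkrig.kriging import (
    KrigingRegressor,
    PSOConfig,
    concentrated_log_likelihood,
    correlation,
    fit_given_hyperparams,
)


def brute_force_log_likelihood(X, y, theta, p, nugget=1e-10):
    """Independent oracle: explicit inverse and determinant, tiny n only."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    R = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            R[i, j] = np.exp(-np.sum(theta * np.abs(X[i] - X[j]) ** p))
    R += nugget * np.eye(n)
    Rinv = np.linalg.inv(R)
    ones = np.ones(n)
    mu = (ones @ Rinv @ y) / (ones @ Rinv @ ones)
    resid = y - mu
    sigma2 = (resid @ Rinv @ resid) / n
    return -0.5 * n * np.log(sigma2) - 0.5 * np.log(np.linalg.det(R))


class TestCorrelation:
    def test_closed_forms(self):
        assert correlation([1.0, 2.0], [1.0, 2.0], [1.0, 1.0], [2.0, 2.0]) == 1.0
        assert correlation([0.0], [1.0], [1.0], [2.0]) == pytest.approx(np.exp(-1))

    def test_monotone_decay(self):
        deltas = np.linspace(0, 10, 50)
        vals = [correlation([0.0], [d], [0.7], [1.5]) for d in deltas]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert all(0 < v <= 1 for v in vals)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="length mismatch"):
            correlation([0.0], [0.0, 1.0], [1.0], [2.0])
        with pytest.raises(ValueError):
            correlation([0.0], [1.0], [-1.0], [2.0])
        with pytest.raises(ValueError):
            correlation([0.0], [1.0], [1.0], [3.0])


class TestFitGivenHyperparams:
    def test_constant_target(self):
        X = np.linspace(0, 1, 7)[:, None]
        mu, a, _ = fit_given_hyperparams(X, np.full(7, 3.25), [1.0], [2.0])
        assert mu == pytest.approx(3.25, abs=1e-8)
        np.testing.assert_allclose(a, 0.0, atol=1e-6)

    def test_two_point_system_solved_by_hand(self):
        """n=2 has a closed algebraic solution for mu and the weights."""
        x0, x1, y0, y1 = 0.0, 1.0, 1.0, 3.0
        theta, p, ng = np.array([0.8]), np.array([1.5]), 1e-10
        r = np.exp(-theta[0] * abs(x0 - x1) ** p[0])
        d = 1.0 + ng
        # symmetric 2x2: mu = (y0 + y1) / 2 by symmetry of R
        mu_hand = 0.5 * (y0 + y1)
        # a = R^-1 (y - mu): R = [[d, r], [r, d]]
        det = d * d - r * r
        a_hand = np.array([d * (y0 - mu_hand) - r * (y1 - mu_hand),
                           -r * (y0 - mu_hand) + d * (y1 - mu_hand)]) / det
        mu, a, _ = fit_given_hyperparams([[x0], [x1]], [y0, y1], theta, p,
                                         nugget=ng)
        assert mu == pytest.approx(mu_hand, abs=1e-10)
        np.testing.assert_allclose(a, a_hand, atol=1e-8)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (12, 3))
        y = rng.normal(size=12)
        theta, p = np.full(3, 2.0), np.full(3, 1.8)
        mu1, _, ll1 = fit_given_hyperparams(X, y, theta, p)
        perm = rng.permutation(12)
        mu2, _, ll2 = fit_given_hyperparams(X[perm], y[perm], theta, p)
        assert mu1 == pytest.approx(mu2, rel=1e-10)
        assert ll1 == pytest.approx(ll2, rel=1e-8)

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_likelihood_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        X = rng.uniform(0, 1, (n, 2))
        y = rng.normal(size=n)
        theta, p = rng.uniform(0.5, 3, 2), rng.uniform(1, 2, 2)
        assert concentrated_log_likelihood(X, y, theta, p) == pytest.approx(
            brute_force_log_likelihood(X, y, theta, p), abs=1e-8)


class TestPredictor:
    @pytest.fixture(scope="class")
    def smooth_model(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (40, 2))
        y = np.sin(3 * X[:, 0]) + 0.5 * np.cos(2 * X[:, 1])
        model = KrigingRegressor(
            normalize=False,
            pso=PSOConfig(seed=1, n_particles=12, n_iterations_max=25)
        ).fit(X, y)
        return model, X, y

    def test_interpolates_training_points(self, smooth_model):
        model, X, y = smooth_model
        # nugget-limited: the residual at a training point is nugget * a_i
        tol = max(1e-6, 10 * model.nugget_ * np.abs(model.weights_).max())
        np.testing.assert_allclose(model.predict(X), y, atol=tol)

    def test_far_field_reverts_to_global_mean(self, smooth_model):
        model, X, _ = smooth_model
        far = np.full((1, 2), 1e6)
        assert model.predict(far)[0] == pytest.approx(model.mu_, abs=1e-10)

    def test_single_training_point_predicts_its_target(self):
        model = KrigingRegressor(theta=[1.0], p=[2.0],
                                 normalize=False).fit([[0.5]], [2.0])
        assert model.mu_ == pytest.approx(2.0)
        assert model.predict([[0.5]])[0] == pytest.approx(2.0, abs=1e-9)
        assert model.predict([[100.0]])[0] == pytest.approx(2.0, abs=1e-9)

    def test_beats_mean_baseline_on_noiseless_sine(self):
        X = np.linspace(0, np.pi, 5)[:, None]
        y = np.sin(X[:, 0])
        model = KrigingRegressor(
            normalize=False,
            pso=PSOConfig(seed=3, n_particles=10, n_iterations_max=30)
        ).fit(X, y)
        xs = np.linspace(0.2, np.pi - 0.2, 25)[:, None]
        err = np.abs(model.predict(xs) - np.sin(xs[:, 0])).mean()
        baseline = np.abs(y.mean() - np.sin(xs[:, 0])).mean()
        assert err < 0.1 * baseline

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (15, 2))
        y = rng.normal(size=15)
        cfg = PSOConfig(seed=11, n_particles=8, n_iterations_max=10)
        m1 = KrigingRegressor(pso=cfg, normalize=False).fit(X, y)
        m2 = KrigingRegressor(pso=cfg, normalize=False).fit(X, y)
        np.testing.assert_array_equal(m1.theta_, m2.theta_)
        np.testing.assert_array_equal(m1.p_, m2.p_)
        np.testing.assert_array_equal(m1.weights_, m2.weights_)

    def test_linearity_in_targets(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (10, 2))
        y = rng.normal(size=10)
        kw = dict(theta=[1.5, 0.5], p=[2.0, 1.5], normalize=False)
        m1 = KrigingRegressor(**kw).fit(X, y)
        m2 = KrigingRegressor(**kw).fit(X, 2 * y)
        xs = rng.uniform(0, 1, (5, 2))
        np.testing.assert_allclose(m2.predict(xs), 2 * m1.predict(xs),
                                   atol=1e-8)

    def test_feature_count_mismatch(self, smooth_model):
        model, _, _ = smooth_model
        with pytest.raises(ValueError, match="features"):
            model.predict([[0.1, 0.2, 0.3]])


class TestMuFix:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, (20, 2))
        y = np.sin(4 * X[:, 0]) * np.cos(2 * X[:, 1])
        return KrigingRegressor(theta=[5.0, 5.0], p=[2.0, 2.0],
                                normalize=False).fit(X, y), X

    def test_shift_displaces_every_prediction_exactly(self, fitted):
        model, X = fitted
        shifted = model.mu_fix(model.mu_ + 0.01)
        np.testing.assert_allclose(shifted.predict(X),
                                   model.predict(X) + 0.01, atol=1e-12)

    def test_identity_shift(self, fitted):
        model, X = fitted
        same = model.mu_fix(model.mu_)
        np.testing.assert_array_equal(same.predict(X), model.predict(X))

    def test_original_untouched_and_refit_differs(self, fitted):
        model, X = fitted
        mu_old = model.mu_
        refit = model.mu_fix(mu_old + 0.05, mode="refit")
        shift = model.mu_fix(mu_old + 0.05, mode="shift")
        assert model.mu_ == mu_old
        # refit still interpolates the original targets at training points,
        # whereas shift displaces them by the mean change
        np.testing.assert_allclose(refit.predict(X), model.y_train_,
                                   atol=1e-6)
        np.testing.assert_allclose(shift.predict(X), model.y_train_ + 0.05,
                                   atol=1e-6)
        # off the training set the two transfers genuinely differ
        mid = X.mean(axis=0) + 0.4
        assert abs(refit.predict([mid])[0] - shift.predict([mid])[0]) > 1e-6

    def test_invalid_inputs(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError):
            model.mu_fix(np.nan)
        with pytest.raises(ValueError):
            model.mu_fix(0.0, mode="bogus")


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 2, (12, 3))
        y = rng.normal(size=12)
        model = KrigingRegressor(theta=[1.0, 2.0, 0.5],
                                 p=[2.0, 1.5, 1.0]).fit(X, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = KrigingRegressor.from_json(path)
        xs = rng.uniform(0, 2, (6, 3))
        np.testing.assert_allclose(back.predict(xs), model.predict(xs),
                                   atol=1e-12)


def test_pso_config_validation():
    with pytest.raises(ValueError):
        PSOConfig(n_particles=0)
    with pytest.raises(ValueError):
        PSOConfig(p_bounds=(1.5, 1.0))
    with pytest.raises(ValueError):
        PSOConfig(log_theta_bounds=(2.0, -4.0))
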