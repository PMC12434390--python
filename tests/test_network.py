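"""The Bayesian-regularized Levenberg-Marquardt regressor."""

import numpy as np
import pytest
import scipy.optimize

from coulombfit.network import (ACTIVATIONS, BRNNRegressor, _forward,
                                _forward_jacobian, _init_weights,
                                _layer_shapes, activation, count_parameters,
                                mse, rmsd)


class TestParameterCount:
    @pytest.mark.parametrize("n_in,hidden,expected", [
        (1, (15,), 46),        # 15 weights + 15 biases + 15 weights + 1 bias
        (1, (10, 10), 141),    # 20 + 110 + 11
        (3, (30, 30, 30), 2011),
        (1, (), 2),            # affine model
    ])
    def test_counts(self, n_in, hidden, expected):
        assert count_parameters(n_in, hidden) == expected

    def test_init_deterministic(self):
        shapes = _layer_shapes(1, (8,), 1)
        w1 = _init_weights(shapes, np.random.default_rng(5))
        w2 = _init_weights(shapes, np.random.default_rng(5))
        assert np.array_equal(w1, w2)
        assert len(w1) == count_parameters(1, (8,))


class TestActivation:
    def test_odd_and_zero(self):
        x = np.linspace(-5, 5, 41)
        s = activation(x)
        assert activation(0.0) == 0.0
        assert np.allclose(s, -activation(-x), atol=1e-15)

    def test_saturation(self):
        assert activation(50.0) == pytest.approx(1.0, abs=1e-12)
        assert activation(-50.0) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_modified_sigmoid_form(self):
        # 2/(1+exp(-2x)) - 1 is the implemented odd sigmoid
        x = np.linspace(-3, 3, 31)
        assert np.allclose(activation(x), 2.0 / (1.0 + np.exp(-2 * x)) - 1.0,
                           atol=1e-12)

    def test_zero_weight_network_is_constant(self):
        shapes = _layer_shapes(1, (7,), 1)
        w = np.zeros(count_parameters(1, (7,)))
        w[-1] = 0.37           # output bias
        out = _forward(w, shapes, ACTIVATIONS["tansig"][0],
                       np.linspace(-1, 1, 9).reshape(-1, 1))
        assert np.allclose(out, 0.37, atol=1e-15)


class TestJacobian:
    @pytest.mark.parametrize("hidden", [(6,), (5, 4)])
    def test_against_central_differences(self, hidden):
        rng = np.random.default_rng(9)
        shapes = _layer_shapes(2, hidden, 1)
        w = _init_weights(shapes, rng)
        X = rng.uniform(-1, 1, size=(12, 2))
        act, dact = ACTIVATIONS["tansig"]
        f, J = _forward_jacobian(w, shapes, act, dact, X)
        h = 1e-6
        for k in range(len(w)):
            e = np.zeros(len(w)); e[k] = h
            fd = (_forward(w + e, shapes, act, X)
                  - _forward(w - e, shapes, act, X)) / (2 * h)
            denom = max(1.0, np.max(np.abs(fd)))
            assert np.max(np.abs(J[:, k] - fd)) / denom < 1e-6


class TestMetrics:
    def test_zero_for_identical(self):
        x = np.arange(5.0)
        assert rmsd(x, x) == 0.0

    def test_arithmetic(self):
        assert rmsd([3.0, 4.0], [0.0, 0.0]) == pytest.approx(
            np.sqrt(25.0 / 2.0), abs=1e-12)

    def test_rmsd_squares_to_mse(self):
        a, b = np.array([1.0, 5.0, -2.0]), np.array([0.5, 4.0, 1.0])
        assert rmsd(a, b) ** 2 == pytest.approx(mse(a, b), rel=1e-15)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmsd([1.0], [1.0, 2.0])


class TestTraining:
    def test_constant_zero_data(self):
        X = np.linspace(-2, 2, 30).reshape(-1, 1)
        net = BRNNRegressor((5,), target_mse=1e-8, max_epochs=50,
                            random_state=0)
        net.fit(X, np.zeros(30))
        assert np.max(np.abs(net.predict(X))) < 1e-3
        assert net.history_.mse[-1] <= 1e-8

    def test_sine_fit_matches_least_squares_floor(self):
        """LM-BR reaches the same residual floor as an independent
        general-purpose least-squares optimizer on sin(x)."""
        X = np.linspace(-3, 3, 50).reshape(-1, 1)
        y = np.sin(X).ravel()
        net = BRNNRegressor((10,), target_mse=1e-6, max_epochs=2000,
                            random_state=1)
        net.fit(X, y)
        assert net.stop_reason_ == "target_mse"
        assert net.history_.mse[-1] <= 1e-6

        # independent oracle: scipy least_squares on the same architecture
        from coulombfit.network import _layer_shapes as ls
        shapes = ls(1, (10,), 1)
        act = ACTIVATIONS["tansig"][0]
        Xn = X / 3.0

        def resid(w):
            return _forward(w, shapes, act, Xn) - y

        w0 = _init_weights(shapes, np.random.default_rng(1))
        sol = scipy.optimize.least_squares(resid, w0, method="lm",
                                           max_nfev=20000)
        assert np.mean(sol.fun ** 2) <= 1e-6

    def test_bit_reproducible(self):
        X = np.linspace(0.5, 5, 40).reshape(-1, 1)
        y = 1.0 / X.ravel()
        kw = dict(hidden_layer_sizes=(6,), target_mse=1e-9, max_epochs=200,
                  random_state=3)
        n1 = BRNNRegressor(**kw).fit(X, y)
        n2 = BRNNRegressor(**kw).fit(X, y)
        assert np.array_equal(n1.weights_, n2.weights_)
        assert n1.history_.mse == n2.history_.mse

    def test_gamma_bounded(self):
        X = np.linspace(-1, 1, 25).reshape(-1, 1)
        y = X.ravel() ** 2
        net = BRNNRegressor((8,), target_mse=1e-10, max_epochs=300,
                            random_state=2)
        net.fit(X, y)
        g = np.array(net.history_.gamma)
        assert np.all(g >= 0.0) and np.all(g <= net.n_params_)

    def test_objective_monotone_at_fixed_hyperparameters(self):
        """With alpha frozen the LM objective decreases on accepted steps."""
        X = np.linspace(-2, 2, 30).reshape(-1, 1)
        y = np.tanh(2 * X).ravel() + 0.1 * X.ravel()
        net = BRNNRegressor((6,), target_mse=1e-12, max_epochs=400,
                            random_state=4, bayes=False)
        net.fit(X, y)
        F = np.array(net.history_.objective)
        acc = np.array(net.history_.accepted)
        Facc = F[acc]
        assert np.all(np.diff(Facc) < 0)

    def test_plain_lm_linear_model_one_step_least_squares(self):
        """alpha = 0, no hidden layer: one accepted step lands on the
        normal-equations solution."""
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, size=(20, 1))
        y = 2.0 * X.ravel() + 1.0 + 0.01 * rng.normal(size=20)
        net = BRNNRegressor((), bayes=False, alpha_init=0.0, mu_init=1e-12,
                            target_mse=1e-20, max_epochs=3, random_state=0)
        net.fit(X, y)
        # oracle: ordinary least squares on the same (normalised) problem
        A = np.column_stack([X.ravel(), np.ones(20)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        pred = net.predict(X)
        assert np.max(np.abs(pred - A @ coef)) < 1e-6

    def test_united_scale_stopping_unit(self):
        """target_mse refers to denormalised outputs: a fit of data spanning
        1e5 with target 0.04 must reach residuals ~0.2 in y units."""
        X = np.linspace(0.2, 5, 60).reshape(-1, 1)
        y = 1e5 * np.tanh(X.ravel() - 2.0)
        net = BRNNRegressor((8,), target_mse=0.04, max_epochs=3000,
                            random_state=0)
        net.fit(X, y)
        assert net.stop_reason_ == "target_mse"
        assert rmsd(net.predict(X), y) <= np.sqrt(0.04) * 1.01


class TestSerialization:
    def test_bit_exact_round_trip(self):
        X = np.linspace(0.5, 4, 30).reshape(-1, 1)
        y = np.exp(-X.ravel())
        net = BRNNRegressor((5,), target_mse=1e-10, max_epochs=100,
                            random_state=8)
        net.fit(X, y)
        doc = net.to_json()
        back = BRNNRegressor.from_json(doc)
        assert np.array_equal(back.weights_, net.weights_)
        assert np.array_equal(back.predict(X), net.predict(X))
        assert back.to_json() == doc

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            BRNNRegressor().to_json()
        with pytest.raises(RuntimeError):
            BRNNRegressor().predict([[1.0]])
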