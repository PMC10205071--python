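"""TRF basis, prediction, boosting, cross-validation and predictive power."""

import numpy as np
import pytest

from cohorttrf.mtrf import (
    TRFBasis,
    TRFModel,
    boost,
    cross_validate,
    explained_variability,
    predict,
    unique_power,
)
from cohorttrf.predictors import PredictorSet, standardize


def naive_convolution(kernels, delays, features):
    """Independent oracle: double-loop evaluation of the TRF prediction."""
    n_time = features.shape[1]
    yhat = np.zeros(n_time)
    for i in range(features.shape[0]):
        for h, d in zip(kernels[i], delays):
            for t in range(n_time):
                if 0 <= t - d < n_time:
                    yhat[t] += h * features[i, t - d]
    return yhat


@pytest.fixture(scope="module")
def basis():
    return TRFBasis()


class TestBasis:
    def test_dimensions(self, basis):
        assert basis.n_delays == 110
        assert basis.n_basis == 110
        assert basis.delays[0] == -10
        assert basis.delays[-1] == 99

    def test_columns_nonnegative_and_nonempty(self, basis):
        assert (basis.matrix >= 0).all()
        assert (basis.matrix.sum(axis=0) > 0).all()

    def test_expand_is_linear(self, basis):
        rng = np.random.default_rng(0)
        w1, w2 = rng.normal(size=(2, basis.n_basis))
        np.testing.assert_allclose(
            basis.expand(2.0 * w1 - 3.0 * w2),
            2.0 * basis.expand(w1) - 3.0 * basis.expand(w2),
            atol=1e-12,
        )

    def test_round_trip_within_span(self, basis):
        rng = np.random.default_rng(1)
        w = rng.normal(size=basis.n_basis)
        kernel = basis.expand(w)
        np.testing.assert_allclose(basis.expand(basis.project(kernel)), kernel,
                                   atol=1e-9)


class TestPredict:
    def test_delayed_impulse(self, basis):
        x = np.zeros((1, 50))
        x[0, 10] = 1.0
        kernel = np.zeros(basis.n_delays)
        kernel[list(basis.delays).index(3)] = 1.0  # delta at +3 samples
        model = TRFModel(basis, ["x0"], basis.project(kernel)[None, :])
        yhat = predict(model, x)
        assert yhat.argmax() == 13
        assert yhat[13] == pytest.approx(1.0, abs=1e-9)

    def test_zero_kernels(self, basis):
        model = TRFModel(basis, ["a", "b"], np.zeros((2, basis.n_basis)))
        x = np.random.default_rng(0).normal(size=(2, 100))
        assert np.abs(predict(model, x)).max() == 0.0

    def test_matches_naive_convolution(self, basis):
        rng = np.random.default_rng(42)
        weights = rng.normal(size=(2, basis.n_basis)) * 0.1
        model = TRFModel(basis, ["a", "b"], weights)
        features = rng.normal(size=(2, 200))
        yhat = predict(model, features)
        oracle = naive_convolution(model.kernels, basis.delays, features)
        np.testing.assert_allclose(yhat, oracle, atol=1e-10)

    def test_linearity(self, basis):
        rng = np.random.default_rng(3)
        w1, w2 = rng.normal(size=(2, 1, basis.n_basis))
        x = rng.normal(size=(1, 150))
        m = lambda w: TRFModel(basis, ["x0"], w)
        lhs = predict(m(2.5 * w1 + 0.5 * w2), x)
        rhs = 2.5 * predict(m(w1), x) + 0.5 * predict(m(w2), x)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_channel_mismatch_rejected(self, basis):
        model = TRFModel(basis, ["a"], np.zeros((1, basis.n_basis)))
        ps = PredictorSet({"b": np.zeros(50)})
        with pytest.raises(ValueError, match="match"):
            predict(model, ps)


def _sim_predictors(rng, n_time=3000, n_events=150):
    x = np.zeros((2, n_time))
    for i in range(2):
        idx = rng.choice(n_time - 120, size=n_events, replace=False)
        x[i, idx] = rng.gamma(2.0, 1.0, size=n_events)
    return x


def _two_peak_weights(basis, rng=None, gain=1.0):
    t = basis.delay_times
    kern = gain * (
        np.exp(-((t - 0.10) ** 2) / (2 * 0.02**2))
        - 0.7 * np.exp(-((t - 0.30) ** 2) / (2 * 0.02**2))
    )
    return basis.project(kern)


class TestBoost:
    def test_zero_response_returns_zero_kernels(self, basis):
        rng = np.random.default_rng(0)
        x = _sim_predictors(rng, 1000, 50)
        model = boost(x, np.zeros(1000), np.arange(600), np.arange(600, 1000),
                      basis=basis)
        assert np.abs(model.weights).max() == 0.0

    def test_noiseless_recovery(self, basis):
        rng = np.random.default_rng(7)
        x = _sim_predictors(rng)
        w_true = np.array([_two_peak_weights(basis), 0.5 * _two_peak_weights(basis)])
        truth = TRFModel(basis, ["x0", "x1"], w_true)
        y = predict(truth, x)
        n = len(y)
        model = boost(x, y, np.arange(0, 2 * n // 3), np.arange(2 * n // 3, n),
                      step=0.005, max_iter=4000, basis=basis)
        for i in range(2):
            r = np.corrcoef(model.kernels[i], truth.kernels[i])[0, 1]
            assert r >= 0.95

    def test_white_noise_no_spurious_fit(self, basis):
        rng = np.random.default_rng(11)
        x = _sim_predictors(rng, 2000, 100)
        y = rng.normal(size=2000)
        tr, va = np.arange(1300), np.arange(1300, 2000)
        model = boost(x, y, tr, va, step=0.01, max_iter=500, basis=basis)
        val_err = np.abs(y[va] - predict(model, x)[va]).sum()
        zero_err = np.abs(y[va]).sum()
        assert val_err <= zero_err * (1 + 1e-6)

    def test_invalid_inputs(self, basis):
        x = np.zeros((1, 100))
        with pytest.raises(ValueError, match="step"):
            boost(x, np.zeros(100), np.arange(50), np.arange(50, 100), step=0.0)
        y = np.zeros(100)
        y[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            boost(x, y, np.arange(50), np.arange(50, 100))
        with pytest.raises(ValueError, match="overlap"):
            boost(x, np.zeros(100), np.arange(60), np.arange(50, 100))


class TestExplainedVariability:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert explained_variability(y, y) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([0.0, 2.0, 4.0])
        assert explained_variability(y, np.full(3, 2.0)) == 0.0

    def test_hand_case(self):
        assert explained_variability(
            np.array([0.0, 2.0]), np.array([1.0, 1.0])
        ) == pytest.approx(0.0)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            explained_variability(np.ones(5), np.zeros(5))


class TestCrossValidate:
    def test_boost_call_count_is_k_times_k_minus_1(self):
        rng = np.random.default_rng(0)
        x = _sim_predictors(rng, 1500, 60)
        y = rng.normal(size=1500) * 0.1
        small = TRFBasis(0.0, 0.2)
        fit = cross_validate(x, y, k=5, step=0.05, max_iter=5, basis=small)
        assert fit.n_boost_calls == 20

    def test_k_below_3_rejected(self):
        with pytest.raises(ValueError, match="k >= 3"):
            cross_validate(np.zeros((1, 100)), np.zeros(100), k=2)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        x = _sim_predictors(rng, 1200, 60)
        w = _two_peak_weights(TRFBasis(0.0, 0.3))
        basis = TRFBasis(0.0, 0.3)
        y = predict(TRFModel(basis, ["x0", "x1"], np.array([w, w * 0.3])), x)
        y = y + np.random.default_rng(6).normal(0, y.std(), len(y))
        f1 = cross_validate(x, y, k=3, step=0.02, max_iter=200, basis=basis)
        f2 = cross_validate(x, y, k=3, step=0.02, max_iter=200, basis=basis)
        assert (f1.weights == f2.weights).all()
        assert (f1.power == f2.power).all()

    def test_informative_predictor_beats_noise(self):
        """Held-out power of the true model exceeds the power obtained after
        permuting the informative predictor's event values."""
        basis = TRFBasis(0.0, 0.4)
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            x = _sim_predictors(rng, 2000, 120)
            w = _two_peak_weights(basis)
            y = predict(TRFModel(basis, ["x0", "x1"], np.array([w, 0.4 * w])), x)
            y = standardize(y + rng.normal(0, y.std() / 2, len(y)))
            fit = cross_validate(x, y, k=3, step=0.02, max_iter=300, basis=basis)
            xp = x.copy()
            nz = np.flatnonzero(xp[0])
            xp[0, nz] = xp[0, nz][rng.permutation(len(nz))]
            fitp = cross_validate(xp, y, k=3, step=0.02, max_iter=300, basis=basis)
            wins += fit.power[0] > fitp.power[0]
        assert wins >= n_rep - 1

    def test_sources_fit_independently(self):
        rng = np.random.default_rng(9)
        x = _sim_predictors(rng, 1000, 50)
        basis = TRFBasis(0.0, 0.2)
        y = rng.normal(size=(2, 1000))
        fit = cross_validate(x, y, k=3, step=0.05, max_iter=20, basis=basis)
        flipped = cross_validate(x, y[::-1], k=3, step=0.05, max_iter=20, basis=basis)
        np.testing.assert_allclose(fit.power, flipped.power[::-1], atol=1e-12)
        np.testing.assert_allclose(fit.weights, flipped.weights[::-1], atol=1e-12)


class TestUniquePower:
    def test_self_difference_zero(self):
        rng = np.random.default_rng(2)
        x = _sim_predictors(rng, 900, 40)
        basis = TRFBasis(0.0, 0.2)
        fit = cross_validate(x, rng.normal(size=900), k=3, step=0.05, max_iter=10,
                             basis=basis)
        np.testing.assert_allclose(unique_power(fit, fit), 0.0, atol=1e-15)

    def test_fold_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        x = _sim_predictors(rng, 900, 40)
        basis = TRFBasis(0.0, 0.2)
        y = rng.normal(size=900)
        f3 = cross_validate(x, y, k=3, step=0.05, max_iter=5, basis=basis)
        f4 = cross_validate(x, y, k=4, step=0.05, max_iter=5, basis=basis)
        with pytest.raises(ValueError, match="fold"):
            unique_power(f3, f4)


class TestModelResultsInterface:
    def test_fit_returns_results_with_summary(self):
        from cohorttrf.mtrf import TemporalResponseModel

        rng = np.random.default_rng(4)
        x = _sim_predictors(rng, 1500, 80)
        basis = TRFBasis(0.0, 0.4)
        w = _two_peak_weights(basis)
        ps = PredictorSet({"drive": x[0], "other": x[1]})
        y = predict(TRFModel(basis, ["drive", "other"], np.array([w, 0 * w])), x)
        y = y + rng.normal(0, y.std() / 3, len(y))
        model = TemporalResponseModel(y, ps, basis=basis)
        res = model.fit(k=3, step=0.02, max_iter=300)
        text = res.summary()
        assert "drive" in text and "l1 explained" in text
        assert res.power[0] > 0.02
        assert res.kernels.shape == (1, 2, basis.n_delays)
        yhat = res.predict()
        assert yhat.shape == y.shape
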