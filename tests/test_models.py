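"""PLS, single-hidden-layer ANN and the prediction-correction network."""

import numpy as np
import pytest

from nircal import ANNConfig, PCNNCalibration, fit_ann, fit_pls, predict_ann
from nircal.models import PLSCalibration, _select_n_latent_cv
from nircal.nn import ACTIVATIONS, MLPParams, mlp_forward, _init_params
from nircal.preprocess import MinMaxScaler
from nircal.simulate import (DistortionConfig, gen_realistic_samples,
                             gen_standard_samples, realistic_composition,
                             standards_composition)


class TestPLS:
    def test_single_collinear_predictor_exact(self):
        x = np.random.default_rng(0).random((10, 1))
        y = 2.0 * x.ravel()
        pls = fit_pls(x, y, 1)
        np.testing.assert_allclose(pls.predict(x).ravel(), y, atol=1e-10)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 5))
        y = X @ [1.0, -2.0, 0.5, 3.0, -1.0] + 0.3 + rng.standard_normal(20) * 0.1
        pls = fit_pls(X, y, 5)
        beta = np.linalg.lstsq(np.column_stack([np.ones(20), X]), y,
                               rcond=None)[0]
        np.testing.assert_allclose(pls.coef_.ravel(), beta[1:], atol=1e-8)

    def test_refit_deterministic(self):
        rng = np.random.default_rng(2)
        X, y = rng.random((15, 4)), rng.random(15)
        c1 = fit_pls(X, y, 3).coef_
        c2 = fit_pls(X, y, 3).coef_
        np.testing.assert_array_equal(c1, c2)

    def test_rank_deficiency_reported(self):
        X = np.outer(np.arange(8.0), [1.0, 2.0, 3.0])  # rank 1
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, np.arange(8.0), 3)

    def test_cv_latent_selection_bounded(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 10))
        y = X[:, 0] + 0.1 * rng.standard_normal(30)
        lv = _select_n_latent_cv(X, y)
        assert 1 <= lv <= 20


class TestANN:
    def test_training_deterministic_bit_for_bit(self):
        rng = np.random.default_rng(4)
        Z, y = rng.standard_normal((30, 5)), rng.random(30)
        cfg = ANNConfig(n_neurons=6, activation="tanh", epochs=200, seed=9)
        p1, p2 = fit_ann(Z, y, cfg), fit_ann(Z, y, cfg)
        np.testing.assert_array_equal(p1.loss_trace, p2.loss_trace)
        np.testing.assert_array_equal(p1.W1, p2.W1)

    def test_learns_linear_map(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((60, 4))
        y = (Z @ [0.2, -0.1, 0.3, 0.05]) * 0.2 + 0.5  # inside [0,1]
        cfg = ANNConfig(n_neurons=8, activation="relu", epochs=12000, seed=1)
        p = fit_ann(Z, y, cfg)
        rmse = np.sqrt(np.mean((mlp_forward(p, Z) - y) ** 2))
        assert rmse <= 1e-2

    def test_zero_weights_predict_bias_constant(self):
        p = MLPParams(W1=np.zeros((3, 4)), b1=np.zeros(4),
                      W2=np.zeros(4), b2=0.7, activation="tanh")
        out = mlp_forward(p, np.random.default_rng(6).random((5, 3)))
        np.testing.assert_allclose(out, 0.7)

    def test_row_permutation_permutes_outputs(self):
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((10, 3))
        p = _init_params(3, 5, seed=2, activation="swish")
        perm = rng.permutation(10)
        np.testing.assert_allclose(mlp_forward(p, Z[perm]),
                                   mlp_forward(p, Z)[perm])

    def test_published_style_config_trains(self):
        # 9 neurons / ReLU / 4000 epochs — the shipped protein ANN setting
        cfg = ANNConfig(n_neurons=9, activation="relu", epochs=4000, seed=3)
        rng = np.random.default_rng(8)
        Z, y = rng.standard_normal((25, 6)), rng.random(25)
        p = fit_ann(Z, y, cfg)
        assert np.isfinite(p.loss_trace).all()
        # loss settles: non-increasing over the last 10% within tolerance
        tail = p.loss_trace[-400:]
        assert tail[-1] <= tail[0] + 1e-6

    def test_all_activations_have_consistent_gradients(self):
        # finite-difference check of each activation derivative
        x = np.linspace(-2, 2, 41) + 0.003  # avoid the relu kink at 0
        for name, (f, g) in ACTIVATIONS.items():
            num = (f(x + 1e-6) - f(x - 1e-6)) / 2e-6
            np.testing.assert_allclose(g(x, f(x)), num, atol=1e-5,
                                       err_msg=name)

    def test_loss_is_mean_squared_error_of_forward_pass(self):
        # 2-sample fixture: first recorded loss equals the hand-computed
        # MSE of the freshly initialised network
        Z = np.array([[0.3, -0.2], [0.1, 0.4]])
        y = np.array([0.2, 0.9])
        cfg = ANNConfig(n_neurons=3, activation="tanh", epochs=1, seed=5)
        p0 = _init_params(2, 3, seed=5, activation="tanh")
        hand = np.mean((y - (np.tanh(Z @ p0.W1 + p0.b1) @ p0.W2 + p0.b2)) ** 2)
        trained = fit_ann(Z, y, cfg)
        assert trained.loss_trace[0] == pytest.approx(hand, rel=1e-12)

    def test_predict_ann_inverse_scales(self):
        p = MLPParams(W1=np.zeros((2, 2)), b1=np.zeros(2), W2=np.zeros(2),
                      b2=0.5, activation="tanh")
        sc = MinMaxScaler().fit([10.0, 20.0])
        out = predict_ann(p, np.zeros((3, 2)), sc)
        np.testing.assert_allclose(out, 15.0)


@pytest.fixture(scope="module")
def small_pcnn_world(small_lib):
    """Standards + biased realistic samples on the short grid."""
    dist = DistortionConfig.none()
    dist.reference_bias = {"protein": 1.5}
    standards = gen_standard_samples(small_lib, standards_composition(),
                                     n=60, seed=100)
    real = gen_realistic_samples(small_lib, realistic_composition(), dist,
                                 n=70, seed=101)
    cal = real.subset(np.arange(25))
    val = real.subset(np.arange(25, 70))
    return standards, cal, val


def _small_configs():
    return (ANNConfig(n_neurons=16, activation="tanh", epochs=8000, seed=11),
            ANNConfig(n_neurons=2, activation="tanh", epochs=800, seed=12))


class TestPCNN:
    def test_additivity_exact(self, small_pcnn_world):
        std, cal, val = small_pcnn_world
        pnn_cfg, cnn_cfg = _small_configs()
        res = PCNNCalibration(std, cal, "protein", pnn_cfg, cnn_cfg,
                              k=10, threshold=0.0).fit()
        pred = res.predict(val)
        np.testing.assert_array_equal(pred.y_hat, pred.y0 + pred.y_eps)

    def test_zeroed_cnn_reduces_to_pnn_plus_constant(self, small_pcnn_world):
        std, cal, val = small_pcnn_world
        pnn_cfg, cnn_cfg = _small_configs()
        res = PCNNCalibration(std, cal, "protein", pnn_cfg, cnn_cfg,
                              k=10, threshold=0.0).fit()
        res.cnn.W1[:] = 0.0
        res.cnn.W2[:] = 0.0
        res.cnn.b2 = 0.25
        pred = res.predict(val)
        const = res.cnn_scaler.inverse_transform([0.25])[0]
        np.testing.assert_allclose(pred.y_eps, const)
        np.testing.assert_allclose(pred.y_hat, pred.y0 + const)

    def test_correction_recovers_injected_reference_bias(self, small_pcnn_world):
        std, cal, val = small_pcnn_world
        pnn_cfg, cnn_cfg = _small_configs()
        res = PCNNCalibration(std, cal, "protein", pnn_cfg, cnn_cfg,
                              k=10, threshold=0.0).fit()
        pred = res.predict(val)
        y_val = val.component_values("protein")
        beta = 1.5
        err_pnn = np.mean(pred.y0 - y_val)
        err_combined = np.mean(pred.y_hat - y_val)
        # the prediction network misses by about -beta; the correction
        # network cancels most of it
        assert abs(err_pnn + beta) <= 0.35 * beta
        assert abs(err_combined) <= 0.2 * beta

    def test_small_correction_when_domains_match(self, small_lib):
        # calibration drawn from the same generator as the standards:
        # nothing to correct, so corrections stay small vs validation S
        std = gen_standard_samples(small_lib, standards_composition(),
                                   n=99, seed=200)
        extra = gen_standard_samples(small_lib, standards_composition(),
                                     n=60, seed=201)
        cal = extra.subset(np.arange(25))
        val = extra.subset(np.arange(25, 60))
        res = PCNNCalibration(
            std, cal, "protein",
            ANNConfig(n_neurons=10, activation="tanh", epochs=4000, seed=11),
            ANNConfig(n_neurons=2, activation="tanh", epochs=800, seed=12),
            k=10, threshold=0.0).fit()
        pred = res.predict(val)
        s_val = np.std(val.component_values("protein"), ddof=1)
        assert np.mean(np.abs(pred.y_eps)) <= 0.10 * s_val

    def test_calibration_floor_and_grid_mismatch_rejected(self, small_pcnn_world):
        std, cal, val = small_pcnn_world
        pnn_cfg, cnn_cfg = _small_configs()
        with pytest.raises(ValueError, match="at least 3"):
            PCNNCalibration(std, cal.subset([0, 1]), "protein",
                            pnn_cfg, cnn_cfg)
        from nircal import resample_to_grid

        shrunk = resample_to_grid(cal, cal.grid[10:50])
        with pytest.raises(ValueError, match="grid"):
            PCNNCalibration(std, shrunk, "protein", pnn_cfg, cnn_cfg)

    def test_published_style_config_parses_and_trains(self, small_pcnn_world):
        # PNN 10/tanh/300 + CNN 2/tanh/3000 — shipped protein PCNN setting
        std, cal, val = small_pcnn_world
        res = PCNNCalibration(
            std, cal, "protein",
            ANNConfig(n_neurons=10, activation="tanh", epochs=300, seed=1),
            ANNConfig(n_neurons=2, activation="tanh", epochs=3000, seed=2),
            k=10, threshold=0.0).fit()
        assert np.isfinite(res.loss1).all() and np.isfinite(res.loss2).all()

    def test_dataset_level_pls_and_summary(self, small_pcnn_world):
        std, cal, val = small_pcnn_world
        res = PLSCalibration(cal, "protein", n_latent=5).fit()
        rep = res.validation_report(val)
        assert rep.n_val == val.n_samples
        assert "PLS" in res.summary()
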