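import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import delaypinn as dp
from delaypinn import (DelayPinnModel, KernelMixture, ModelConfig,
                       TimeTraceSet, TrainingConfig, data_loss,
                       kl_regularization, physics_loss, physics_residual,
                       scale_regularization, scale_target, train)
from delaypinn._autodiff import Tensor
from delaypinn.model import DecodedParams
from delaypinn.training import _epoch_losses, _moving_average


class TestDataLoss:
    def test_zero_on_identity(self, rng):
        y = rng.uniform(size=(3, 6))
        assert float(data_loss(Tensor(y), y).data) == 0.0

    def test_constant_offset(self, rng):
        y = rng.uniform(size=(4, 5))
        assert float(data_loss(Tensor(y + 0.3), y).data) == pytest.approx(0.3)

    def test_small_example(self):
        # residuals (1, -3) -> (1 + 3) / 2 = 2
        y_tilde = Tensor(np.array([[2.0, 1.0]]))
        y = np.array([[1.0, 4.0]])
        assert float(data_loss(y_tilde, y).data) == pytest.approx(2.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            data_loss(Tensor(np.zeros((2, 3))), np.zeros((2, 4)))


class TestPhysicsLoss:
    def test_exact_solution_oracle(self, rng):
        """Construct y(t) = lb * int_0^t exp(-ld (t-u)) G(u) du by quadrature
        for random mixtures; the residual of the exact solution vanishes."""
        for _ in range(10):
            mix = KernelMixture(
                centers=np.sort(rng.uniform(0, 3, 3)),
                scales=rng.uniform(0.3, 1.5, 3),
                weights=np.array([0.2, 0.3, 0.5]),
            )
            lb, ld = rng.uniform(0.5, 3), rng.uniform(0.2, 1.5)
            colloc = np.linspace(0, 8, 15)
            y = np.array([
                integrate.quad(lambda u, t=t: np.exp(-ld * (t - u)) * mix.cdf(u),
                               0, t, limit=200)[0] * lb
                for t in colloc
            ])
            ydot = lb * mix.cdf(colloc) - ld * y  # from the governing equation
            g_int = mix.cdf(colloc)
            res = physics_residual(ydot[None, :], y[None, :], g_int[None, :],
                                   lb, ld)
            assert float(res.data) <= 1e-10

    def test_quadrature_vs_direct_derivative(self, rng):
        """Independent check: numerical derivative of the quadrature solution
        matches lb*G - ld*y, so the residual formula targets the right ODE."""
        mix = KernelMixture(centers=[0.5, 2.0], scales=[0.5, 0.8],
                            weights=[0.4, 0.6])
        lb, ld = 2.0, 0.7
        t_dense = np.linspace(0, 8, 2001)
        y = dp.mean_trace_ode(lb, ld, mix.cdf, t_dense)
        ydot = np.gradient(y, t_dense)
        inner = slice(10, -10)
        res = physics_residual(ydot[None, inner], y[None, inner],
                               mix.cdf(t_dense)[None, inner], lb, ld)
        assert float(res.data) <= 1e-4

    def test_trivial_zero_solution(self, tiny_trained_inputs):
        model, dec, omega_p = tiny_trained_inputs
        # at t = 0 every kernel cdf and pdf vanish: residual is exactly 0
        res = physics_loss(model, dec, omega_p, np.array([0.0]))
        assert float(res.data) == 0.0

    def test_steady_state_zero_residual(self):
        """Far beyond every kernel, y = 1, G = 1, pdf = 0; with lb = ld the
        equation is satisfied exactly."""
        grid = np.linspace(0, 7, 8)
        model = DelayPinnModel(grid, ModelConfig(smax=2.0), seed=0)
        n = 3
        omega = Tensor(np.full((n, model.M), 1.0 / model.M))
        s = Tensor(np.full((n, model.M), 1.0))
        lam = Tensor(np.full((n, 1), 0.8))
        dec = DecodedParams(omega=omega, s=s, lambda_b=lam, lambda_d=lam)
        colloc = np.linspace(200.0, 210.0, 5)
        res = physics_loss(model, dec, omega, colloc)
        assert float(res.data) < 1e-12

    @pytest.fixture
    def tiny_trained_inputs(self, rng):
        grid = np.linspace(0, 7, 8)
        model = DelayPinnModel(grid, ModelConfig(), seed=0)
        dec = model.decode(rng.normal(size=(3, 4)))
        omega_p = model.transform_weights(dec.omega)
        return model, dec, omega_p


class TestScaleTarget:
    def test_extremes_map_to_bounds(self):
        grid = np.linspace(0, 10, 11)
        # logistic-like rise: steepest in the middle
        y = 1.0 / (1.0 + np.exp(-(grid - 5)))
        beta, target = scale_target(y[None, :], grid, window=1, smin=0.5,
                                    smax=2.0)
        j_max = np.argmax(np.gradient(y, grid))
        assert beta[0, j_max] == pytest.approx(1.0)
        assert target[0, j_max] == pytest.approx(0.5)
        assert target[0, np.argmin(beta[0])] == pytest.approx(2.0)
        assert np.all((beta >= 0) & (beta <= 1))
        assert np.all((target >= 0.5) & (target <= 2.0))

    def test_moving_average_of_constant(self):
        y = np.full((2, 20), 3.3)
        np.testing.assert_allclose(_moving_average(y, 7), 3.3, atol=1e-12)

    def test_flat_trace_warns_target_smax(self):
        grid = np.linspace(0, 5, 6)
        with pytest.warns(UserWarning, match="flat"):
            beta, target = scale_target(np.ones((1, 6)), grid, window=7,
                                        smin=0.2, smax=1.5)
        np.testing.assert_array_equal(beta, 0.0)
        np.testing.assert_array_equal(target, 1.5)


class TestScaleRegularization:
    def test_zero_at_target(self):
        t = np.full((2, 5), 1.2)
        assert float(scale_regularization(Tensor(t), t).data) == 0.0

    def test_constant_offset(self):
        t = np.full((2, 5), 1.2)
        assert float(scale_regularization(Tensor(t + 0.25), t).data) == \
            pytest.approx(0.25)

    def test_bounded_by_box_width(self, rng):
        smin, smax = 0.5, 2.0
        s = rng.uniform(smin, smax, (3, 7))
        t = rng.uniform(smin, smax, (3, 7))
        assert float(scale_regularization(Tensor(s), t).data) <= smax - smin


class TestKLRegularization:
    def test_prior_match_is_zero(self):
        mu = Tensor(np.zeros((3, 4)))
        sigma = Tensor(np.ones((3, 4)))
        assert float(kl_regularization(mu, sigma).data) == pytest.approx(0.0)

    def test_half_mu_squared(self):
        mu = Tensor(np.array([[1.0, 0.0, 0.0, 0.0]]))
        sigma = Tensor(np.ones((1, 4)))
        assert float(kl_regularization(mu, sigma).data) == pytest.approx(0.5)

    def test_monte_carlo_oracle(self, rng):
        mu = np.array([[0.4, -0.9, 0.2, 1.1]])
        sd = np.array([[0.7, 1.3, 0.5, 1.0]])
        z = mu + sd * rng.standard_normal((200_000, 4))
        logq = -0.5 * (((z - mu) / sd) ** 2 + np.log(2 * np.pi * sd**2))
        logp = -0.5 * (z**2 + np.log(2 * np.pi))
        mc = (logq - logp).sum(axis=1).mean()
        closed = float(kl_regularization(Tensor(mu), Tensor(sd)).data)
        assert closed == pytest.approx(mc, abs=0.02)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            kl_regularization(Tensor(np.zeros((1, 4))),
                              Tensor(np.zeros((1, 4))))


def _small_dataset(n=8, seed=0):
    sc = dp.preset_scenarios(n_traces=n)["unimodal"]
    tts, _ = dp.generate_dataset(sc, seed=seed)
    return tts


class TestTrainLoop:
    CFG = dict(max_epochs=60, patience=60, collocation_count=41)

    def test_total_is_sum_of_terms(self):
        tts = _small_dataset()
        model, hist = train(tts, model_config=ModelConfig(smax=2.0),
                            config=TrainingConfig(**self.CFG), seed=0)
        np.testing.assert_allclose(
            hist["total"],
            hist[["data", "physics", "scale_reg", "kl_reg"]].sum(axis=1),
            atol=1e-12)

    def test_seeded_determinism(self):
        tts = _small_dataset()
        _, h1 = train(tts, config=TrainingConfig(**self.CFG), seed=11)
        _, h2 = train(tts, config=TrainingConfig(**self.CFG), seed=11)
        pd.testing.assert_frame_equal(h1, h2)

    def test_different_seeds_differ(self):
        tts = _small_dataset()
        _, h1 = train(tts, config=TrainingConfig(**self.CFG), seed=1)
        _, h2 = train(tts, config=TrainingConfig(**self.CFG), seed=2)
        assert not np.allclose(h1["total"], h2["total"])

    def test_beats_constant_predictor(self):
        from delaypinn.model import standardize

        tts = _small_dataset(n=20, seed=3)
        cfg = TrainingConfig(max_epochs=500, patience=500,
                             collocation_count=41)
        model, hist = train(tts, model_config=ModelConfig(smax=2.0),
                            config=cfg, seed=0)
        y_std, _ = standardize(tts, mode="scale")
        best_const = np.abs(y_std - np.median(y_std)).mean()
        assert hist["data"].iloc[-1] < best_const

    def test_trained_flag_and_history_columns(self):
        tts = _small_dataset()
        model, hist = train(tts, config=TrainingConfig(**self.CFG), seed=0)
        assert model.trained
        assert list(hist.columns) == ["epoch", "data", "physics", "scale_reg",
                                      "kl_reg", "total", "val_total"]

    def test_early_stopping_restores_best(self):
        tts = _small_dataset()
        cfg = TrainingConfig(max_epochs=300, patience=10, collocation_count=41)
        model, hist = train(tts, config=cfg, seed=0)
        assert len(hist) <= 300
        assert model.trained

    def test_nonfinite_abort_names_term(self):
        tts = _small_dataset()
        model = DelayPinnModel(tts.grid, ModelConfig(), seed=0)
        model._layers["enc1"][0].data[0, 0] = np.nan
        from delaypinn.model import standardize

        y_std, _ = standardize(tts, mode="scale")
        with pytest.raises(RuntimeError, match="data"):
            _epoch_losses(model, y_std, np.zeros((y_std.shape[0], 4)),
                          tts.grid, np.full((y_std.shape[0], model.M), 1.0),
                          (1, 1, 1, 1))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainingConfig(patience=0)
        with pytest.raises(ValueError):
            TrainingConfig(collocation_count=1)
        with pytest.raises(ValueError):
            TrainingConfig(val_fraction=1.5)


class TestGradients:
    def test_total_loss_gradcheck(self, rng):
        """Finite differences vs backprop on a tiny model (d = 8, M = 8)."""
        grid = np.linspace(0, 7, 8)
        model = DelayPinnModel(grid, ModelConfig(smax=2.0), seed=2)
        y = np.cumsum(rng.uniform(0, 0.3, size=(3, 8)), axis=1)
        eps = rng.standard_normal((3, 4))
        colloc = np.linspace(0, 7, 15)
        targets = np.full((3, 8), 1.0)

        def loss_value():
            total, _ = _epoch_losses(model, y, eps, colloc, targets,
                                     (1, 1, 1, 1))
            return total

        total = loss_value()
        for p in model.parameters:
            p.grad = None
        total.backward()

        h = 1e-6
        checked = 0
        for name in ("enc1", "om3", "sc3", "rt2", "wn2"):
            w = model._layers[name][0]
            for idx in [(0, 0), (w.data.shape[0] - 1, w.data.shape[1] - 1)]:
                orig = w.data[idx]
                w.data[idx] = orig + h
                up = float(loss_value().data)
                w.data[idx] = orig - h
                dn = float(loss_value().data)
                w.data[idx] = orig
                fd = (up - dn) / (2 * h)
                ad = w.grad[idx]
                denom = max(abs(fd), abs(ad), 1e-8)
                assert abs(fd - ad) / denom < 1e-4, (name, idx, fd, ad)
                checked += 1
        assert checked == 10
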