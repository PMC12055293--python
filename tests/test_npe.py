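"""Mixture density network and the amortized posterior estimator."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

import reefsbi as rb
from reefsbi.mdn import MDNConfig, MixtureDensityNetwork
from reefsbi.npe import ThetaTransform, load_estimator, save_estimator


def _toy_linear_gaussian(n=8000, seed=0, noise_sd=0.1):
    """x = A theta + eps with standard-normal theta: conjugate posterior known."""
    rng = np.random.default_rng(seed)
    A = np.array([[1.0, 0.5], [0.2, -1.0], [0.7, 0.3]])
    theta = rng.standard_normal((n, 2))
    x = theta @ A.T + noise_sd * rng.standard_normal((n, 3))
    return A, theta, x, noise_sd


class TestMDNCore:
    def test_analytic_gradients_match_finite_differences(self):
        cfg = MDNConfig(hidden_layers=2, units_per_layer=8, n_components=3)
        net = MixtureDensityNetwork(4, 3, cfg, seed=0)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 4))
        Y = rng.standard_normal((12, 3))
        loss, gW, gb = net._loss_and_grads(X, Y)
        eps = 1e-6
        for plist, glist in ((net.weights, gW), (net.biases, gb)):
            for p, g in zip(plist, glist):
                flat, gflat = p.reshape(-1), g.reshape(-1)
                for idx in rng.choice(flat.size, size=3, replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp, _, _ = net._loss_and_grads(X, Y)
                    flat[idx] = orig - eps
                    lm, _, _ = net._loss_and_grads(X, Y)
                    flat[idx] = orig
                    assert (lp - lm) / (2 * eps) == pytest.approx(
                        gflat[idx], rel=1e-4, abs=1e-7
                    )

    def test_mixture_weights_sum_to_one(self):
        cfg = MDNConfig()
        net = MixtureDensityNetwork(7, 5, cfg, seed=3)
        X = np.random.default_rng(0).standard_normal((1000, 7))
        w, _, _ = net.mixture_params(X)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(w > 0)

    def test_single_component_reduces_to_gaussian(self):
        """With K=1 and hand-set outputs the density is the closed-form normal."""
        cfg = MDNConfig(hidden_layers=1, units_per_layer=4, n_components=1)
        net = MixtureDensityNetwork(2, 2, cfg, seed=0)
        # zero the MLP so outputs equal the output bias
        for W in net.weights:
            W[...] = 0.0
        mu = np.array([0.3, -0.7])
        # precision Cholesky U (lower): diag exp(s), one off-diagonal
        s = np.array([0.2, -0.4])
        off = np.array([0.5])
        net.biases[-1][...] = np.concatenate([[0.0], mu, s, off])
        U = np.array([[np.exp(0.2), 0.0], [0.5, np.exp(-0.4)]])
        cov = np.linalg.inv(U @ U.T)
        y = np.array([[0.1, 0.2]])
        expected = stats.multivariate_normal(mu, cov).logpdf(y)
        got = net.log_prob(np.zeros((1, 2)), y)
        assert got[0] == pytest.approx(float(expected), abs=1e-6)

    def test_sampler_matches_analytic_moments(self):
        cfg = MDNConfig(hidden_layers=1, units_per_layer=4, n_components=1)
        net = MixtureDensityNetwork(2, 2, cfg, seed=0)
        for W in net.weights:
            W[...] = 0.0
        mu = np.array([1.0, -2.0])
        net.biases[-1][...] = np.concatenate([[0.0], mu, [0.0, 0.0], [0.0]])
        s = net.sample(np.zeros(2), 100_000, seed=4)
        se = 1.0 / np.sqrt(100_000)
        assert np.all(np.abs(s.mean(axis=0) - mu) < 3 * se)
        np.testing.assert_allclose(np.cov(s.T), np.eye(2), atol=0.02)

    def test_seeded_training_is_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((400, 3))
        Y = X[:, :2] + 0.1 * rng.standard_normal((400, 2))
        cfg = MDNConfig(hidden_layers=1, units_per_layer=16, n_components=2,
                        max_epochs=5, early_stop_patience=50)
        n1 = MixtureDensityNetwork(3, 2, cfg, seed=9)
        l1 = n1.fit(X, Y, seed=11)
        n2 = MixtureDensityNetwork(3, 2, cfg, seed=9)
        l2 = n2.fit(X, Y, seed=11)
        assert l1["val_loss"] == l2["val_loss"]

    def test_early_stopping_improves_validation(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((600, 3))
        Y = 2 * X[:, :2] + 0.05 * rng.standard_normal((600, 2))
        cfg = MDNConfig(hidden_layers=1, units_per_layer=16, n_components=2,
                        max_epochs=60)
        net = MixtureDensityNetwork(3, 2, cfg, seed=0)
        log = net.fit(X, Y, seed=1)
        assert log["best_val_loss"] <= log["val_loss"][0]


class TestConjugateRecovery:
    def test_linear_gaussian_posterior_within_ten_percent(self):
        """MDN posterior matches the conjugate closed form on a linear toy."""
        A, theta, x, sd = _toy_linear_gaussian()
        train = rb.SimulatedDataset(
            theta, x, rb.WavelengthGrid(np.array([1.0, 2.0, 3.0]))
        )
        cfg = MDNConfig(n_components=2, max_epochs=150, learning_rate=1e-3)
        est = rb.train_estimator(train, cfg, seed=5, transform="none",
                                 truncate_to_support=False)
        Sig = np.linalg.inv(np.eye(2) + A.T @ A / sd**2)
        x0 = np.array([0.5, -0.3, 0.2])
        mu = Sig @ (A.T @ x0 / sd**2)
        samples = rb.sample_posterior(est, x0, 40_000, seed=6)
        got_mu = samples.mean(axis=0)
        got_cov = np.cov(samples.T)
        scale = np.sqrt(np.diag(Sig))
        assert np.all(np.abs(got_mu - mu) < 0.1 * scale + 0.1 * np.abs(mu))
        assert np.all(np.abs(np.diag(got_cov) - np.diag(Sig)) <= 0.1 * np.diag(Sig) + 1e-4)


class TestEstimatorServices:
    def test_uninformative_data_recovers_prior(self, priors):
        """x independent of theta -> posterior ~ prior marginals."""
        rng = np.random.default_rng(2)
        thetas = rb.sample_prior(priors, 4000, seed=21)
        X = rng.standard_normal((4000, 8))  # pure noise, no information
        train = rb.SimulatedDataset(thetas, X, rb.WavelengthGrid(np.arange(8) + 400.0))
        cfg = MDNConfig(max_epochs=40)
        est = rb.train_estimator(train, cfg, seed=3)
        samples = rb.sample_posterior(est, X[0], 20_000, seed=4)
        for j in range(5):
            prior_col = thetas[:, j]
            assert samples[:, j].mean() == pytest.approx(
                prior_col.mean(), rel=0.10, abs=0.1 * prior_col.std()
            )
            assert samples[:, j].std() == pytest.approx(prior_col.std(), rel=0.15)

    def test_samples_respect_prior_support(self, trained_bundle):
        est = trained_bundle.estimator
        x = trained_bundle.test.X[0]
        s = rb.sample_posterior(est, x, 2000, seed=0)
        assert s[:, 0].max() <= 7.0
        assert s[:, 1].max() <= 2.5
        assert s[:, 2].max() <= 30.0
        assert s[:, 4].min() >= 0.10 and s[:, 4].max() <= 20.00
        np.testing.assert_array_equal(
            s, rb.sample_posterior(est, x, 2000, seed=0)
        )

    def test_log_prob_minus_inf_outside_support(self, trained_bundle):
        est = trained_bundle.estimator
        x = trained_bundle.test.X[0]
        bad = np.array([8.0, 0.05, 0.5, 5.0, 5.0])  # phytoplankton above cap
        assert rb.log_prob(est, bad, x) == -np.inf
        good = trained_bundle.test.theta[0]
        assert np.isfinite(rb.log_prob(est, good, x))

    def test_marginal_density_integrates_to_one(self, trained_bundle):
        """1-D depth marginal of the mixture integrates to ~1 by quadrature."""
        est = trained_bundle.estimator
        x = trained_bundle.test.X[1]
        xs = est._check_x(x)
        w, means, U = est.net.mixture_params(xs)
        w, means, U = w[0], means[0], U[0]
        j = 4  # depth
        # marginal of component k in transformed-standardized space:
        # variance = [ (U U^T)^{-1} ]_jj
        covs = [np.linalg.inv(U[k] @ U[k].T) for k in range(len(w))]

        def marginal_pdf(z):
            return sum(
                wk * stats.norm.pdf(z, means[k][j], np.sqrt(covs[k][j, j]))
                for k, wk in enumerate(w)
            )

        val, _ = quad(marginal_pdf, -12, 12, limit=200)
        assert val == pytest.approx(1.0, abs=1e-2)

    def test_marginal_interval_extremes_and_oracle(self, trained_bundle):
        est = trained_bundle.estimator
        x = trained_bundle.test.X[2]
        iv = rb.marginal_interval(est, x, 0, 100, n=500, seed=1)
        samples = rb.sample_posterior(est, x, 500, seed=1)
        np.testing.assert_allclose(iv[:, 0], samples.min(axis=0))
        np.testing.assert_allclose(iv[:, 1], samples.max(axis=0))
        med = np.median(samples, axis=0)
        iv2 = rb.marginal_interval(est, x, 5, 95, n=500, seed=1)
        assert np.all((med >= iv2[:, 0]) & (med <= iv2[:, 1]))
        # independent sort-based percentile oracle
        lo_oracle = np.sort(samples, axis=0)[int(0.05 * 500) - 1]
        assert np.all(np.abs(iv2[:, 0] - lo_oracle) <= np.abs(lo_oracle) * 0.2 + 0.2)

    def test_wrong_band_count_rejected(self, trained_bundle):
        with pytest.raises(ValueError, match="bands"):
            rb.sample_posterior(trained_bundle.estimator, np.zeros(7), 10, seed=0)

    def test_save_load_round_trip(self, trained_bundle, tmp_path):
        est = trained_bundle.estimator
        path = tmp_path / "est.npz"
        save_estimator(est, path)
        back = load_estimator(path)
        x = trained_bundle.test.X[3]
        theta = trained_bundle.test.theta[3]
        assert rb.log_prob(back, theta, x) == pytest.approx(
            rb.log_prob(est, theta, x), rel=1e-12
        )
        np.testing.assert_array_equal(
            rb.sample_posterior(back, x, 100, seed=5),
            rb.sample_posterior(est, x, 100, seed=5),
        )


class TestThetaTransform:
    def test_round_trip(self):
        tf = ThetaTransform.reef_default()
        theta = np.array([[0.3, 0.05, 0.5, 6.0, 5.0], [6.9, 2.4, 29.0, 0.1, 19.9]])
        np.testing.assert_allclose(tf.inverse(tf.forward(theta)), theta, rtol=1e-12)

    def test_jacobian_matches_finite_difference(self):
        tf = ThetaTransform.reef_default()
        theta = np.array([[0.3, 0.05, 0.5, 6.0, 5.0]])
        eps = 1e-7
        num = 0.0
        for j in range(5):
            tp = theta.copy(); tp[0, j] += eps
            tm = theta.copy(); tm[0, j] -= eps
            num += np.log(
                (tf.forward(tp)[0, j] - tf.forward(tm)[0, j]) / (2 * eps)
            )
        assert tf.log_abs_det_jacobian(theta)[0] == pytest.approx(num, rel=1e-5)
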