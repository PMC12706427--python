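import numpy as np
import pytest
from scipy import integrate, stats

import vaenlme as v
from vaenlme.encoder import PosteriorApprox
from vaenlme.models import ErrorModel
from vaenlme.objective import (AnnealSchedule, PopulationParameters,
                               anneal_weight, bicc_elbo, elbo,
                               elbo_parts_with_grads, kl_gaussian,
                               reconstruction_loglik)
from conftest import make_conjugate_dataset, conjugate_loglik


class TestReconstructionLoglik:
    def test_single_exact_value(self):
        assert reconstruction_loglik([1.0], [1.0], ErrorModel("constant", 1.0)) \
            == pytest.approx(-0.918938533)

    def test_doubling_sd_with_zero_residuals(self):
        x = np.zeros(4)
        l1 = reconstruction_loglik(x, x, ErrorModel("constant", 1.0))
        l2 = reconstruction_loglik(x, x, ErrorModel("constant", 2.0))
        assert l1 - l2 == pytest.approx(4 * np.log(2.0))

    def test_monotone_in_residual(self):
        vals = [reconstruction_loglik([r], [0.0], ErrorModel("constant", 0.5))
                for r in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_loglik([1.0, 2.0], [1.0], ErrorModel("constant", 1.0))


class TestKLGaussian:
    def test_identical_distributions_zero(self):
        L = np.linalg.cholesky(np.diag([0.3, 0.7]))
        assert kl_gaussian([1.0, 2.0], L, [1.0, 2.0], [0.3, 0.7]) \
            == pytest.approx(0.0, abs=1e-12)

    def test_unit_mean_shift(self):
        assert kl_gaussian([1.0], [[1.0]], [0.0], [1.0]) == pytest.approx(0.5)

    def test_variance_mismatch_vs_numeric_integration(self):
        # KL(N(0,1) || N(0,4)) by quadrature
        p = stats.norm(0, 1)
        q = stats.norm(0, 2)
        val, _ = integrate.quad(lambda x: p.pdf(x) * (p.logpdf(x) - q.logpdf(x)), -10, 10)
        assert kl_gaussian([0.0], [[1.0]], [0.0], [4.0]) == pytest.approx(val, rel=1e-8)
        assert kl_gaussian([0.0], [[1.0]], [0.0], [4.0]) \
            == pytest.approx(0.5 * (0.25 - 1 + np.log(4)))

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            nz = rng.integers(1, 5)
            A = rng.standard_normal((nz, nz))
            L = np.linalg.cholesky(A @ A.T + np.eye(nz) * 0.1)
            kl = kl_gaussian(rng.standard_normal(nz), L,
                             rng.standard_normal(nz), rng.uniform(0.1, 3, nz))
            assert kl >= 0

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            kl_gaussian([0.0], [[-1.0]], [0.0], [1.0])


class TestAnnealing:
    def test_schedule_endpoints_and_midpoint(self):
        s = AnnealSchedule(burn_in_iters=50, anneal_end_iter=100, start_weight=0.2)
        assert anneal_weight(0, s) == pytest.approx(0.2)
        assert anneal_weight(50, s) == pytest.approx(0.6)
        assert anneal_weight(100, s) == 1.0
        assert anneal_weight(5000, s) == 1.0

    def test_monotone(self):
        s = AnnealSchedule(burn_in_iters=10, anneal_end_iter=40, start_weight=0.1)
        ws = [anneal_weight(k, s) for k in range(60)]
        assert all(b >= a for a, b in zip(ws, ws[1:]))


class TestBiccElbo:
    def test_counting(self):
        beta = np.zeros((3, 2))
        assert bicc_elbo(-100.0, beta, 12) == pytest.approx(200.0)
        beta[0, 0] = 1.5
        assert bicc_elbo(-100.0, beta, 12) == pytest.approx(200.0 + np.log(12))
        beta[2, 1] = -0.3
        assert bicc_elbo(-100.0, beta, 12) == pytest.approx(200.0 + 2 * np.log(12))


class TestElbo:
    def _setup(self):
        ds, X, _ = make_conjugate_dataset(N=12, n=4, seed=3)
        model = v.direct_observation_model(1)
        theta = PopulationParameters([1.8], np.zeros((1, 0)), [0.2],
                                     ErrorModel("constant", 0.5))
        posts = [PosteriorApprox(np.array([float(x.mean())]), np.array([[0.2]]))
                 for x in X]
        return ds, model, theta, posts

    def test_zero_kl_weight_is_reconstruction(self):
        ds, model, theta, posts = self._setup()
        rng = np.random.default_rng(0)
        total, recon, kl = elbo(ds, model, theta, posts, 3, kl_weight=0.0,
                                rng=np.random.default_rng(0))
        assert total == pytest.approx(recon)
        assert kl > 0

    def test_degenerate_posterior_is_plugin_loglik(self):
        ds, model, theta, posts = self._setup()
        tiny = [PosteriorApprox(p.mean, np.array([[1e-10]])) for p in posts]
        total, recon, _ = elbo(ds, model, theta, tiny, 5, kl_weight=0.0,
                               rng=np.random.default_rng(1))
        direct = sum(
            reconstruction_loglik(ind.observations,
                                  np.full(ind.n_obs, p.mean[0]), theta.error)
            for ind, p in zip(ds.individuals, tiny))
        assert recon == pytest.approx(direct, rel=1e-9)

    def test_maximized_elbo_attains_marginal_loglik(self):
        # conjugate toy: with the exact posterior as q, ELBO == LL exactly
        ds, X, _ = make_conjugate_dataset(N=20, n=4, seed=9)
        model = v.direct_observation_model(1)
        zpop, om2, a2 = 1.7, 0.3, 0.25
        n = 4
        theta = PopulationParameters([zpop], np.zeros((1, 0)), [om2],
                                     ErrorModel("constant", np.sqrt(a2)))
        post_var = 1.0 / (n / a2 + 1.0 / om2)
        posts = [PosteriorApprox(
            [post_var * (x.sum() / a2 + zpop / om2)],
            [[np.sqrt(post_var)]]) for x in X]
        total, _, _ = elbo(ds, model, theta, posts, 4000,
                           rng=np.random.default_rng(2))
        ll = conjugate_loglik(X, zpop, om2, a2)
        assert total == pytest.approx(ll, abs=0.05)

    def test_posterior_gradients_match_finite_difference(self):
        ds, model, theta, posts = self._setup()
        mu = np.vstack([p.mean for p in posts])
        L = np.stack([p.chol for p in posts])
        eps = np.random.default_rng(5).standard_normal((2, ds.N, 1))
        parts = elbo_parts_with_grads(ds, model, theta, mu, L, eps, kl_weight=0.7)
        h = 1e-6
        for i in (0, 5):
            for arr, grad in ((mu, parts["dmu"]), (L, parts["dL"])):
                ix = (i, 0) if arr is mu else (i, 0, 0)
                old = arr[ix]
                arr[ix] = old + h
                up = elbo_parts_with_grads(ds, model, theta, mu, L, eps,
                                           kl_weight=0.7, want_grad=False)["elbo"]
                arr[ix] = old - h
                dn = elbo_parts_with_grads(ds, model, theta, mu, L, eps,
                                           kl_weight=0.7, want_grad=False)["elbo"]
                arr[ix] = old
                assert grad[ix] == pytest.approx((up - dn) / (2 * h), rel=1e-4, abs=1e-8)
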