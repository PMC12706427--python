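import numpy as np
import pytest

import vaenlme as v
from vaenlme.encoder import PosteriorApprox
from vaenlme.evaluate import BiccBreakdown, bicc, gof_tables, loglik_is
from vaenlme.models import ErrorModel
from vaenlme.objective import PopulationParameters
from conftest import make_conjugate_dataset, conjugate_loglik


@pytest.fixture(scope="module")
def conjugate_with_exact_posteriors():
    ds, X, _ = make_conjugate_dataset(N=25, n=4, seed=13)
    zpop, om2, a2 = 1.9, 0.3, 0.25
    n = 4
    theta = PopulationParameters([zpop], np.zeros((1, 0)), [om2],
                                 ErrorModel("constant", np.sqrt(a2)))
    post_var = 1.0 / (n / a2 + 1.0 / om2)
    posts = [PosteriorApprox([post_var * (x.sum() / a2 + zpop / om2)],
                             [[np.sqrt(post_var)]]) for x in X]
    model = v.direct_observation_model(1)
    exact = conjugate_loglik(X, zpop, om2, a2)
    return ds, model, theta, posts, exact


class TestLoglikIS:
    def test_matches_closed_form(self, conjugate_with_exact_posteriors):
        ds, model, theta, posts, exact = conjugate_with_exact_posteriors
        ll = loglik_is(ds, model, theta, posts, M=500,
                       rng=np.random.default_rng(0))
        assert abs(ll.minus2LL - (-2 * exact)) <= max(3 * ll.mc_se, 1e-6)

    def test_exact_proposal_gives_zero_variance(self, conjugate_with_exact_posteriors):
        # with the exact posterior as proposal the weights are constant
        ds, model, theta, posts, exact = conjugate_with_exact_posteriors
        ll = loglik_is(ds, model, theta, posts, M=200,
                       rng=np.random.default_rng(1))
        assert ll.mc_se == pytest.approx(0.0, abs=1e-8)
        assert ll.minus2LL == pytest.approx(-2 * exact, rel=1e-9)

    def test_se_shrinks_with_more_samples(self, conjugate_with_exact_posteriors):
        ds, model, theta, posts, _ = conjugate_with_exact_posteriors
        wide = [PosteriorApprox(p.mean, p.chol * 2.5) for p in posts]
        ses = []
        for M in (100, 3200):
            vals = [loglik_is(ds, model, theta, wide, M=M,
                              rng=np.random.default_rng(s)).mc_se
                    for s in range(5)]
            ses.append(np.mean(vals))
        assert ses[1] < ses[0]

    def test_order_invariance(self, conjugate_with_exact_posteriors):
        ds, model, theta, posts, _ = conjugate_with_exact_posteriors
        ll = loglik_is(ds, model, theta, posts, M=100,
                       rng=np.random.default_rng(3))
        perm = v.PopulationDataset(list(reversed(ds.individuals)),
                                   ds.covariate_names, ds.covariate_meta)
        llp = loglik_is(perm, model, theta, list(reversed(posts)), M=100,
                        rng=np.random.default_rng(3))
        assert ll.minus2LL == pytest.approx(llp.minus2LL, rel=1e-9)
        assert ll.minus2LL == pytest.approx(-2 * float(np.sum(ll.per_individual)))

    def test_degenerate_proposal_rejected(self, conjugate_with_exact_posteriors):
        ds, model, theta, posts, _ = conjugate_with_exact_posteriors
        bad = [PosteriorApprox(p.mean, [[1e-13]]) for p in posts]
        with pytest.raises(ValueError, match="degenerate|diagonal"):
            loglik_is(ds, model, theta, bad, M=10)


class TestBicc:
    def _ll(self, value=332.2):
        return v.LikelihoodEstimate(minus2LL=value, mc_se=0.1, M=100,
                                    per_individual=np.zeros(12))

    def test_counting_all_iiv_constant_error(self):
        theta = PopulationParameters(np.zeros(3), np.zeros((3, 2)),
                                     np.ones(3), ErrorModel("constant", 1.0))
        out = bicc(self._ll(), theta, N=12, Ntot=132)
        assert out.dim_thetaR == 6 and out.dim_thetaF == 1
        assert out.bicc == pytest.approx(332.2 + 6 * np.log(12) + np.log(132))

    def test_one_selected_effect_adds_logN(self):
        theta = PopulationParameters(np.zeros(3), np.zeros((3, 2)),
                                     np.ones(3), ErrorModel("constant", 1.0))
        base = bicc(self._ll(), theta, N=12, Ntot=132).bicc
        theta.beta[0, 0] = 2.5
        assert bicc(self._ll(), theta, N=12, Ntot=132).bicc \
            == pytest.approx(base + np.log(12))

    def test_declared_convention_example(self):
        # 8 random-effect-linked + 1 fixed dims at -2LL = 332.2
        theta = PopulationParameters(np.zeros(3), np.zeros((3, 2)),
                                     np.ones(3), ErrorModel("constant", 1.0))
        theta.beta[0, 0] = 2.55
        theta.beta[2, 0] = 0.57
        out = bicc(self._ll(), theta, N=12, Ntot=132)
        assert out.dim_thetaR == 8 and out.dim_thetaF == 1
        assert out.bicc == pytest.approx(356.96, abs=0.01)

    def test_breakdown_identity_enforced(self):
        with pytest.raises(ValueError):
            BiccBreakdown(minus2LL=100.0, dim_thetaR=2, dim_thetaF=1,
                          N=10, Ntot=50, bicc=123.456)


class TestGofTables:
    def test_zero_noise_self_consistency(self):
        ds, truth = v.theophylline_like(N=6, seed=4)
        model = v.theophylline_model()
        theta = truth.theta_true
        # replace observations by exact predictions at the prior means
        mu = theta.prior_means(ds.covariate_matrix())
        preds = v.predict_population(model, model.transform_inverse(mu), ds)
        for ind, p in zip(ds.individuals, preds):
            ind.observations = p.copy()
        posts = [PosteriorApprox(mu[i], np.eye(3) * 1e-6) for i in range(ds.N)]
        tab = gof_tables(ds, model, theta, posts)
        np.testing.assert_allclose(tab["IRES"], 0.0, atol=1e-8)
        np.testing.assert_allclose(tab["RES"], 0.0, atol=1e-8)
        assert len(tab) == ds.Ntot

    def test_population_prediction_ignores_observations(self):
        ds, truth = v.theophylline_like(N=4, seed=6)
        model = v.theophylline_model()
        mu = truth.theta_true.prior_means(ds.covariate_matrix())
        posts = [PosteriorApprox(mu[i], np.eye(3) * 0.01) for i in range(ds.N)]
        t1 = gof_tables(ds, model, truth.theta_true, posts)
        for ind in ds.individuals:
            ind.observations = ind.observations + 1.0
        t2 = gof_tables(ds, model, truth.theta_true, posts)
        np.testing.assert_allclose(t1["PRED"], t2["PRED"])
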