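import numpy as np
import pytest

import vaenlme as v

THEOPH_CSV = __file__.rsplit("/", 2)[0] + "/data/theophylline_synthetic_sex.csv"


def make_conjugate_dataset(N=60, n=5, zpop=2.0, omega=0.4, a=0.5, seed=7,
                           beta=None, covariates=None):
    """Balanced one-way random-effects data: x_ij = z_i + e_ij.

    The marginal likelihood is Gaussian and available in closed form, which
    makes this the exactness oracle for the whole estimation machinery.
    """
    rng = np.random.default_rng(seed)
    if covariates is None:
        C = np.zeros((N, 0))
    else:
        C = np.asarray(covariates, dtype=float)
    eff = np.zeros(N) if beta is None else C @ np.atleast_1d(beta)
    z = zpop + eff + omega * rng.standard_normal(N)
    X = z[:, None] + a * rng.standard_normal((N, n))
    individuals = [
        v.Individual(id=i, times=np.arange(1, n + 1, dtype=float),
                     observations=X[i], covariates=C[i])
        for i in range(N)
    ]
    names = [f"c{j}" for j in range(C.shape[1])]
    ds = v.PopulationDataset(individuals, covariate_names=names,
                             covariate_meta=[{"name": nm, "kind": "continuous",
                                              "transform": "none"} for nm in names])
    return ds, X, z


def conjugate_mle(X):
    """Closed-form MLE of the balanced one-way random-effects model."""
    N, n = X.shape
    xbar = X.mean(axis=1)
    grand = X.mean()
    ssw = float(((X - xbar[:, None]) ** 2).sum())
    a2 = ssw / (N * (n - 1))
    om2 = float(((xbar - grand) ** 2).mean()) - a2 / n
    return grand, om2, a2


def conjugate_loglik(X, mu, om2, a2):
    """Exact marginal log-likelihood of the balanced one-way model."""
    N, n = X.shape
    xbar = X.mean(axis=1)
    logdet = (n - 1) * np.log(a2) + np.log(a2 + n * om2)
    quad = ((X - xbar[:, None]) ** 2).sum(axis=1) / a2 \
        + n * (xbar - mu) ** 2 / (a2 + n * om2)
    return float(np.sum(-0.5 * (n * np.log(2 * np.pi) + logdet + quad)))


@pytest.fixture(scope="session")
def conjugate_case():
    ds, X, z = make_conjugate_dataset()
    return ds, X, z


@pytest.fixture(scope="session")
def theoph_synthetic_small():
    """Small theophylline-like synthetic dataset shared across tests."""
    ds, truth = v.theophylline_like(N=30, seed=11)
    return ds, truth
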