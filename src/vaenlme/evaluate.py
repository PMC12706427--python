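"""Post-fit evaluation: importance-sampling likelihood, BICc, GOF tables.

The marginal log-likelihood is estimated per individual by importance
sampling with the trained encoder posterior as the proposal,

    LL_i = log (1/M) sum_m p(x_i | z^(m)) p(z^(m); zpop + beta c_i, Omega)
                            / q(z^(m) | x_i),

computed with log-sum-exp; the Monte Carlo standard error follows from the
delta method on the normalized weights. BICc penalizes random-effect-linked
parameters by log N and the rest by log Ntot; the counting convention is
recorded in the returned breakdown so alternatives can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .models import error_logpdf, predict_population
from .objective import PopulationParameters

__all__ = ["LikelihoodEstimate", "BiccBreakdown", "loglik_is", "bicc", "gof_tables"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class LikelihoodEstimate:
    minus2LL: float
    mc_se: float           # MC standard error of minus2LL
    M: int
    per_individual: np.ndarray

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("need at least two importance samples")
        if self.mc_se < 0:
            raise ValueError("mc_se must be non-negative")


@dataclass
class BiccBreakdown:
    minus2LL: float
    dim_thetaR: int
    dim_thetaF: int
    N: int
    Ntot: int
    bicc: float
    convention: str = (
        "dim_thetaR = fixed effects with IIV + selected covariate effects on "
        "IIV parameters + variances; dim_thetaF = fixed effects without IIV "
        "+ their covariate effects + error parameters"
    )

    def __post_init__(self) -> None:
        expected = self.minus2LL + math.log(self.N) * self.dim_thetaR \
            + math.log(self.Ntot) * self.dim_thetaF
        if abs(self.bicc - expected) > 1e-8 * max(1.0, abs(expected)):
            raise ValueError("bicc does not match its own breakdown")


def _sample_predictions(model, Z, individual):
    """Predictions for M parameter draws of a single individual."""
    pseudo = SimpleNamespace(individuals=[individual] * Z.shape[0])
    return predict_population(model, model.transform_inverse(Z), pseudo)


def loglik_is(dataset, model, theta: PopulationParameters, posteriors,
              M: int = 1000, rng: np.random.Generator | None = None) -> LikelihoodEstimate:
    """Importance-sampling estimate of -2 LL(theta) with its MC standard error."""
    if rng is None:
        rng = np.random.default_rng(0)
    nz = theta.nz
    C = dataset.covariate_matrix()
    prior_means = theta.prior_means(C)
    log_det_omega = float(np.sum(np.log(theta.omega2)))
    ll = np.empty(dataset.N)
    var_ll = np.empty(dataset.N)
    for i, (ind, post) in enumerate(zip(dataset.individuals, posteriors)):
        Ld = np.diag(post.chol)
        if np.any(Ld <= 1e-12):
            raise ValueError(f"degenerate proposal for individual {ind.id}")
        eps = rng.standard_normal((M, nz))
        Z = post.mean + eps @ post.chol.T
        # log q: Gaussian with Cholesky factor
        log_q = -0.5 * (nz * _LOG2PI + np.sum(eps**2, axis=1)) - float(np.sum(np.log(Ld)))
        dev = Z - prior_means[i]
        log_prior = -0.5 * (nz * _LOG2PI + log_det_omega
                            + np.sum(dev**2 / theta.omega2, axis=1))
        preds = _sample_predictions(model, Z, ind)
        log_px = np.array([float(np.sum(error_logpdf(ind.observations, p, theta.error)))
                           for p in preds])
        logw = log_px + log_prior - log_q
        ll[i] = logsumexp(logw) - math.log(M)
        # delta method: var(log wbar) ~= var(w) / (M wbar^2), stably via shifts
        shifted = np.exp(logw - np.max(logw))
        wbar = float(np.mean(shifted))
        var_ll[i] = float(np.var(shifted)) / (M * wbar**2)
    minus2 = -2.0 * float(np.sum(ll))
    se = 2.0 * math.sqrt(float(np.sum(var_ll)))
    return LikelihoodEstimate(minus2LL=minus2, mc_se=se, M=M, per_individual=ll)


def bicc(ll: LikelihoodEstimate, theta: PopulationParameters,
         iiv_flags=None, selection=None, N: int | None = None,
         Ntot: int | None = None) -> BiccBreakdown:
    """BICc = -2LL + log(N) dim(thetaR) + log(Ntot) dim(thetaF).

    ``iiv_flags`` marks which structural parameters carry inter-individual
    variability (default: all). Selected covariate effects are the nonzero
    entries of ``theta.beta`` (or of ``selection.beta`` when given).
    """
    nz = theta.nz
    if iiv_flags is None:
        iiv_flags = np.ones(nz, dtype=bool)
    iiv_flags = np.asarray(iiv_flags, dtype=bool)
    beta = selection.beta if selection is not None else theta.beta
    n_beta_iiv = int(np.count_nonzero(beta[iiv_flags])) if beta.size else 0
    n_beta_fix = int(np.count_nonzero(beta[~iiv_flags])) if beta.size else 0
    dim_r = int(np.sum(iiv_flags)) + n_beta_iiv + int(np.sum(iiv_flags))
    dim_f = int(np.sum(~iiv_flags)) + n_beta_fix + theta.error.n_params
    if N is None or Ntot is None:
        raise ValueError("N and Ntot are required")
    value = ll.minus2LL + math.log(N) * dim_r + math.log(Ntot) * dim_f
    return BiccBreakdown(minus2LL=ll.minus2LL, dim_thetaR=dim_r, dim_thetaF=dim_f,
                         N=N, Ntot=Ntot, bicc=value)


def gof_tables(dataset, model, theta: PopulationParameters, posteriors) -> pd.DataFrame:
    """Per-observation goodness-of-fit table.

    Population predictions evaluate the model at zeta = h^-1(zpop + beta c_i)
    (no random effects); individual predictions use each subject's MAP
    estimate h^-1(mu_i).
    """
    C = dataset.covariate_matrix()
    Z_pop = theta.prior_means(C)
    Z_map = np.vstack([p.mean for p in posteriors])
    pred_pop = predict_population(model, model.transform_inverse(Z_pop), dataset)
    pred_ind = predict_population(model, model.transform_inverse(Z_map), dataset)
    rows = []
    for i, ind in enumerate(dataset.individuals):
        for j in range(ind.n_obs):
            dv = ind.observations[j]
            rows.append({
                "ID": ind.id, "TIME": ind.times[j], "DV": dv,
                "PRED": pred_pop[i][j], "IPRED": pred_ind[i][j],
                "RES": dv - pred_pop[i][j], "IRES": dv - pred_ind[i][j],
            })
    return pd.DataFrame(rows)
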