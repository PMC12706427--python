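"""Variational objectives for mixed-effects estimation.

The training objective is an ELBO adapted to the hierarchical model: per
individual, a Monte Carlo reconstruction term (Gaussian observation
log-likelihood at decoder predictions from reparameterized posterior
samples) minus the closed-form KL divergence between the Gaussian posterior
q(z_i|x_i) = N(mu_i, Sigma_i) and the population prior
N(zpop + beta c_i, Omega). The covariate-selection variant is the BICc-ELBO

    -2 * ELBO + log(N) * ||beta||_0   (additive constant dropped),

whose fixed-effect update becomes an L0-penalized best-subset problem
(see :mod:`vaenlme.mstep`). A burn-in/annealing schedule weights the KL term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import ErrorModel, error_dlogpdf_dpred, error_logpdf, predict_population

__all__ = [
    "PopulationParameters",
    "AnnealSchedule",
    "anneal_weight",
    "reconstruction_loglik",
    "kl_gaussian",
    "elbo",
    "bicc_elbo",
    "elbo_parts_with_grads",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class PopulationParameters:
    """theta = (zpop, beta, Omega diagonal, error model)."""

    zpop: np.ndarray
    beta: np.ndarray        # (nz, nc)
    omega2: np.ndarray      # (nz,)
    error: ErrorModel

    def __post_init__(self) -> None:
        self.zpop = np.asarray(self.zpop, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.omega2 = np.asarray(self.omega2, dtype=float)
        nz = self.zpop.size
        if self.beta.shape[0] != nz and self.beta.size == 0:
            self.beta = np.zeros((nz, 0))
        if self.beta.shape[0] != nz or self.omega2.size != nz:
            raise ValueError("inconsistent parameter dimensions")
        if np.any(self.omega2 <= 0):
            raise ValueError("omega2 must be strictly positive")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")

    @property
    def nz(self) -> int:
        return self.zpop.size

    @property
    def nc(self) -> int:
        return self.beta.shape[1]

    def prior_means(self, covariates: np.ndarray) -> np.ndarray:
        """m_i = zpop + beta c_i for a stacked (N, nc) covariate block."""
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if self.nc == 0:
            return np.tile(self.zpop, (C.shape[0], 1))
        return self.zpop + C @ self.beta.T

    def copy(self) -> "PopulationParameters":
        return PopulationParameters(self.zpop.copy(), self.beta.copy(),
                                    self.omega2.copy(),
                                    ErrorModel(self.error.kind, self.error.a, self.error.b))

    def flatten(self) -> np.ndarray:
        err = [self.error.a] if self.error.n_params == 1 else [self.error.a, self.error.b]
        return np.concatenate([self.zpop, self.beta.ravel(), self.omega2, err])


@dataclass
class AnnealSchedule:
    """Linear KL-weight ramp: start_weight at iteration 0, 1 from anneal_end on."""

    burn_in_iters: int = 100
    anneal_end_iter: int = 200
    start_weight: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.start_weight <= 1.0:
            raise ValueError("start_weight must lie in [0, 1]")
        if self.burn_in_iters > self.anneal_end_iter:
            raise ValueError("burn-in must end before annealing completes")


def anneal_weight(iteration: int, sched: AnnealSchedule) -> float:
    """KL weight at an iteration: monotone linear ramp, constant 1 afterward."""
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    if sched.anneal_end_iter <= 0 or iteration >= sched.anneal_end_iter:
        return 1.0
    frac = iteration / sched.anneal_end_iter
    return sched.start_weight + frac * (1.0 - sched.start_weight)


def reconstruction_loglik(x, pred, err: ErrorModel) -> float:
    """Sum of Gaussian observation log-densities for one individual."""
    x = np.asarray(x, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if x.shape != pred.shape:
        raise ValueError("observations and predictions differ in length")
    return float(np.sum(error_logpdf(x, pred, err)))


def kl_gaussian(mu, chol, m, omega2) -> float:
    """KL( N(mu, L L^T) || N(m, diag(omega2)) ), closed form.

    0.5 [ tr(Omega^-1 Sigma) + (m-mu)^T Omega^-1 (m-mu) - nz
          + log det Omega - log det Sigma ]
    """
    mu = np.asarray(mu, dtype=float)
    m = np.asarray(m, dtype=float)
    L = np.asarray(chol, dtype=float)
    omega2 = np.asarray(omega2, dtype=float)
    nz = mu.size
    d = np.diag(L)
    if np.any(d <= 0) or not np.all(np.isfinite(L)):
        raise ValueError("covariance factor must be lower-triangular with positive diagonal")
    sigma_diag = np.sum(L**2, axis=1)
    quad = np.sum((m - mu) ** 2 / omega2)
    return 0.5 * float(
        np.sum(sigma_diag / omega2) + quad - nz
        + np.sum(np.log(omega2)) - 2.0 * np.sum(np.log(d))
    )


def bicc_elbo(elbo_value: float, beta: np.ndarray, N: int) -> float:
    """-2 ELBO + log(N) * number of nonzero covariate effects (constant dropped)."""
    if N < 2:
        raise ValueError("N must be at least 2")
    l0 = int(np.count_nonzero(np.asarray(beta)))
    return -2.0 * float(elbo_value) + math.log(N) * l0


def _kl_block(mu, L, M, omega2):
    """Vectorized KL and its (mu, L) gradients for stacked posteriors.

    mu (N, nz), L (N, nz, nz), M (N, nz) prior means, omega2 (nz,).
    Returns (kl_per_individual, dKL/dmu, dKL/dL).
    """
    inv = 1.0 / omega2
    diagL = np.einsum("nkk->nk", L)
    sigma_diag = np.sum(L**2, axis=2)
    dev = mu - M
    kl = 0.5 * (
        sigma_diag @ inv + (dev**2) @ inv - mu.shape[1]
        + np.sum(np.log(omega2)) - 2.0 * np.sum(np.log(diagL), axis=1)
    )
    dmu = dev * inv
    dL = L * inv[None, :, None]
    idx = np.arange(mu.shape[1])
    dL[:, idx, idx] -= 1.0 / diagL
    tril = np.tril(np.ones((mu.shape[1],) * 2))
    return kl, dmu, dL * tril


def _predictions_and_zgrad(model, Z, dataset, fd_step=1e-4, want_grad=True):
    """Decoder predictions and their Jacobian w.r.t. the transformed z.

    Central finite differences on the transformed scale (nz is small, each
    probe is one vectorized population prediction). Predictions come back
    both as a per-individual list and concatenated; the Jacobian is a flat
    (nz, Ntot) block aligned with the concatenation.
    """
    zeta = model.transform_inverse(Z)
    preds = predict_population(model, zeta, dataset)
    flat = np.concatenate(preds)
    if not want_grad:
        return preds, flat, None
    nz = Z.shape[1]
    J = np.empty((nz, flat.size))
    for k in range(nz):
        Zp = Z.copy()
        Zp[:, k] += fd_step
        Zm = Z.copy()
        Zm[:, k] -= fd_step
        pp = predict_population(model, model.transform_inverse(Zp), dataset)
        pm = predict_population(model, model.transform_inverse(Zm), dataset)
        J[k] = (np.concatenate(pp) - np.concatenate(pm)) / (2.0 * fd_step)
    return preds, flat, J


def elbo_parts_with_grads(dataset, model, theta: PopulationParameters,
                          mu: np.ndarray, L: np.ndarray, eps: np.ndarray,
                          kl_weight: float = 1.0, want_grad: bool = True):
    """ELBO pieces and gradients w.r.t. the stacked posterior (mu, L).

    eps has shape (S, N, nz): S reparameterized samples per individual. The
    reconstruction term is the Monte Carlo average over samples; the KL term
    is closed form. Returned gradients are of the *annealed* ELBO
    (recon - kl_weight * KL), to be ascended.

    Returns a dict with totals, per-individual parts, the sampled residual
    statistics reused by the M-step (pred/obs pairs per sample) and, when
    ``want_grad``, d/dmu (N, nz) and d/dL (N, nz, nz).
    """
    S, N, nz = eps.shape
    C = dataset.covariate_matrix()
    M = theta.prior_means(C)
    kl, kdmu, kdL = _kl_block(mu, L, M, theta.omega2)
    recon_i = np.zeros(N)
    dmu = np.zeros_like(mu) if want_grad else None
    dL = np.zeros_like(L) if want_grad else None
    obs_flat = np.concatenate([ind.observations for ind in dataset.individuals])
    counts = np.array([ind.n_obs for ind in dataset.individuals])
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    sample_preds = []
    for s in range(S):
        Z = mu + np.einsum("nab,nb->na", L, eps[s])
        preds, pred_flat, J = _predictions_and_zgrad(model, Z, dataset, want_grad=want_grad)
        sample_preds.append(preds)
        ll_flat = error_logpdf(obs_flat, pred_flat, theta.error)
        recon_i += np.add.reduceat(ll_flat, starts) / S
        if want_grad:
            gpred = error_dlogpdf_dpred(obs_flat, pred_flat, theta.error)
            gz = np.add.reduceat(J * gpred, starts, axis=1).T / S  # (N, nz)
            dmu += gz
            dL += gz[:, :, None] * eps[s][:, None, :]
    if want_grad:
        tril = np.tril(np.ones((nz, nz)))
        dL = dL * tril - kl_weight * kdL
        dmu = dmu - kl_weight * kdmu
    recon = float(np.sum(recon_i))
    kl_total = float(np.sum(kl))
    return {
        "elbo": recon - kl_weight * kl_total,
        "elbo_full_kl": recon - kl_total,
        "recon": recon,
        "kl": kl_total,
        "recon_i": recon_i,
        "kl_i": kl,
        "dmu": dmu,
        "dL": dL,
        "sample_preds": sample_preds,
    }


def elbo(dataset, model, theta: PopulationParameters, posteriors,
         samples_per_individual: int = 1, kl_weight: float = 1.0,
         rng: np.random.Generator | None = None):
    """Monte Carlo ELBO at given posteriors.

    Returns ``(total, recon_total, kl_total)`` where
    ``total = recon - kl_weight * kl``.
    """
    if samples_per_individual < 1:
        raise ValueError("need at least one sample per individual")
    if rng is None:
        rng = np.random.default_rng(0)
    N = dataset.N
    nz = theta.nz
    mu = np.vstack([p.mean for p in posteriors])
    L = np.stack([p.chol for p in posteriors])
    eps = rng.standard_normal((samples_per_individual, N, nz))
    parts = elbo_parts_with_grads(dataset, model, theta, mu, L, eps,
                                  kl_weight=kl_weight, want_grad=False)
    return parts["elbo"], parts["recon"], parts["kl"]
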