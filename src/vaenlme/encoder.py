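"""Amortized Gaussian posterior over individual parameters.

A single subject-independent LSTM reads each individual's measurement
sequence (normalized time, normalized observation, time increment per step;
optionally the coded covariates as static channels) and two affine heads map
the final hidden state to the posterior mean and the Cholesky factor of the
posterior covariance on the transformed parameter scale:

    q(z_i | x_i) = N(mu_i, L_i L_i^T).

Sampling uses the reparameterization z = mu + L eps with eps ~ N(0, I), so
gradients flow through (mu, L) into the network weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, LSTMStack, init_uniform_fan_in, softplus, softplus_inv

__all__ = [
    "EncoderConfig",
    "PosteriorApprox",
    "GaussianSequenceEncoder",
    "compute_feature_stats",
    "featurize",
    "encode",
    "sample_latent",
    "posterior_readout",
]

_DIAG_FLOOR = 1e-6

#: per-step channels before optional covariates: t, x, dt, dx
N_BASE_FEATURES = 4


@dataclass
class EncoderConfig:
    hidden_dim: int | None = None  # default max(16, 4 nz), resolved at build time
    n_layers: int = 1
    include_covariates: bool = False
    feature_normalization: dict | None = None
    seed: int = 0

    def resolved_hidden_dim(self, nz: int) -> int:
        h = self.hidden_dim if self.hidden_dim is not None else max(16, 4 * nz)
        if h < nz:
            raise ValueError(f"hidden_dim {h} must be at least nz={nz}")
        return h


@dataclass
class PosteriorApprox:
    """Gaussian posterior N(mean, chol chol^T) on the transformed scale."""

    mean: np.ndarray
    chol: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.chol = np.asarray(self.chol, dtype=float)
        nz = self.mean.size
        if self.chol.shape != (nz, nz):
            raise ValueError("chol must be (nz, nz)")
        if np.any(np.diag(self.chol) <= 0) or not np.all(np.isfinite(self.chol)):
            raise ValueError("chol needs a strictly positive, finite diagonal")

    @property
    def cov(self) -> np.ndarray:
        return self.chol @ self.chol.T

    @property
    def marginal_sd(self) -> np.ndarray:
        return np.sqrt(np.sum(self.chol**2, axis=1))


def compute_feature_stats(dataset) -> dict:
    """Dataset-level location/scale constants, frozen at fit start."""
    t = np.concatenate([ind.times for ind in dataset.individuals])
    x = dataset.all_observations()
    return {
        "t_mean": float(np.mean(t)), "t_sd": float(np.std(t)) or 1.0,
        "x_mean": float(np.mean(x)), "x_sd": float(np.std(x)) or 1.0,
    }


def featurize(dataset, stats: dict, include_covariates: bool = False):
    """Pack the dataset into a padded (N, T_max, F) array plus lengths.

    Per-step channels: normalized time, normalized observation, time
    increment since the previous observation (scaled by the time sd), the
    observation increment (scaled by the observation sd), then optionally the
    individual's coded covariates repeated at every step. The increment
    channels hand the network local slope information directly, which is
    where rate parameters live.
    """
    if stats is None:
        raise ValueError("feature normalization constants are unset")
    N = dataset.N
    T = max(ind.n_obs for ind in dataset.individuals)
    nc = dataset.n_covariates if include_covariates else 0
    X = np.zeros((N, T, N_BASE_FEATURES + nc))
    lengths = np.empty(N, dtype=int)
    for i, ind in enumerate(dataset.individuals):
        n = ind.n_obs
        lengths[i] = n
        X[i, :n, 0] = (ind.times - stats["t_mean"]) / stats["t_sd"]
        X[i, :n, 1] = (ind.observations - stats["x_mean"]) / stats["x_sd"]
        X[i, :n, 2] = np.diff(ind.times, prepend=0.0) / stats["t_sd"]
        X[i, 1:n, 3] = np.diff(ind.observations) / stats["x_sd"]
        if nc:
            X[i, :n, N_BASE_FEATURES:] = ind.covariates
    return X, lengths


class GaussianSequenceEncoder:
    """LSTM + affine heads producing (mu_i, L_i) per individual.

    ``mu_bias_init`` seeds the mean head's bias (typically the transformed
    initial fixed effects) so that early posterior samples start near the
    prior; the Cholesky head's diagonal bias starts at sd ``init_sd``.
    """

    def __init__(self, nz: int, n_features: int, cfg: EncoderConfig,
                 mu_bias_init: np.ndarray | None = None, init_sd: float = 0.5):
        self.nz = nz
        self.cfg = cfg
        H = cfg.resolved_hidden_dim(nz)
        self.hidden_dim = H
        rng = np.random.default_rng(cfg.seed)
        self.lstm = LSTMStack(n_features, H, cfg.n_layers, rng)
        self.tril_rows, self.tril_cols = np.tril_indices(nz)
        n_chol = len(self.tril_rows)
        self.diag_mask = self.tril_rows == self.tril_cols
        head_scale = 0.1  # keep early outputs close to the bias initialization
        # arrays are shared with the LSTM's own dict; the LSTM only ever
        # iterates its W/U/b keys, the optimizer sees everything
        self.params = dict(self.lstm.params)
        self._head_keys = ("A_mu", "b_mu", "A_chol", "b_chol")
        self.params["A_mu"] = head_scale * init_uniform_fan_in(rng, (H, nz), H)
        self.params["b_mu"] = (np.zeros(nz) if mu_bias_init is None
                               else np.asarray(mu_bias_init, dtype=float).copy())
        self.params["A_chol"] = head_scale * init_uniform_fan_in(rng, (H, n_chol), H)
        b_chol = np.zeros(n_chol)
        b_chol[self.diag_mask] = softplus_inv(init_sd - _DIAG_FLOOR)
        self.params["b_chol"] = b_chol

    def forward(self, X: np.ndarray, lengths: np.ndarray):
        """Returns (mu (N,nz), L (N,nz,nz), cache)."""
        h, lstm_cache = self.lstm.forward(X, lengths)
        mu = h @ self.params["A_mu"] + self.params["b_mu"]
        raw = h @ self.params["A_chol"] + self.params["b_chol"]
        vals = np.where(self.diag_mask, softplus(raw) + _DIAG_FLOOR, raw)
        N = X.shape[0]
        L = np.zeros((N, self.nz, self.nz))
        L[:, self.tril_rows, self.tril_cols] = vals
        return mu, L, (lstm_cache, h, raw)

    def backward(self, cache, dmu: np.ndarray, dL: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients w.r.t. all weights given d loss/d mu and d loss/d L."""
        lstm_cache, h, raw = cache
        dvals = dL[:, self.tril_rows, self.tril_cols]
        # softplus'(raw) = sigmoid(raw) on the diagonal entries
        dsig = 1.0 / (1.0 + np.exp(-raw))
        draw = np.where(self.diag_mask, dvals * dsig, dvals)
        grads = {
            "A_mu": h.T @ dmu, "b_mu": dmu.sum(axis=0),
            "A_chol": h.T @ draw, "b_chol": draw.sum(axis=0),
        }
        dh = dmu @ self.params["A_mu"].T + draw @ self.params["A_chol"].T
        grads.update(self.lstm.backward(lstm_cache, dh))
        return grads

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params, lr=lr)

    def save(self, path) -> None:
        np.savez(path, **self.params,
                 __meta=np.array([self.nz, self.hidden_dim, self.cfg.n_layers]))

    def load_params(self, path) -> None:
        with np.load(path) as chk:
            for k in self.params:
                if k not in chk:
                    raise ValueError(f"checkpoint missing parameter {k!r}")
                if chk[k].shape != self.params[k].shape:
                    raise ValueError(f"checkpoint shape mismatch for {k!r}")
                self.params[k][...] = chk[k]


def encode(dataset, encoder: GaussianSequenceEncoder, stats: dict | None = None):
    """Run the encoder over a dataset -> one :class:`PosteriorApprox` each."""
    cfg = encoder.cfg
    stats = stats if stats is not None else cfg.feature_normalization
    X, lengths = featurize(dataset, stats, cfg.include_covariates)
    mu, L, _ = encoder.forward(X, lengths)
    return [PosteriorApprox(mu[i], L[i]) for i in range(dataset.N)]


def sample_latent(post: PosteriorApprox, eps: np.ndarray) -> np.ndarray:
    """Reparameterized draw z = mu + L eps."""
    eps = np.asarray(eps, dtype=float)
    return post.mean + post.chol @ eps


def posterior_readout(dataset, encoder: GaussianSequenceEncoder, model,
                      stats: dict | None = None) -> list[dict]:
    """Per-individual MAP estimates and posterior summaries.

    The Gaussian posterior's mode equals its mean, so the MAP on the
    transformed scale is mu_i and the natural-scale estimate is h^-1(mu_i).
    """
    posteriors = encode(dataset, encoder, stats)
    out = []
    for ind, post in zip(dataset.individuals, posteriors):
        out.append({
            "id": ind.id,
            "map_z": post.mean.copy(),
            "zeta_hat": model.transform_inverse(post.mean),
            "posterior_sd": post.marginal_sd,
        })
    return out
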