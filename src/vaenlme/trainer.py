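"""Training orchestration: burn-in, annealing, alternating updates, smoothing.

The fit alternates, once per iteration, (i) Adam gradient ascent steps on the
encoder weights against the annealed ELBO at the current population
parameters and (ii) the closed-form population update (plain or L0-penalized
when covariate selection is on) plus the error-model update. During the
burn-in phase the population parameters stay frozen at their initial values
while the encoder pre-trains under KL annealing; after a configurable point
the M-step sufficient statistics are running-averaged (stochastic-
approximation style) to damp Monte Carlo noise in the final estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .encoder import (N_BASE_FEATURES, EncoderConfig, GaussianSequenceEncoder,
                      PosteriorApprox, compute_feature_stats, featurize)
from .models import ErrorModel, StructuralModel, predict_population
from .mstep import MStepStats, SelectionResult, collect_stats, update_error, \
    update_l0, update_unpenalized
from .objective import (AnnealSchedule, PopulationParameters, anneal_weight,
                        bicc_elbo, elbo_parts_with_grads)

__all__ = ["TrainingConfig", "FitResult", "initialize", "fit", "convergence_check"]


@dataclass
class TrainingConfig:
    max_iters: int = 250
    burn_in_iters: int = 100
    anneal: AnnealSchedule | None = None          # default: ramp ends at 2x burn-in
    smooth_start_iter: int | None = None          # default: midway burn-in end -> max
    encoder_lr: float = 3e-3
    lr_decay_rate: float = 0.1    # 1/(1 + rate*(k - smooth_start)) decay in the smoothing phase
    grad_clip: float | None = 10.0
    psi_steps_per_iter: int = 5
    samples_per_individual: int = 1
    seed: int = 0
    select_covariates: bool = True
    selection_backend: str = "exhaustive"
    error_kind: str = "constant"
    hidden_dim: int | None = None
    n_layers: int = 1
    include_covariates_in_encoder: bool = False
    convergence_tol: float = 1e-3
    convergence_window: int = 30
    #: simulated-annealing floor on omega2 (SAEM-style): the IIV variances are
    #: kept above a linearly decaying fraction of their initial value until the
    #: smoothing phase, so individual posteriors keep exploring early and the
    #: fit is less prone to local maxima of the marginal likelihood
    variance_anneal: bool = False

    def __post_init__(self) -> None:
        if self.burn_in_iters >= self.max_iters:
            raise ValueError("burn_in_iters must be smaller than max_iters")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.anneal is None:
            self.anneal = AnnealSchedule(
                burn_in_iters=self.burn_in_iters,
                anneal_end_iter=2 * self.burn_in_iters,
                start_weight=0.1,
            )
        if self.smooth_start_iter is None:
            self.smooth_start_iter = (self.burn_in_iters + self.max_iters) // 2


@dataclass
class FitResult:
    theta: PopulationParameters
    selection: SelectionResult | None
    encoder: GaussianSequenceEncoder
    feature_stats: dict
    trajectories: "object"                  # pandas DataFrame, one row per iteration
    posteriors: list[PosteriorApprox]
    config: TrainingConfig
    seed_used: int
    converged: bool
    n_iters: int


def initialize(dataset, model: StructuralModel, user_inits: PopulationParameters | None = None,
               seed: int = 0) -> tuple[PopulationParameters, GaussianSequenceEncoder, dict]:
    """Initial population parameters and a seeded encoder.

    Without user inits, zpop comes from one naive pooled least-squares fit of
    the structural model to all observations (every individual at the same
    parameters, on the transformed scale), omega2 starts at 0.25 per row,
    beta at zero, and the residual sd at sd(observations)/10.
    """
    nz = model.n_params
    nc = dataset.n_covariates
    stats = compute_feature_stats(dataset)
    if user_inits is not None:
        theta0 = user_inits.copy()
    else:
        z_start = model.transform_forward(model.default_zeta)

        def data_resid(z):
            Z = np.tile(z, (dataset.N, 1))
            preds = predict_population(model, model.transform_inverse(Z), dataset)
            return np.concatenate(
                [p - ind.observations for p, ind in zip(preds, dataset.individuals)]
            )

        # Tikhonov term toward the model's typical values: flat (ridge)
        # directions of the pooled objective stay at their physiological
        # starting point instead of wandering to an arbitrary ridge point
        lam = 1e-3 * float(np.sum(data_resid(z_start) ** 2))
        root_lam = np.sqrt(max(lam, 1e-12))

        def resid(z):
            return np.concatenate([data_resid(z), root_lam * (z - z_start)])

        try:
            sol = least_squares(resid, z_start, method="lm", max_nfev=200 * nz)
            z0 = sol.x if np.all(np.isfinite(sol.x)) else z_start
        except Exception as exc:  # pooled fit is a heuristic; fall back quietly
            warnings.warn(f"pooled initialization failed ({exc}); using model defaults")
            z0 = z_start
        a0 = max(float(np.std(dataset.all_observations())) / 10.0, 1e-6)
        theta0 = PopulationParameters(
            zpop=z0, beta=np.zeros((nz, nc)), omega2=np.full(nz, 0.25),
            error=ErrorModel("constant", a0),
        )
    cfg = EncoderConfig(seed=seed, feature_normalization=stats)
    enc = GaussianSequenceEncoder(nz, N_BASE_FEATURES, cfg, mu_bias_init=theta0.zpop)
    return theta0, enc, stats


def _smooth(prev: MStepStats, new: MStepStats, step: float) -> MStepStats:
    """Running average of the sufficient statistics (step = 1/(k - k0 + 1))."""
    return replace(
        new,
        post_means=prev.post_means + step * (new.post_means - prev.post_means),
        post_vars=prev.post_vars + step * (new.post_vars - prev.post_vars),
        residual_sq_sum=prev.residual_sq_sum + step * (new.residual_sq_sum - prev.residual_sq_sum),
        pred_flat=prev.pred_flat + step * (new.pred_flat - prev.pred_flat),
    )


def convergence_check(theta_rows: list[np.ndarray], tol: float, window: int):
    """Relative change of every population-parameter component over a window.

    Returns ``(converged, per_component_flags)``; needs at least ``window+1``
    recorded parameter vectors.
    """
    if len(theta_rows) < window + 1:
        return False, None
    new = theta_rows[-1]
    old = theta_rows[-1 - window]
    scale = np.maximum(np.maximum(np.abs(old), np.abs(new)), 1e-2)
    rel = np.abs(new - old) / scale
    flags = rel < tol
    return bool(np.all(flags)), flags


def fit(dataset, model: StructuralModel, cfg: TrainingConfig | None = None,
        user_inits: PopulationParameters | None = None) -> FitResult:
    """Run the full alternating estimation; see the module docstring.

    Identical seed, config and dataset give identical results on one
    platform: all randomness flows from ``cfg.seed`` through named
    substreams (encoder init, sampling).
    """
    import pandas as pd

    if cfg is None:
        cfg = TrainingConfig()
    root = np.random.SeedSequence(cfg.seed)
    ss_init, ss_sample = root.spawn(2)
    init_seed = int(ss_init.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(ss_sample)

    theta, enc, stats = initialize(dataset, model, user_inits, seed=init_seed)
    if cfg.hidden_dim is not None or cfg.n_layers != 1 or cfg.include_covariates_in_encoder:
        ecfg = EncoderConfig(hidden_dim=cfg.hidden_dim, n_layers=cfg.n_layers,
                             include_covariates=cfg.include_covariates_in_encoder,
                             feature_normalization=stats, seed=init_seed)
        n_features = N_BASE_FEATURES + (dataset.n_covariates if cfg.include_covariates_in_encoder else 0)
        enc = GaussianSequenceEncoder(model.n_params, n_features, ecfg,
                                      mu_bias_init=theta.zpop)
    theta.error = ErrorModel(cfg.error_kind,
                             a=theta.error.a if cfg.error_kind != "proportional" else 1.0,
                             b=0.1 if cfg.error_kind != "constant" else 0.0)

    X, lengths = featurize(dataset, stats, enc.cfg.include_covariates)
    opt = enc.make_optimizer(cfg.encoder_lr)
    opt.clip_norm = cfg.grad_clip
    N, nz = dataset.N, model.n_params
    S = cfg.samples_per_individual
    penalty = math.log(N)

    omega2_init = theta.omega2.copy()
    rows = []
    theta_rows: list[np.ndarray] = []
    selection: SelectionResult | None = None
    smoothed: MStepStats | None = None
    converged = False
    mu = L = None
    last_parts = None
    k = 0
    for k in range(cfg.max_iters):
        w = anneal_weight(k, cfg.anneal)
        if k >= cfg.smooth_start_iter:
            # damp encoder steps alongside the M-step smoothing so the
            # posterior settles instead of hovering at Adam's noise floor
            opt.lr = cfg.encoder_lr / (1.0 + cfg.lr_decay_rate * (k - cfg.smooth_start_iter))
        for _ in range(cfg.psi_steps_per_iter):
            mu, L, cache = enc.forward(X, lengths)
            eps = rng.standard_normal((S, N, nz))
            parts = elbo_parts_with_grads(dataset, model, theta, mu, L, eps,
                                          kl_weight=w, want_grad=True)
            if not np.isfinite(parts["elbo"]):
                raise FloatingPointError(
                    f"objective diverged (non-finite ELBO) at iteration {k}"
                )
            # minimize -ELBO
            grads = enc.backward(cache, -parts["dmu"], -parts["dL"])
            opt.step(grads)
            last_parts = parts

        if k >= cfg.burn_in_iters:
            mu, L, _ = enc.forward(X, lengths)
            posteriors = [PosteriorApprox(mu[i], L[i]) for i in range(N)]
            stats_k = collect_stats(dataset, model, theta, posteriors, S=S, rng=rng)
            if k >= cfg.smooth_start_iter:
                if smoothed is None:
                    smoothed = stats_k
                else:
                    step = 1.0 / (k - cfg.smooth_start_iter + 1)
                    smoothed = _smooth(smoothed, stats_k, step)
                stats_use = smoothed
            else:
                stats_use = stats_k
            if cfg.select_covariates and dataset.n_covariates > 0:
                selection = update_l0(stats_use, penalty_per_effect=penalty,
                                      backend=cfg.selection_backend)
                zpop, beta, omega2 = selection.zpop, selection.beta, selection.omega2
            else:
                zpop, beta, omega2 = update_unpenalized(stats_use)
            if cfg.variance_anneal and k < cfg.smooth_start_iter:
                frac = 1.0 - (k - cfg.burn_in_iters) / max(
                    cfg.smooth_start_iter - cfg.burn_in_iters, 1)
                omega2 = np.maximum(omega2, omega2_init * frac)
            error = update_error(stats_use, cfg.error_kind)
            theta = PopulationParameters(zpop, beta, omega2, error)

        elbo_w = last_parts["elbo"]
        elbo_full = last_parts["elbo_full_kl"]
        rows.append({
            "iteration": k, "elbo": elbo_full, "elbo_annealed": elbo_w,
            "reconstruction": last_parts["recon"], "kl": last_parts["kl"],
            "kl_weight": w, "bicc_elbo": bicc_elbo(elbo_full, theta.beta, N),
            **{f"zpop_{model.param_names[j]}": theta.zpop[j] for j in range(nz)},
            **{f"omega_{model.param_names[j]}": math.sqrt(theta.omega2[j]) for j in range(nz)},
            "error_a": theta.error.a,
            "n_selected": int(np.count_nonzero(theta.beta)),
        })
        theta_rows.append(theta.flatten())
        if k >= cfg.burn_in_iters:
            converged, _ = convergence_check(
                theta_rows[cfg.burn_in_iters:], cfg.convergence_tol, cfg.convergence_window
            )
            if converged:
                break

    mu, L, _ = enc.forward(X, lengths)
    posteriors = [PosteriorApprox(mu[i], L[i]) for i in range(N)]
    if not cfg.select_covariates:
        selection = None
    return FitResult(theta=theta, selection=selection, encoder=enc,
                     feature_stats=stats, trajectories=pd.DataFrame(rows),
                     posteriors=posteriors, config=cfg, seed_used=cfg.seed,
                     converged=converged, n_iters=k + 1)
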