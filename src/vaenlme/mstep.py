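"""Global population-parameter updates.

Given the current per-individual Gaussian posteriors, the ELBO's
theta-dependent part separates by parameter row (Omega is diagonal), so the
update of (zpop, beta, Omega) is row-wise ordinary least squares of the
posterior means on the coded covariates, with

    omega2_k = (1/N) sum_i [ (mu_ik - fit_ik)^2 + Var_q(z_ik) ].

Under the BICc-ELBO the fixed-effect update gains an L0 penalty log(N) per
nonzero covariate effect. Profiling omega2 out turns each row into the exact
subset-selection criterion

    N log(RSS_k(S)/N) + penalty * |S|,
    RSS_k(S) = sum_i [ (mu_ik - OLS fit on S)^2 + Var_q(z_ik) ],

minimized either by exhaustive enumeration of the 2^nc supports (exact,
canonical tie-break) or by an exact branch-and-bound search over the binary
inclusion indicators — the same formulation MIQP solvers attack — which
scales to large nc. Both return the global optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import minimize_scalar, minimize

from .models import ErrorModel, error_logpdf

__all__ = [
    "MStepStats",
    "SelectionResult",
    "collect_stats",
    "update_unpenalized",
    "update_l0",
    "update_error",
    "CapacityError",
    "SingularDesignError",
]


class SingularDesignError(np.linalg.LinAlgError):
    """Covariate design is rank deficient on a candidate support."""


class CapacityError(RuntimeError):
    """Exhaustive enumeration requested beyond its covariate-count cap."""


@dataclass
class MStepStats:
    """Sufficient statistics of one maximization step."""

    post_means: np.ndarray      # (N, nz) posterior means mu_i
    post_vars: np.ndarray       # (N, nz) diag of Sigma_i
    covariates: np.ndarray      # (N, nc) coded covariates
    residual_sq_sum: float      # sum_{i,j,s} (x_ij - pred_ij^(s))^2 / S
    obs_flat: np.ndarray        # observations repeated per sample (error-model fits)
    pred_flat: np.ndarray       # matching predictions
    N: int
    Ntot: int
    S: int

    def __post_init__(self) -> None:
        if np.any(self.post_vars < 0):
            raise ValueError("posterior variances must be non-negative")


@dataclass
class SelectionResult:
    """Outcome of the L0-penalized fixed-effect update."""

    support: set          # {(parameter row k, covariate column j)}
    beta: np.ndarray      # (nz, nc), zero off-support
    zpop: np.ndarray
    omega2: np.ndarray
    objective: float      # sum over rows of N log(RSS/N) + penalty |S|

    def __post_init__(self) -> None:
        for (k, j) in self.support:
            if self.beta[k, j] == 0.0:
                raise ValueError("support entry with zero coefficient")


def collect_stats(dataset, model, theta, posteriors, S: int = 1,
                  rng: np.random.Generator | None = None,
                  sample_preds=None) -> MStepStats:
    """Assemble M-step sufficient statistics.

    ``sample_preds`` (list over samples of per-individual prediction arrays,
    as produced by the gradient pass) is reused when given so the M-step sees
    the same reparameterized samples; otherwise fresh samples are drawn.
    """
    from .objective import elbo_parts_with_grads  # local import to avoid cycle

    N = dataset.N
    mu = np.vstack([p.mean for p in posteriors])
    post_vars = np.vstack([np.sum(p.chol**2, axis=1) for p in posteriors])
    if sample_preds is None:
        if rng is None:
            rng = np.random.default_rng(0)
        eps = rng.standard_normal((S, N, theta.nz))
        parts = elbo_parts_with_grads(dataset, model, theta, mu,
                                      np.stack([p.chol for p in posteriors]),
                                      eps, want_grad=False)
        sample_preds = parts["sample_preds"]
    S = len(sample_preds)
    obs = [ind.observations for ind in dataset.individuals]
    obs_flat = np.concatenate([np.concatenate(obs) for _ in range(S)])
    pred_flat = np.concatenate([np.concatenate(p) for p in sample_preds])
    rss = float(np.sum((obs_flat - pred_flat) ** 2)) / S
    return MStepStats(post_means=mu, post_vars=post_vars,
                      covariates=dataset.covariate_matrix(),
                      residual_sq_sum=rss, obs_flat=obs_flat, pred_flat=pred_flat,
                      N=N, Ntot=dataset.Ntot, S=S)


def _ols_row(y: np.ndarray, C: np.ndarray, cols: tuple[int, ...]):
    """OLS of y on intercept + C[:, cols]; returns (intercept, coefs, sse)."""
    N = y.size
    X = np.column_stack([np.ones(N)] + [C[:, j] for j in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"collinear covariate design on support {tuple(cols)}"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef[0], coef[1:], float(resid @ resid)


def update_unpenalized(stats: MStepStats):
    """Exact (zpop, beta, omega2) maximizer of the ELBO at fixed posteriors."""
    N, nz = stats.post_means.shape
    nc = stats.covariates.shape[1]
    cols = tuple(range(nc))
    zpop = np.empty(nz)
    beta = np.zeros((nz, nc))
    omega2 = np.empty(nz)
    for k in range(nz):
        y = stats.post_means[:, k]
        intercept, coefs, sse = _ols_row(y, stats.covariates, cols)
        zpop[k] = intercept
        beta[k, cols] = coefs
        omega2[k] = (sse + float(np.sum(stats.post_vars[:, k]))) / N
    return zpop, beta, np.maximum(omega2, 1e-12)


def _row_criterion(sse_plus_var: float, N: int, penalty: float, size: int) -> float:
    return N * math.log(max(sse_plus_var, 1e-300) / N) + penalty * size


def _best_subset_exhaustive(y, C, var_sum, N, penalty):
    """Scan all supports; ties prefer smaller, then lexicographically
    smallest, supports (subsets are visited in exactly that order)."""
    nc = C.shape[1]
    best = None
    for size in range(nc + 1):
        for cols in combinations(range(nc), size):
            _, _, sse = _ols_row(y, C, cols)
            crit = _row_criterion(sse + var_sum, N, penalty, size)
            if best is None or crit < best[0] - 1e-10:
                best = (crit, cols)
    return best


def _best_subset_bnb(y, C, var_sum, N, penalty):
    """Exact branch and bound over the binary inclusion indicators.

    Nodes fix a prefix of covariates in/out; the bound uses the smallest
    achievable RSS (everything undecided included) with the penalty of the
    forced-in set only — valid because adding regressors never increases
    RSS and the criterion is increasing in RSS. Returns a global optimum
    (on criterion ties the incumbent found first is kept, which may differ
    from the exhaustive backend's canonical tie-break).
    """
    nc = C.shape[1]
    best: list = [math.inf, ()]

    def visit(cols):
        _, _, sse = _ols_row(y, C, cols)
        crit = _row_criterion(sse + var_sum, N, penalty, len(cols))
        if crit < best[0] - 1e-10:
            best[0], best[1] = crit, cols

    def bound(fixed_in, j):
        # optimistic completion: include every undecided covariate
        cols = fixed_in + tuple(range(j, nc))
        _, _, sse = _ols_row(y, C, cols)
        return _row_criterion(sse + var_sum, N, penalty, len(fixed_in))

    def recurse(fixed_in, j):
        if j == nc:
            visit(fixed_in)
            return
        if bound(fixed_in, j) >= best[0] - 1e-12:
            return
        recurse(fixed_in, j + 1)                 # exclude j first
        recurse(fixed_in + (j,), j + 1)          # then include j
    visit(tuple(range(nc)))  # incumbent: full support
    recurse((), 0)
    return best[0], tuple(best[1])


_BACKENDS = ("exhaustive", "bnb", "miqp")


def update_l0(stats: MStepStats, penalty_per_effect: float | None = None,
              backend: str = "exhaustive", max_exhaustive_nc: int = 20) -> SelectionResult:
    """L0-penalized best-subset update of (zpop, beta, omega2).

    ``penalty_per_effect`` defaults to log(N) (the BICc-ELBO penalty). Rows
    decouple because Omega is diagonal; each row's profiled criterion is
    solved exactly by the chosen backend ("miqp" is an alias for the exact
    branch-and-bound indicator search, "bnb").
    """
    if backend not in _BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; choose from {_BACKENDS}")
    N, nz = stats.post_means.shape
    nc = stats.covariates.shape[1]
    if penalty_per_effect is None:
        penalty_per_effect = math.log(N)
    if backend == "exhaustive" and nc > max_exhaustive_nc:
        raise CapacityError(
            f"nc={nc} exceeds max_exhaustive_nc={max_exhaustive_nc}; "
            "use the branch-and-bound ('miqp') backend"
        )
    solver = _best_subset_exhaustive if backend == "exhaustive" else _best_subset_bnb
    zpop = np.empty(nz)
    beta = np.zeros((nz, nc))
    omega2 = np.empty(nz)
    support: set = set()
    total = 0.0
    for k in range(nz):
        y = stats.post_means[:, k]
        var_sum = float(np.sum(stats.post_vars[:, k]))
        crit, cols = solver(y, stats.covariates, var_sum, N, penalty_per_effect)
        total += crit
        intercept, coefs, sse = _ols_row(y, stats.covariates, cols)
        zpop[k] = intercept
        omega2[k] = max((sse + var_sum) / N, 1e-12)
        for j, b in zip(cols, coefs):
            beta[k, j] = b
            if b != 0.0:
                support.add((k, j))
    return SelectionResult(support=support, beta=beta, zpop=zpop,
                           omega2=omega2, objective=total)


def update_error(stats: MStepStats, kind: str = "constant") -> ErrorModel:
    """Maximize the reconstruction term over the error-model parameters."""
    if stats.Ntot < 1:
        raise ValueError("need at least one observation")
    if kind == "constant":
        a2 = stats.residual_sq_sum / stats.Ntot
        if a2 <= 0:
            warnings.warn("zero residuals; flooring error sd at 1e-10")
            return ErrorModel("constant", 1e-10)
        return ErrorModel("constant", math.sqrt(a2))
    x, p = stats.obs_flat, stats.pred_flat
    if kind == "proportional":
        res = minimize_scalar(
            lambda lb: -float(np.sum(error_logpdf(x, p, ErrorModel("proportional", b=math.exp(lb))))) / stats.S,
            bounds=(-12.0, 5.0), method="bounded",
        )
        return ErrorModel("proportional", b=math.exp(res.x))
    if kind == "combined":
        def nll(q):
            return -float(np.sum(error_logpdf(
                x, p, ErrorModel("combined", a=math.exp(q[0]), b=math.exp(q[1]))))) / stats.S
        sd0 = max(math.sqrt(stats.residual_sq_sum / stats.Ntot), 1e-6)
        res = minimize(nll, x0=[math.log(sd0), math.log(0.1)], method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000})
        return ErrorModel("combined", a=math.exp(res.x[0]), b=math.exp(res.x[1]))
    raise ValueError(f"unknown error model kind {kind!r}")
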