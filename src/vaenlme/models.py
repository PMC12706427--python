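"""Structural ODE models, dosing, error models and parameter transforms.

A :class:`StructuralModel` bundles the ODE right-hand side ``f``, initial
state, output function ``g`` and one invertible transform ``h`` per
individual parameter, so that transformed parameters ``z = h(zeta)`` carry a
Gaussian population prior while ``zeta`` lives on its natural scale
(log-normal parameters use ``h = log``).

Three models ship with the package: a one-compartment first-order
absorption/elimination PK model (theophylline-type), a neonatal
weight-maturation model with smooth production delay, and a
direct-observation model used for analytically tractable checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TRANSFORMS",
    "IntegrationError",
    "StructuralModel",
    "ErrorModel",
    "error_logpdf",
    "error_dlogpdf_dpred",
    "predict_individual",
    "predict_population",
    "one_compartment_closed_form",
    "theophylline_model",
    "neonatal_model",
    "direct_observation_model",
    "get_model",
]


class IntegrationError(RuntimeError):
    """ODE integration failed or produced a non-finite state."""


def _logit(x):
    return np.log(x / (1.0 - x))


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


#: transform name -> (forward h, inverse h^-1)
TRANSFORMS: dict[str, tuple[Callable, Callable]] = {
    "identity": (lambda x: np.asarray(x, dtype=float), lambda z: np.asarray(z, dtype=float)),
    "log": (np.log, np.exp),
    "logit": (_logit, _expit),
}


@dataclass
class StructuralModel:
    """Mechanistic model mapping individual parameters to predictions."""

    name: str
    param_names: list[str]
    transforms: list[str]
    rhs: Callable | None = None            # f(t, y, zeta) -> dy/dt
    y0: Callable | None = None             # y0(zeta) -> initial state
    output: Callable | None = None         # g(t, y, zeta) -> observable
    depot_index: int | None = None         # state receiving bolus doses
    default_zeta: np.ndarray | None = None  # typical natural-scale values
    #: optional fast path: (Zeta (N,nz), dataset) -> list of per-individual predictions
    predict_batch: Callable | None = None

    def __post_init__(self) -> None:
        if len(self.param_names) != len(self.transforms):
            raise ValueError("param_names and transforms must align")
        for t in self.transforms:
            if t not in TRANSFORMS:
                raise ValueError(f"unknown transform {t!r}")
        if self.default_zeta is not None:
            self.default_zeta = np.asarray(self.default_zeta, dtype=float)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def transform_forward(self, zeta: np.ndarray) -> np.ndarray:
        """z = h(zeta), applied column-wise for 2-d input."""
        zeta = np.asarray(zeta, dtype=float)
        out = np.empty_like(zeta)
        for k, t in enumerate(self.transforms):
            out[..., k] = TRANSFORMS[t][0](zeta[..., k])
        return out

    def transform_inverse(self, z: np.ndarray) -> np.ndarray:
        """zeta = h^-1(z)."""
        z = np.asarray(z, dtype=float)
        out = np.empty_like(z)
        for k, t in enumerate(self.transforms):
            out[..., k] = TRANSFORMS[t][1](z[..., k])
        return out


@dataclass
class ErrorModel:
    """Residual error: constant, proportional or combined standard deviation."""

    kind: str = "constant"
    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "proportional", "combined"):
            raise ValueError(f"unknown error model kind {self.kind!r}")
        if self.kind == "constant" and self.a <= 0:
            raise ValueError("constant error model needs a > 0")
        if self.kind == "proportional" and self.b <= 0:
            raise ValueError("proportional error model needs b > 0")
        if self.kind == "combined" and (self.a <= 0 or self.b <= 0):
            raise ValueError("combined error model needs a, b > 0")

    def sd(self, pred) -> np.ndarray:
        pred = np.asarray(pred, dtype=float)
        if self.kind == "constant":
            return np.full_like(pred, self.a)
        if self.kind == "proportional":
            return self.b * np.abs(pred)
        return np.sqrt(self.a**2 + (self.b * pred) ** 2)

    @property
    def n_params(self) -> int:
        return 2 if self.kind == "combined" else 1


_LOG2PI = math.log(2.0 * math.pi)


def error_logpdf(x, pred, err: ErrorModel):
    """Gaussian log-density of observation(s) x around prediction(s)."""
    sd = err.sd(pred)
    if np.any(sd <= 0):
        raise ValueError("error standard deviation must be positive at the prediction")
    z = (np.asarray(x, dtype=float) - np.asarray(pred, dtype=float)) / sd
    return -0.5 * (_LOG2PI + 2.0 * np.log(sd) + z * z)


def error_dlogpdf_dpred(x, pred, err: ErrorModel):
    """d/dpred of :func:`error_logpdf` (needed for encoder backprop)."""
    x = np.asarray(x, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sd = err.sd(pred)
    r = x - pred
    grad = r / sd**2
    if err.kind == "constant":
        return grad
    # sd depends on pred: d/dpred [-log sd - r^2/(2 sd^2)]
    if err.kind == "proportional":
        dsd = err.b * np.sign(pred)
    else:
        dsd = err.b**2 * pred / sd
    return grad + (-1.0 / sd + r * r / sd**3) * dsd


def one_compartment_closed_form(D, ka, ke, V, t, switch_rel=1e-8):
    """Concentration of a one-compartment first-order absorption model.

    ``D ka/(V (ka-ke)) (exp(-ke t) - exp(-ka t))`` with the analytic limit
    ``D ka t exp(-ka t)/V`` when ``|ka-ke| < switch_rel * max(ka, ke)``.
    Broadcasts over all arguments.
    """
    D, ka, ke, V, t = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (D, ka, ke, V, t))
    )
    near = np.abs(ka - ke) < switch_rel * np.maximum(ka, ke)
    denom = np.where(near, 1.0, ka - ke)
    general = D * ka / (V * denom) * (np.exp(-ke * t) - np.exp(-ka * t))
    limit = D * ka * t * np.exp(-ka * t) / V
    return np.where(near, limit, general)


def predict_individual(model: StructuralModel, zeta, times, doses=(),
                       rtol: float = 1e-6, atol: float = 1e-8) -> np.ndarray:
    """Predicted observations for one individual by piecewise ODE integration.

    Integration restarts at each dose event, adding the bolus amount to the
    depot state. ``zeta`` is on the natural (untransformed) scale.
    """
    zeta = np.asarray(zeta, dtype=float)
    times = np.asarray(times, dtype=float)
    if model.rhs is None:
        raise ValueError(f"model {model.name!r} defines no ODE right-hand side")
    state = np.asarray(model.y0(zeta), dtype=float)
    events = sorted(doses, key=lambda d: d[0])
    # apply doses at t <= first integration start (t=0)
    t_cur = 0.0
    pending = []
    for t_d, amt in events:
        if t_d <= t_cur:
            state[model.depot_index] += amt
        else:
            pending.append((t_d, amt))
    preds = np.empty_like(times)
    done = 0
    segments = pending + [(float(times[-1]) if times.size else t_cur, None)]
    for t_next, amt in segments:
        t_end = max(t_next, t_cur)
        seg_mask = (times >= t_cur) & (times <= t_end) if amt is None else \
                   (times >= t_cur) & (times < t_next)
        seg_times = times[seg_mask]
        eval_times = np.unique(np.concatenate([seg_times, [t_end]]))
        if t_end > t_cur:
            sol = solve_ivp(model.rhs, (t_cur, t_end), state, t_eval=eval_times,
                            args=(zeta,), rtol=rtol, atol=atol, method="RK45")
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise IntegrationError(
                    f"integration failed for zeta={zeta} at t={sol.t[-1] if sol.t.size else t_cur}"
                )
            for j, t_obs in enumerate(seg_times):
                col = np.searchsorted(sol.t, t_obs)
                preds[done + j] = model.output(t_obs, sol.y[:, col], zeta)
            state = sol.y[:, -1].copy()
        else:
            for j, t_obs in enumerate(seg_times):
                preds[done + j] = model.output(t_obs, state, zeta)
        done += seg_times.size
        t_cur = t_end
        if amt is not None:
            state[model.depot_index] += amt
    return preds


def predict_population(model: StructuralModel, Zeta: np.ndarray, dataset,
                       rtol: float = 1e-6, atol: float = 1e-8) -> list[np.ndarray]:
    """Per-individual predictions for a matrix of natural-scale parameters.

    Uses the model's vectorized fast path when available, otherwise falls
    back to individual ODE integration.
    """
    Zeta = np.atleast_2d(np.asarray(Zeta, dtype=float))
    if model.predict_batch is not None:
        return model.predict_batch(Zeta, dataset)
    return [
        predict_individual(model, Zeta[i], ind.times, ind.doses, rtol=rtol, atol=atol)
        for i, ind in enumerate(dataset.individuals)
    ]


# ---------------------------------------------------------------------------
# built-in models


def theophylline_model(use_closed_form: bool = True) -> StructuralModel:
    """One-compartment PK model with first-order absorption and elimination.

    States (Abs, A): dAbs/dt = -ka*Abs, dA/dt = ka*Abs - ke*A; a bolus dose
    enters the absorption compartment; the observed concentration is A/V.
    Parameters (ka, ke, V) are log-normal (log transforms).
    """

    def rhs(t, y, zeta):
        ka, ke, _ = zeta
        return np.array([-ka * y[0], ka * y[0] - ke * y[1]])

    def y0(zeta):
        return np.zeros(2)

    def output(t, y, zeta):
        return y[1] / zeta[2]

    def predict_batch(Zeta, dataset):
        # closed form valid for a single bolus at t=0 (the study design);
        # falls back to ODE integration for anything else. Fully vectorized
        # when every individual shares the same number of sampling times;
        # the stacked design is cached on the dataset (it never changes).
        inds = dataset.individuals
        design = getattr(dataset, "_onecpt_design", None)
        if design is None:
            simple = all(len(ind.doses) == 1 and ind.doses[0][0] == 0.0 for ind in inds)
            n0 = inds[0].n_obs
            if simple and all(ind.n_obs == n0 for ind in inds):
                T = np.vstack([ind.times for ind in inds])
                D = np.array([ind.doses[0][1] for ind in inds])[:, None]
                design = (T, D)
            else:
                design = False
            try:
                dataset._onecpt_design = design
            except AttributeError:
                pass
        if design:
            T, D = design
            ka, ke, V = Zeta[:, :1], Zeta[:, 1:2], Zeta[:, 2:3]
            near = np.abs(ka - ke) < 1e-8 * np.maximum(ka, ke)
            denom = np.where(near, 1.0, ka - ke)
            conc = np.where(
                near,
                D * ka * T * np.exp(-ka * T) / V,
                D * ka / (V * denom) * (np.exp(-ke * T) - np.exp(-ka * T)),
            )
            return list(conc)
        preds = []
        for i, ind in enumerate(inds):
            ka, ke, V = Zeta[i]
            if len(ind.doses) == 1 and ind.doses[0][0] == 0.0:
                D = ind.doses[0][1]
                preds.append(one_compartment_closed_form(D, ka, ke, V, ind.times))
            else:
                preds.append(predict_individual(model, Zeta[i], ind.times, ind.doses))
        return preds

    model = StructuralModel(
        name="theophylline",
        param_names=["ka", "ke", "V"],
        transforms=["log", "log", "log"],
        rhs=rhs, y0=y0, output=output, depot_index=0,
        default_zeta=np.array([1.5, 0.08, 30.0]),
        predict_batch=predict_batch if use_closed_form else None,
    )
    return model


def neonatal_model(step: float = 0.1) -> StructuralModel:
    """Neonatal weight-maturation model over the first days of life.

    dW/dt = kprod(t) - kel(t) W with a smooth-delay zero-order production
    kprod(t) = kin / (1 + exp(-2 (t - Tlag))) and a maturing first-order
    elimination kel(t) = kout (1 - t/(T50 + t)); W(0) = W0. Parameters
    (W0, kin, Tlag, kout, T50) are log-normal. The sigmoid steepness is a
    fixed constant (2 per unit time), not an estimated parameter.

    The fast path integrates all individuals simultaneously with classical
    RK4 on a fixed grid (``step`` in the dataset's time unit, days here) and
    linearly interpolates at observation times; the smooth right-hand side
    makes this accurate far below the residual-error scale.
    """

    def kprod(t, kin, tlag):
        return kin / (1.0 + np.exp(-2.0 * (t - tlag)))

    def kel(t, kout, t50):
        return kout * (1.0 - t / (t50 + t))

    def rhs(t, y, zeta):
        w0, kin, tlag, kout, t50 = zeta
        return np.array([kprod(t, kin, tlag) - kel(t, kout, t50) * y[0]])

    def y0(zeta):
        return np.array([zeta[0]])

    def output(t, y, zeta):
        return y[0]

    def predict_batch(Zeta, dataset):
        t_max = max(float(ind.times[-1]) for ind in dataset.individuals)
        n_steps = max(1, int(np.ceil(t_max / step)))
        grid = np.linspace(0.0, n_steps * step, n_steps + 1)
        w0, kin, tlag, kout, t50 = (Zeta[:, k] for k in range(5))

        def f(t, w):
            return kprod(t, kin, tlag) - kel(t, kout, t50) * w

        W = np.empty((n_steps + 1, Zeta.shape[0]))
        W[0] = w0
        h = grid[1] - grid[0]
        for s in range(n_steps):
            t = grid[s]
            w = W[s]
            k1 = f(t, w)
            k2 = f(t + h / 2, w + h / 2 * k1)
            k3 = f(t + h / 2, w + h / 2 * k2)
            k4 = f(t + h, w + h * k3)
            W[s + 1] = w + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        preds = []
        for i, ind in enumerate(dataset.individuals):
            preds.append(np.interp(ind.times, grid, W[:, i]))
        return preds

    return StructuralModel(
        name="neonatal",
        param_names=["W0", "kin", "Tlag", "kout", "T50"],
        transforms=["log"] * 5,
        rhs=rhs, y0=y0, output=output, depot_index=None,
        default_zeta=np.array([3300.0, 150.0, 2.0, 0.03, 5.0]),
        predict_batch=predict_batch,
    )


def direct_observation_model(nz: int = 1) -> StructuralModel:
    """Identity-transform model whose prediction is the first parameter.

    Every observation of individual i is predicted by zeta_i[0] regardless of
    time, so the marginal likelihood is Gaussian and available in closed
    form. Used for exactness checks of the whole estimation machinery.
    """

    def predict_batch(Zeta, dataset):
        inds = dataset.individuals
        n0 = inds[0].n_obs
        if all(ind.n_obs == n0 for ind in inds):
            return list(np.broadcast_to(Zeta[:, :1], (len(inds), n0)))
        return [np.full(ind.n_obs, Zeta[i, 0]) for i, ind in enumerate(inds)]

    def rhs(t, y, zeta):
        return np.zeros(1)

    return StructuralModel(
        name="direct",
        param_names=[f"m{k}" for k in range(nz)],
        transforms=["identity"] * nz,
        rhs=rhs, y0=lambda zeta: np.array([zeta[0]]),
        output=lambda t, y, zeta: y[0], depot_index=None,
        default_zeta=np.zeros(nz),
        predict_batch=predict_batch,
    )


_REGISTRY = {
    "theophylline": theophylline_model,
    "neonatal": neonatal_model,
    "direct": direct_observation_model,
}


def get_model(name: str) -> StructuralModel:
    """Look a built-in model up by name."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(_REGISTRY)}") from None
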