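"""Synthetic mixed-effects datasets with known ground truth.

The generator draws covariates, forms transformed individual parameters
z_i = zpop + beta c_i + eta_i with eta_i ~ N(0, Omega), simulates the
structural model at h^-1(z_i) and adds residual noise — exactly the
hierarchical data-generating process the estimator assumes. Covariate coding
reuses :func:`vaenlme.data.transform_covariates`, so continuous covariates
are log-centered at the realized sample mean just as a fitted dataset would
be.

Two presets emulate the case studies: a theophylline-type single-dose PK
design (11 samples over 24 h, covariates weight and sex, true effects on ka
and V only) and a neonatal weight-progression design (daily weights for a
week, five parameters, five covariates, six true effects among the 25
candidate parameter-covariate pairs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .data import CovariateSpec, Individual, PopulationDataset, transform_covariates
from .models import ErrorModel, StructuralModel, neonatal_model, predict_population, \
    theophylline_model
from .objective import PopulationParameters

__all__ = ["TruthManifest", "generate_population", "theophylline_like",
           "neonatal_like", "write_truth_json"]


@dataclass
class TruthManifest:
    """Everything needed to regenerate a dataset and judge recovery."""

    theta_true: PopulationParameters
    support_true: set                 # {(parameter row, covariate column)}
    covariate_rules: list[dict]       # generation rule per raw covariate
    design: dict                      # observation times and dose rule
    seed: int = 0

    def __post_init__(self) -> None:
        beta = self.theta_true.beta
        nonzero = {(int(k), int(j)) for k, j in zip(*np.nonzero(beta))}
        if nonzero != {(int(k), int(j)) for k, j in self.support_true}:
            raise ValueError("support_true inconsistent with nonzeros of beta")

    def to_jsonable(self) -> dict:
        t = self.theta_true
        return {
            "zpop": t.zpop.tolist(), "beta": t.beta.tolist(),
            "omega2": t.omega2.tolist(),
            "error": {"kind": t.error.kind, "a": t.error.a, "b": t.error.b},
            "support_true": sorted([int(k), int(j)] for k, j in self.support_true),
            "covariate_rules": self.covariate_rules,
            "design": self.design, "seed": self.seed,
        }


def write_truth_json(truth: TruthManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=2)


def _draw_covariates(rules, N, rng):
    """Raw covariate draws plus the coding specs matching the rules."""
    raw, specs = {}, []
    for rule in rules:
        name = rule["name"]
        if rule["kind"] == "continuous":
            sigma = math.sqrt(math.log(1.0 + rule["cv"] ** 2))
            raw[name] = rule["median"] * np.exp(sigma * rng.standard_normal(N))
            specs.append(CovariateSpec(name, "continuous",
                                       rule.get("transform", "log_centered")))
        elif rule["kind"] == "categorical":
            draws = (rng.random(N) < rule["p"]).astype(int)
            raw[name] = draws
            specs.append(CovariateSpec(name, "categorical", reference_level=0))
        else:
            raise ValueError(f"unknown covariate rule kind {rule['kind']!r}")
    return raw, specs


def _code_covariates(raw, specs, N):
    """Code with the data-module transform; a degenerate categorical draw
    (all individuals one level) codes to an all-zero column."""
    columns, meta = [], []
    for spec in specs:
        values = raw[spec.name]
        if spec.kind == "categorical" and len({str(v) for v in values}) < 2:
            columns.append(np.zeros(N))
            meta.append({"name": spec.name, "kind": "categorical",
                         "raw_name": spec.name, "level": "1", "reference_level": "0"})
            continue
        coded, m = transform_covariates({spec.name: values}, [spec])
        columns.append(coded[:, 0])
        meta.extend(m)
    if not columns:
        return np.zeros((N, 0)), meta
    return np.column_stack(columns), meta


def _doses_for(design, raw, i):
    rule = design.get("dose")
    if rule is None:
        return []
    if "per_kg" in rule:
        amt = rule["per_kg"] * float(np.asarray(raw[rule["of"]])[i])
    else:
        amt = rule["amount"]
    return [(float(rule.get("time", 0.0)), float(amt))]


def generate_population(model: StructuralModel, truth: TruthManifest, N: int,
                        seed: int | None = None):
    """Simulate N individuals under the manifest's ground truth.

    Returns ``(dataset, z_true)`` with ``z_true`` the (N, nz) transformed
    individual parameters actually used.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    theta = truth.theta_true
    raw, specs = _draw_covariates(truth.covariate_rules, N, rng)
    C, meta = _code_covariates(raw, specs, N)
    if C.shape[1] != theta.nc:
        raise ValueError("covariate rules inconsistent with beta dimensions")
    eta = rng.standard_normal((N, theta.nz)) * np.sqrt(theta.omega2)
    z_true = theta.prior_means(C) + eta
    zeta = model.transform_inverse(z_true)
    times = np.asarray(truth.design["times"], dtype=float)
    skeleton = PopulationDataset(
        [Individual(id=i + 1, times=times, observations=np.zeros_like(times),
                    doses=_doses_for(truth.design, raw, i), covariates=C[i])
         for i in range(N)],
        covariate_names=[m["name"] for m in meta], covariate_meta=meta,
    )
    preds = predict_population(model, zeta, skeleton)
    for i, ind in enumerate(skeleton.individuals):
        sd = theta.error.sd(preds[i])
        ind.observations = preds[i] + sd * rng.standard_normal(times.size)
    return skeleton, z_true


def theophylline_like(N: int = 12, seed: int = 0):
    """Theophylline-type synthetic study.

    Single oral dose (4.53 mg/kg) at t = 0, 11 concentration samples over
    24 h; covariates weight (log-normal, median 70 kg, cv 15%, coded
    log-centered) and sex (Bernoulli 1/2). The generating truth mirrors the
    fitted values of the real study: effects of weight on ka and V only.
    Returns ``(dataset, TruthManifest)``.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    beta = np.zeros((3, 2))
    beta[0, 0] = 2.55   # weight on ka
    beta[2, 0] = 0.57   # weight on V
    theta = PopulationParameters(
        zpop=np.log([1.6, 0.087, 32.0]),
        beta=beta,
        omega2=np.array([0.53, 0.15, 0.13]) ** 2,
        error=ErrorModel("constant", 0.71),
    )
    truth = TruthManifest(
        theta_true=theta,
        support_true={(0, 0), (2, 0)},
        covariate_rules=[
            {"name": "weight", "kind": "continuous", "median": 70.0, "cv": 0.15,
             "transform": "log_centered"},
            {"name": "sex", "kind": "categorical", "p": 0.5},
        ],
        design={"times": [0.25, 0.5, 1.0, 2.0, 3.5, 5.0, 7.0, 9.0, 12.0, 18.0, 24.0],
                "dose": {"time": 0.0, "per_kg": 4.53, "of": "weight"}},
        seed=seed,
    )
    dataset, _ = generate_population(theophylline_model(), truth, N)
    return dataset, truth


def neonatal_like(N: int = 500, seed: int = 0, support: dict | None = None):
    """Neonatal weight-progression synthetic study.

    Daily weights at t = 0..7 days; five log-normal parameters
    (W0, kin, Tlag, kout, T50) and five covariates (sex, DelM, Para2
    categorical; GA, Mage continuous log-centered), giving 25 candidate
    parameter-covariate pairs. The default sparse truth carries six effects.
    Returns ``(dataset, TruthManifest)``.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    # covariate order: sex, DelM, GA, Mage, Para2
    # effect sizes sit at >= 5x the detection threshold implied by the
    # design's identified information per parameter (the daily-weight design
    # identifies Tlag/T50 only weakly, so their effects must be larger to be
    # recoverable at all)
    if support is None:
        support = {(0, 0): -0.06,   # sex on W0
                   (0, 2): 2.5,     # GA on W0
                   (1, 2): 2.8,     # GA on kin
                   (3, 1): 0.25,    # delivery mode on kout
                   (2, 4): 0.30,    # parity on Tlag
                   (4, 3): 1.25}    # maternal age on T50
    beta = np.zeros((5, 5))
    for (k, j), v in support.items():
        beta[k, j] = v
    theta = PopulationParameters(
        zpop=np.log([3300.0, 150.0, 2.0, 0.03, 5.0]),
        beta=beta,
        omega2=np.array([0.10, 0.25, 0.25, 0.25, 0.25]) ** 2,
        error=ErrorModel("constant", 30.0),
    )
    truth = TruthManifest(
        theta_true=theta,
        support_true=set(support),
        covariate_rules=[
            {"name": "sex", "kind": "categorical", "p": 0.5},
            {"name": "DelM", "kind": "categorical", "p": 0.3},
            {"name": "GA", "kind": "continuous", "median": 39.0, "cv": 0.03,
             "transform": "log_centered"},
            {"name": "Mage", "kind": "continuous", "median": 30.0, "cv": 0.15,
             "transform": "log_centered"},
            {"name": "Para2", "kind": "categorical", "p": 0.4},
        ],
        design={"times": list(range(8)), "dose": None},
        seed=seed,
    )
    dataset, _ = generate_population(neonatal_model(), truth, N)
    return dataset, truth
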