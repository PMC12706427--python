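# Methods

## Model

`vaenlme` estimates nonlinear mixed-effects (NLME) models. Individual `i`
contributes observations `x_ij` at times `t_ij`, predicted by a structural
model — an ODE `dy/dt = f(t, y, ζ_i)` with initial state `y0(ζ_i)` and
output `g` — plus Gaussian residual error (constant sd `a` by default;
proportional and combined error models are supported). Individual
parameters are log-normal (or identity/logit) via a per-parameter
invertible transform `h`: on the transformed scale

```
z_i = z_pop + β c_i + η_i,   η_i ~ N(0, Ω),   Ω diagonal.
```

`c_i` are coded covariates: continuous covariates are log-centered at the
population arithmetic mean (`c = log(value/mean)`, so the population-typical
individual codes to 0 and `z_pop` keeps its interpretation), binary
categorical covariates are 0/1 indicators against a reference level,
multi-level ones expand to reference-coded indicators. Centering constants
are frozen at ingestion and reused for new individuals.

Estimation maximizes the marginal likelihood `p(x | θ)`, `θ = (z_pop, β, Ω,
a)`, which has no closed form.

## Amortized inference and training

A single LSTM with subject-independent weights maps each individual's
sequence to a Gaussian posterior `q(z_i|x_i) = N(μ_i, L_i L_iᵀ)` (lower
triangular `L_i`, softplus-positive diagonal floored at 1e-6). Per-step
features: normalized time, normalized observation, time increment,
observation increment; normalization constants are dataset-level mean/sd
frozen at fit start. The increment channels hand the network local slope
information, which is where rate parameters live. Optionally the coded
covariates can be appended as static channels (off by default, so `q`
conditions on measurements only). Variable-length sequences are processed
at native length under a carry-forward mask; no padding semantics leak into
the results.

Training ascends the ELBO

```
L(ψ, θ) = Σ_i E_q[log p(x_i | z_i)] − w_k · Σ_i KL(q(z_i|x_i) ‖ N(z_pop + β c_i, Ω))
```

with reparameterized samples `z = μ + Lε` (S samples per individual per
step, default 1), the KL term in closed form, and a linear annealing weight
`w_k` ramping from 0.1 at iteration 0 to 1 at twice the burn-in length.
Gradients of the reconstruction term with respect to `z` chain the analytic
error-model derivative with central finite differences of the structural
model on the transformed scale (step 1e-4; nz is small, each probe is one
vectorized population prediction); gradients through `μ`, `L` and the LSTM
are exact and verified against finite differences in the test suite. The
optimizer is Adam (default step 3e-3–5e-3, global gradient-norm clip 10),
full batch, several encoder steps per outer iteration.

Each outer iteration after burn-in also performs the global population
update at fixed `q`. Because `Ω` is diagonal the θ-dependent part of the
ELBO separates by parameter row, and the maximizer is ordinary least
squares of the posterior means `μ_ik` on `[1, c_i]` with

```
ω_k² = (1/N) Σ_i [ (μ_ik − fit_ik)² + Var_q(z_ik) ],
a² = mean squared sampled residual  (constant error; 1-D/2-D numeric
     maximization for proportional/combined).
```

During burn-in (default 100 iterations) θ stays frozen at its initial value
while the encoder pre-trains under annealed KL. From the smoothing point
(default midway between burn-in end and the iteration cap, 250 by default)
the M-step sufficient statistics are running-averaged with step
`1/(k−k₀+1)` and the encoder step size decays as `1/(1+0.1(k−k₀))`, so the
estimates settle instead of hovering at the optimizer's noise floor.
Convergence is declared when every θ component changes by less than a
relative tolerance (default 1e-3) across a 30-iteration window. All
randomness flows from one root seed through named substreams; identical
seed, config and dataset reproduce runs bitwise on one platform.

## Covariate selection

With selection enabled the training objective becomes the BICc-ELBO
`−2·L + log(N)·‖β‖₀` (an additive constant involving the always-present
parameters is dropped; the run manifest records this convention). The
fixed-effect update then minimizes, independently per parameter row `k`,

```
N log(RSS_k(S)/N) + log(N) · |S|    over supports S ⊆ {1..nc},
RSS_k(S) = Σ_i [ (μ_ik − OLS fit on S)² + Var_q(z_ik) ],
```

which profiles `ω_k²` out exactly. Two exact backends: exhaustive
enumeration of the `2^nc` supports per row (default, capped at nc = 20;
ties prefer smaller supports, then lexicographically smallest indices) and
a branch-and-bound search over the binary inclusion indicators — the
formulation MIQP solvers attack — whose bound uses the smallest achievable
RSS of each subtree (valid since adding regressors never increases RSS).
Both return a global optimum; on exact criterion ties branch-and-bound may
return a different optimal support than the exhaustive tie-break.
Selection activates with the first post-burn-in M-step. A zero column of
the selected `β` means the covariate is irrelevant to every parameter.

## Evaluation

The marginal log-likelihood is estimated by importance sampling with the
trained encoder posterior as proposal (`M = 1000` per individual by
default), via log-sum-exp; the Monte Carlo standard error comes from the
delta method on the normalized weights. BICc is
`−2LL + log(N)·dim θ_R + log(Ntot)·dim θ_F` with the hybrid counting
convention: parameters linked to random effects (fixed effects with IIV,
their selected covariate effects, the variances) count under `log N`;
non-IIV fixed effects, their covariate effects and the error parameters
count under `log Ntot`. The convention is printed with every breakdown so
an alternative count is a visible constant offset; the −2LL itself is
convention-free. Goodness-of-fit tables report population predictions (at
`h⁻¹(z_pop + β c_i)`) and individual predictions (at the MAP, which equals
`h⁻¹(μ_i)` for a Gaussian posterior).

## Built-in structural models

- **One-compartment oral PK** (theophylline-type): states (Abs, A), bolus
  into Abs, output `A/V`, parameters (ka, ke, V) log-normal. Predictions
  use the closed form `D·ka/(V(ka−ke))(e^{−ke·t} − e^{−ka·t})` with the
  analytic `ka≈ke` limit (switch at `|ka−ke| < 1e-8·max`), fully vectorized
  across individuals for the single-dose design; arbitrary dosing falls
  back to piecewise adaptive ODE integration (Dormand–Prince, rtol 1e-6 /
  atol 1e-8, restart with depot increment at each bolus).
- **Neonatal weight maturation**: `dW/dt = kin/(1+e^{−2(t−T_lag)}) −
  kout(1−t/(T50+t))·W`, `W(0) = W0`, five log-normal parameters. The
  smooth sigmoid delay keeps the right-hand side differentiable, which
  gradient-based training needs; the sigmoid steepness (2 per day) is a
  fixed constant, not estimated. The fast path integrates all individuals
  simultaneously with classical RK4 on a 0.1-day grid (error < 1e-5 g
  against adaptive integration, far below the ~30 g residual sd).
- **Direct observation**: prediction equals the first parameter, identity
  transform — the conjugate linear-Gaussian case whose marginal likelihood,
  MLE and posterior are closed-form, used to verify exactness of the whole
  machinery.

## Initialization

Without user values, `z_pop` starts from one pooled least-squares fit of
the structural model to all observations at common parameters, regularized
toward the model's typical values (Tikhonov weight `1e-3 ×` the starting
SSE). The regularization matters for weakly identified parameter
combinations: the neonatal elimination terms `kout` and `T50` enter the
mean curve almost only through `kout·T50/(T50+t)`, so an unregularized
pooled fit picks an arbitrary point on that ridge, and an EM-style
iteration started there can converge to a genuine local maximum of the
marginal likelihood several hundred `−2LL` units short of the optimum —
verified by running exact-posterior EM steps from such a fit. `ω_k²`
starts at 0.25, `β` at zero, `a` at sd(observations)/10; the encoder's
mean head is biased to the initial `z_pop` and its initial posterior sd is
0.5. An optional SAEM-style simulated-annealing floor on `Ω` is available
(`variance_anneal`) but off by default: in our experiments it did not
improve escape from the ridge, while the regularized initialization did.

## Synthetic-data generators

Both presets draw covariates, form `z_i = z_pop + β c_i + η_i`, simulate
the structural model at `h⁻¹(z_i)` and add residual noise — exactly the
estimator's assumed data-generating process — and return the ground truth
alongside the dataset. Covariate coding reuses the data module's transform
(centering at the realized sample mean), so generated and fitted design
matrices agree.

- **theophylline_like**: single oral dose 4.53 mg/kg at t=0, 11 samples
  over 24 h; weight log-normal (median 70 kg, cv 15%), sex Bernoulli(1/2);
  truth mirrors the fitted values of the real study (z_pop = log(1.6,
  0.087, 32), β_ka,w = 2.55, β_V,w = 0.57, ω = (0.53, 0.15, 0.13),
  a = 0.71) so recovery runs in a realistic signal regime.
- **neonatal_like**: daily weights at t = 0..7 days; covariates sex,
  delivery mode, parity (Bernoulli 0.5/0.3/0.4) and gestational/maternal
  age (log-normal, medians 39 wk / 30 y, cv 3% / 15%, log-centered); five
  parameters (W0 3300 g, kin 150 g/day, T_lag 2 d, kout 0.03 /day, T50
  5 d), ω = (0.10, 0.25, 0.25, 0.25, 0.25), a = 30 g; six true effects
  among the 25 candidates. The daily-weight design identifies `T_lag` and
  `T50` only weakly (the identified-information fraction of their IIV is
  ~0.1–0.2), so the default effect sizes are placed at or above five times
  the detection threshold implied by that identified information — below
  it, no likelihood-based selector can recover them, which would make
  recovery tests a statement about the design rather than the method.

What the generators do *not* emulate: dropout and missingness, dose
recording errors, time-varying covariates, inter-occasion variability,
model misspecification (the fitted structural model is the generating one),
and the real neonatal cohort's demographics. Passing recovery tests
therefore demonstrates correct estimation under the assumed model class,
not robustness to violations of it.

## Numerical choices and degenerate inputs

Posterior Cholesky diagonals are floored at 1e-6; `ω_k²` at 1e-12; a zero
residual floors `a` at 1e-10 with a warning. Rank-deficient covariate
designs raise a singular-design error naming the support. The `ka = ke`
closed-form switch is continuous to 1e-6 relative. Subset-criterion ties
are resolved toward smaller supports deterministically. Importance sampling
uses log-sum-exp throughout; a proposal with a collapsed Cholesky diagonal
is rejected rather than silently producing infinite weights.

## Known limitations

- The Gaussian posterior family biases estimates when the true posterior is
  skewed; on the theophylline-type model the fitted `ka_pop` sits ~2%
  above an exact-MLE reference (R `nlme` on the same data), comparable to
  the scatter among established estimators.
- Weakly identified parameters (neonatal `T_lag`, `T50`) keep the fit
  sensitive to initialization even with the regularized pooled start;
  covariate effects on such parameters need to be large to be detectable
  at moderate N — this is an information limit of the design, not of the
  selector, which is exactly optimal for its criterion.
- When two parameters enter the observable nearly interchangeably (the
  neonatal pairs `kin`/`T50` and `T_lag`/`kout` both modulate the week-1
  weight curve through similar shapes), a real covariate effect on one of
  them is often attributed to the other, or to both: selection computed
  from exact posterior statistics shows the same mis-attribution as the
  amortized fit, so this is a property of the penalized likelihood surface,
  not of the encoder. Supports on confounded parameter pairs should be
  read jointly, not cell by cell.
- The `log N` selection penalty is weak at very small N (N = 12 admits
  chance effects with likelihood-ratio > 2.5), so small-cohort supports
  should be read with the usual skepticism.
- Residual error is univariate Gaussian per observation; no correlated
  residuals, no censoring/BLQ handling, no inter-occasion variability,
  no infusion or steady-state dosing records.
- Training cost is dominated by structural-model evaluations
  (2·nz + 1 vectorized population predictions per gradient step for the
  finite-difference Jacobian); models without a vectorized fast path fall
  back to per-individual adaptive integration and are correspondingly
  slower.

## Study sizes used by the test suite and acceptance script

Conjugate exactness: N = 60 individuals × 5 observations. L0 solver
equivalence: 50 random instances at N = 40, nz = 3, nc = 6, plus a joint
enumeration check at nz = 2, nc = 3. Theophylline recovery: 20 generator
seeds at N = 12 × 11 observations scaled to N = 100. Neonatal recovery:
three seeds at N = 500 × 8 observations (the real cohort is ~5× larger).
Robustness: one N = 50 dataset, five seeds × two hidden widths. These
sizes were chosen so the full suite completes in minutes on one CPU core
while keeping every check in its intended signal regime.
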