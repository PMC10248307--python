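# Methods

## Problem and model

`dwitr` estimates a one-stage, repeated-measures individualized treatment
rule (ITR) from longitudinal data in which the *observation times of the
outcome are irregular and covariate-driven* — the situation typical of
electronic health records, where a patient's weight or blood pressure is
recorded only when they visit, and visiting itself depends on treatment,
symptoms and comorbidities. Conditioning on "being observed" opens
collider paths between the treatment A(t) and the outcome Y(t); an
unadjusted regression on the observed rows is biased even when all
confounders are in the model.

The outcome mean is modelled as

    E[Y(t) | A(t), X(t)] = β'X_β(t) + A(t) · ψ'X_ψ(t),

with X_β(t) the *treatment-free* block (intercept, confounders K(t),
tailoring variables Q(t); never a mediator of the treatment effect) and
ψ'X_ψ(t) the *blip* — the conditional gain from treatment 1 over
treatment 0 given the tailoring variables. The fitted rule is

    treat with A(t) = 1  iff  ψ̂'X_ψ(t) ≥ 0,

with the boundary assigned to treatment 1. Two inverse weights make the
weighted least squares solution of the estimating equation

    Σ_i ∫ w_i(t;κ̂) ρ_i(t;γ̂) [∂f/∂β, A_i X_ψi]' (Y_i − β'X_βi − A_i ψ'X_ψi) dN_i(t) = 0

consistent under the assumptions below:

* **IPT weight** w(t) = 1 / P(A(t)=a_obs | K(t); κ̂), from a logistic
  propensity model — the classical balancing weight for confounding;
* **IIV weight** ρ(t) = exp{−γ̂'V(t)}, from an Andersen–Gill proportional
  rate model E[dN(t) | V(t)] = ξ(t) exp{γ'V(t)} dΛ₀(t) for the visit
  counting process, V(t) = (A(t), Z(t), K₂, K₃) — removing the
  covariate-driven selection of observation times. On the
  time-since-entry axis the baseline rate dΛ₀ is common to everyone at
  risk at t, cancels from the weight up to a constant, and is never
  estimated.

Because f is linear, the estimating equation is exactly weighted least
squares on the stacked design [X_β | A·X_ψ] over the observed-outcome rows;
the solver is the closed-form WLS solution via a rank-revealing
least-squares decomposition, no iteration. Shared columns between the two
blocks are deliberately not deduplicated (they are distinguished by the
treatment gating).

Assumptions: conditional exchangeability given (K, V, dN), positivity of
treatment and of observation, outcome consistency, an acute
(non-carryover) treatment effect so that repeated measures from the same
patient can all enter the estimating equation, uninformative censoring,
and a correctly specified blip. The estimator is *partially doubly
robust*: with a correct blip and an observation model correct with respect
to the covariates linking treatment and outcome, only one of the treatment
or treatment-free models needs to be correct.

## Nuisance-model fitting

**Propensity.** statsmodels logistic regression (Newton ML). By default it
is fit on **all at-risk person-time**, not only the visit rows: the
treatment and confounders are observed continuously, and on the full
process the estimate recovers the treatment-assignment mechanism itself.
Fitting on visit rows only (`propensity_rows="analysis"`) is available; we
found it absorbs part of the visit-selection effect into κ̂ under strongly
informative observation and inflates the doubly weighted estimator's MSE,
so it is not the default. Fitted probabilities must be strictly inside
(0, 1); hitting the boundary raises a positivity error rather than
silently producing infinite weights.

**Visit intensity.** The Andersen–Gill coefficients maximise the Breslow
partial likelihood. Grid-discretised data tie every event time, which makes
Breslow the natural (and fast) choice:

    l(γ) = Σ_t [ Σ_{events at t} γ'V_i(t) − d_t log Σ_{at risk at t} exp(γ'V_j(t)) ].

The solver is a damped Newton iteration on grouped sums over the grid
(`numpy.bincount` per time code), linear in person-time rows. It converges
in well under ten iterations on every simulated design and handles the
5-million-row n = 50,000 cohorts in seconds. Convergence requires the
score norm below 1e−9 × (number of events); failure raises with the final
gradient norm. The implementation is cross-checked in the tests against a
direct Nelder–Mead maximizer of the written-out partial likelihood and
against R `survival::coxph(ties="breslow")` in counting-process form.

Weights are used raw (no stabilisation or truncation), matching the
methodology; an optional upper-percentile truncation
(`weight_truncation=`) exists for real-data use.

## Synthetic cohorts

The generator reproduces the simulation design the method was validated
on. Per patient: K₁ ~ N(1, 1), K₂ ~ Bernoulli(0.55), K₃ ~ N(0, 1), random
intercept φ ~ N(0, 0.04). Per grid time t ∈ {0.01, …, 1.00} (step 0.01,
τ = 1):

    A(t) ~ Bernoulli(expit(0.5 + 0.55K₁ − 0.2K₂ − K₃))
    Z(t) | A=1 ~ N(2, 1);  Z(t) | A=0 ~ N(4, 2)       (a mediator)
    Q(t) ~ N(0.5, 0.5)                                 (tailoring variable)
    Y(t) = t/100 − 2A + 2.5(Z − E[Z|A]) + 0.4K₁ + 0.05K₂ − 0.6K₃
           + 0.5·A·Q − 1·A·K₁ + ε(t),   ε(t) ~ N(φ, 0.01)

All N(a, b) are (mean, **variance**). The true blip is −2 + 0.5Q − K₁,
i.e. ψ = (−2, 0.5, −1) on (1, Q, K₁). Visits are per-grid-point Bernoulli
draws with probability min(0.1·exp{γ'V(t)}, 1) — the discretised
nonhomogeneous Poisson intensity with proportionality constant 1,
calibrated so the uninformative scenario (γ = 0) yields 10 expected visits
on the 100-point grid. Clipping at 1 is logged. Four preset γ vectors on
(A, Z, K₂, K₃) span strong to absent covariate-driven observation:

    scenario1 (−2, −0.3, 0.2, −1.2)   ~3 visits/patient
    scenario2 (0.3, −0.6, −0.4, −0.3) ~3
    scenario3 (0.4, −0.8, 1, 0.6)     ~6
    scenario4 (0, 0, 0, 0)            ~10

What the generator does *not* emulate: serial correlation in covariates
(A, Z, Q are redrawn independently at each grid point), censoring before τ,
outcome-dependent visiting, or measurement error. Passing tests therefore
demonstrate correctness of the estimator under covariate-driven visiting
with independent within-patient covariate draws — not robustness to
endogenous visit feedback or informative censoring.

Randomness: one master seed; replicate r of a Monte Carlo run uses the
`SeedSequence(master, spawn_key=(r,))` substream, so runs are reproducible
and trivially parallelisable.

## Estimator presets

Six configurations mirror the validation study's misspecification grid
(blip always correct):

| name | observation model | treatment model | treatment-free |
|------|-------------------|-----------------|----------------|
| DW1  | A, Z, K₂, K₃      | K₁, K₂, K₃      | K₁, K₂, K₃, Q |
| DW2  | A, Z              | K₁, K₂, K₃      | K₁, K₃, Q (omits K₂) |
| DW3  | A, Z              | K₁², K₂, K₃²    | K₁, K₂, K₃, Q |
| DW4  | A, K₂             | K₁, K₂, K₃      | K₁, K₂, K₃, Q |
| OLS  | —                 | —               | K₁, K₂, K₃, Q |
| IPT  | —                 | K₁, K₂, K₃      | K₁, K₂, K₃, Q |
| IIV  | A, Z, K₂, K₃      | —               | K₁, K₂, K₃, Q |

DW4 omits the mediator Z from the visit model, leaving the collider path
through Z open — it, OLS and IPT are the biased comparators.

## Evaluation metrics

* **MSE of blip values**: per replicate, the mean over that replicate's
  analysis rows of (true blip − estimated blip)²; reported as the mean
  over replicates. It decomposes as squared empirical bias of the blip
  values plus empirical variance (the report carries both, and the
  identity holds by construction of the variance term).
* **Decision error rate**: fraction of analysis rows where the estimated
  and true rules disagree.
* **Value function**: mean outcome over all person-time of a freshly
  simulated population treated by the rule, with the mediator drawn
  conditional on the *assigned* treatment. The time-aggregation (mean over
  all person-time rather than end of follow-up) is this package's choice;
  with the outcome drift α(t) = t/100 being tiny, the two differ by at
  most ~0.005.

Monte Carlo defaults: `run_scenario` defaults to 1000 replicates (the
scale of the original study) and reports MC standard errors so reduced
runs remain interpretable. The bundled tests and the acceptance script use
200 replicates per cell, and the bootstrap coverage check uses 30
simulated datasets × 80 bootstrap replicates — sizes chosen to keep the
default runs desk-scale while leaving every agreement band at ±3 MC
standard errors honest.

## Inference

Two-stage cluster bootstrap (percentile, 95%): resample patients with
replacement, then within each sampled patient resample its observed
outcomes with replacement keeping the original count; relabel duplicated
patients as distinct clusters; refit *everything* (both nuisance models
and the WLS) per replicate so weight-estimation variability propagates.
Percentile rather than BCa intervals, matching the plain bootstrap used in
the methodology's application; the scheme preserves within-patient
correlation but not time trends, and no analytic two-step sandwich
variance is provided.

## Numerical choices and degenerate inputs

* WLS solve via `numpy.linalg.lstsq`; rank deficiency raises an error
  naming the collinear terms (QR with column pivoting).
* Newton step-halving in the rate model guarantees ascent; a singular
  information matrix raises rather than regularising silently.
* Ties at blip = 0 treat (the "≥ 0" convention).
* Zero-visit panels, constant treatment (separation), fewer rows than
  parameters, non-finite weights and single-patient bootstraps all raise
  typed errors.
* BMI utility U(t) = 100 − (|BMI(t)−22| − |BMI(0)−22|)/BMI(0) × 100 for
  application-style outcomes; BMI values outside [15, 50] can be masked
  to missing before analysis (`mask_implausible_bmi`).

## Known limitations

One decision stage only (no backward induction over multiple stages); no
informative-censoring weights; no time effect in the outcome model; no
kernel-smoothing for sporadically measured visit-model covariates; the
bootstrap does not preserve within-patient time trends. The MSE expression
is evaluated as the inner product ψ̂'(1, q, k₁) against the true blip —
the sign convention under which a consistent estimator's MSE tends to
zero.
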