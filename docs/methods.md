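# Methods

This note records the scientific and numerical choices behind `asdyn`: the
submodels and their assumptions, the coupling engine, the synthetic-data
generator, the estimation design, and the places where the underlying
framework left the design genuinely open.

## Submodels

### Social reciprocity (fast tier, hours)

Reciprocity is a depletable resource. The implementation generalises the
constant-rate exponential R(t) = α·R₀·e^(−β_eff·t) to an integrated hazard
R(t) = α·R₀·exp(−∫₀ᵗ β_eff(τ) dτ), accumulated by the trapezoid rule on
the fast grid. With constant loads this reproduces the constant-rate form
at machine precision; with time-varying sensory load it lets the depletion
rate rise mid-interaction, which is exactly the behaviour the packaged
scenario exercises. β_base carries hour⁻¹; all loads and sensitivities are
dimensionless. Resource *restoration* after an interaction has no
governing equation in the framework and is exposed only as a reset between
scenario segments.

### Nonverbal effectiveness and relationships

N = Σ w_norm,i·η_i·x_i is stateless. The six canonical channels (gaze,
facial expression, gesture, posture, paralinguistics, proxemics) ship as a
default registry with normative weights (0.25, 0.25, 0.15, 0.10, 0.15,
0.10) chosen once to sum to one and weight the early-developing channels
highest; arbitrary channel lists are accepted. Relationship quality uses
months as its native unit. The degenerate growth rate k_j = 0 (e.g.
maximal prediction-error variance) returns the analytic limit a_j/2 rather
than raising.

### Stereotypies and the bout process

The oscillatory model is evaluated pointwise; the nonnegativity clamp is
off by default because the mechanistic form is allowed to dip below
baseline, with a flag for observation realism. The bout extension needs an
onset-rate function which the framework leaves unspecified beyond
"dependent on environmental entropy"; the package reuses the amplitude's
saturating form, λ(t) = rate_scale · H/(H + k_H), to keep a single entropy
nonlinearity, and accepts any callable rate as an override. Onsets are
sampled by thinning (candidates at the grid supremum of λ, accepted with
probability λ(t)/λ_max), durations default to log-normal (the framework
names a duration distribution without choosing one) and are truncated at
the next onset so bouts never overlap.

### Insistence on sameness and equifinality

Distress at zero deviation is not forced to zero: the sigmoid's floor
s/(1 + e^(rθ)) is retained as implied by the functional form. The
equifinality diagnostic returns three configurations — high-precision
(π = 4), low-threshold (θ = ref/6) and high-severity (s_max near its cap)
— each solved in closed form for the baseline steepness that places the
reference deviation at the target distress. Feasibility requires the
target to sit strictly between half and all of the chosen s_max; targets
at or above the severity cap raise.

### Sensory load

The three analytic branches of P(s) are implemented as printed, with a
series branch |δ| ≤ ε = 1e-8 hour⁻¹ using the second-order expansion
σT·(1 − δT/2 + (δT)²/6) to avoid catastrophic cancellation while honouring
the explicit δ = 0 branch; continuity across the joins is tested at
1e-6·σT. σ is stored as a sensitivity index per unit time — the source
notation is internally ambiguous on this point ("dimensionless index" with
hour⁻¹ attached) and the package resolves it as index·time⁻¹ in the
scenario's time unit.

## The coupling engine

Each fast step updates, in order: (1) per-stimulus response levels and
cumulative load P_total, using the habituation rate computed from the
*previous* step's arousal (the one-step lag that makes the dependency
graph acyclic — asserted by topological sort at startup via networkx);
(2) the instantaneous social sensory load Λ_s = P_total/(P_total +
capacity), a saturating two-parameter coupling chosen for boundedness
because the framework states only that Λ_s increases with P_total;
(3) β_eff and R by integrated hazard; (4) Γ_eff and M from current
entropy; (5) routine-deviation distress, with events persisting from their
onset; (6) arousal Ξ_{n+1} = max(0, a·Ξ_n + b·Λ_s + c·S), a minimal linear
recursion (no arousal equation exists in the framework) with coefficients
(0.8, 0.5, 0.5) per reference minute, rescaled as a^(dt/dt₀) and linear
gains ·(dt/dt₀) so grid refinement is consistent to first order. Slow-tier
states C(t) and I(t) are evaluated on their own monthly grid and
interpolated; over sub-day horizons they are effectively quasi-static, as
are the slow parameters (precision weights, baseline depletion). The
composite A(t) is computed last and never fed back.

Within-step load accumulation uses the exact one-step solution
ΔP = y·(1 − e^(−δ·dt))/δ with y ← y·e^(−δ·dt), so a constant-δ exposure
reproduces the analytic branches to round-off; with δ = 0 accumulation is
exactly linear and independent of step size. Post-exposure clearance is an
optional first-order decay (default off, matching the packaged scenario's
monotone accumulation; recovery is asserted only as "no further
accumulation"). Withdrawal fires at the first *reporting-grid* time
(default 15 min) where P_total exceeds the profile threshold, matching the
cadence at which a person or observer would actually register the state.

### The packaged restaurant scenario

Time unit: minutes, with σ and δ per minute so the printed arithmetic
0.8 × 90 = 72 is reproduced literally; the narrated δ ≈ 0.02 is dropped in
the same source's own arithmetic, and the package follows the arithmetic
(δ = 0). The seating-routine baseline steepness is a derived calibration,
solved by root finding so that a deviation of 0.6 against (π = 4.0,
θ = 0.3, s = 0.9) yields distress 0.85 (r_base ≈ 2.36); it is not treated
as ground truth. The coupling capacity (30), sensory-load sensitivity
(k_Λ = 2), Γ_max = 1.0 and k_H = 2.0 bits are unprinted free parameters
chosen once so that the depletion rate rises from 0.30 toward ≈ 0.5 per
hour by t = 60 as narrated; the narrated R(t) ≈ 0.45 and Γ_eff ≈ 0.4 → 0.7
depend on these unprinted values and are matched qualitatively (monotone
decline; rising amplitude), not asserted numerically.

## Composite index

Orientation is not specified by the framework: it calls the index a
severity measure while three of its components (R, N, C) increase with
*better* functioning. The package therefore reflects those three
(z ← 1 − z) by default, controlled by a per-component orientation flag.
Normalisation bounds default to theoretical ranges where forced (R ∈
[0, 1]) and to generous calibration ranges otherwise; the movement bound
admits negative values because the unclamped oscillation dips below
baseline. Bounds, orientations and the descriptive-summary caveat are
echoed into the result metadata. Out-of-range components are clipped with
a logged warning. The acknowledged redundancy — cumulative sensory load
entering both directly and through β_eff — is retained as designed.

## Synthetic EMA data

The generator emulates smartphone-based EMA: six prompts per day with
±30-minute uniform jitter by default, nearest-grid-point lookup into the
simulated truth, additive Gaussian noise, and clipping to each variable's
valid range. Observations carry the identifiability tier of their data
stream (tier 1 = EMA-observable; tier 2 = structured observation), and
fitting specs gate on tier so recovery experiments can restrict themselves
to realistically observable channels. Population draws use uniform ranges
matching the plausible ranges stated for each submodel (e.g. baseline
depletion 0.1–0.5 hour⁻¹), with point masses elsewhere. What the
generator does *not* emulate: missing-not-at-random responses,
retrospective-report bias, logit-scale (floor/ceiling-compressed) noise,
and actigraphy waveforms (bout sequences stand in for actigraphy counts).
Passing recovery tests therefore show identifiability under clean
measurement, not robustness to real EMA pathologies.

## Estimation

Fitting is sum-of-squares minimisation (`scipy.optimize.least_squares`)
in transformed space — log for positive parameters, logit for unit-interval
parameters — with a seeded Latin-hypercube multi-start (default 8; the
round-trip tests use 16 because the sinusoid's frequency–phase surface is
multimodal) and asymptotic standard errors from the Jacobian at the
optimum via the delta method. Structural confounds are resolved by
canonical reparameterisation: the reciprocity amplitude α·R₀, the distress
steepness r = r_base·π, and interest intensities/decays b_l, λ_l are
estimated jointly, because the mechanistic factors are not separately
identifiable from trajectories alone (they belong to different data-source
tiers). The mechanistic factorisations remain available to the
identifiability audit, which ranks log-parameter sensitivity directions by
singular value and reports near-null directions — an exact multiplicative
confound appears as a (1, −1) direction. Recovery experiments are fully
seeded simulate–fit–compare loops reporting per-parameter bias, RMSE with
Monte-Carlo standard error, and 3-SE coverage. Hierarchical Bayesian and
state-space estimators are out of scope; the least-squares path is the
only estimator. Note the caveat that recovering tier-3 parameters (δ_s,
β_base) from synthetic trajectories overstates their real-world
identifiability, where they are proposed to need neuroimaging anchors.

## Units and validation

Hours are canonical for fast submodels, months for slow ones; scenario
files may use minutes, converted on load. The dimensional rules (every
exponent, sinusoid argument and ratio reduces to dimensionless) are
encoded as a static table checked during profile validation. Unit
reduction has a strict mode (hour and month distinct) and a permissive
default (time units collapsed), because scenarios legitimately mix
minute-scale narration with hour-scale rates. Profile validation returns
messages rather than raising, is idempotent, and renormalises composite
weights on load (tolerance 1e-12) with a logged notice. Name collisions in
the source notation (two distinct k_E's; three distinct sensory-load
symbols) are resolved by namespaced fields; `asdyn.symbol_concordance()`
prints the symbol ↔ field mapping.

## Problem sizes

The default test and acceptance runs use the 121-point vignette grid
(1-minute steps over two hours), 200-replicate bout calibrations over
50-hour horizons, 200-point fits, and 50-replicate recovery experiments —
sizes at which every stochastic check has comfortable Monte-Carlo margins
while the whole suite completes in seconds.

## Known limitations

- No continuous-time ODE solver: all submodels are closed-form between
  events, which is exact here but precludes adding feedback terms without
  reworking the engine.
- The arousal recursion and the load-coupling map are package constructs
  (the framework names the couplings without equations); both are
  configurable and documented rather than hidden.
- Developmental parameter drift (e.g. β_base as a function of age) is an
  extension point only; profiles are static within a scenario.
- The composite's orientation convention and normalisation bounds are
  package defaults, fully recorded in output metadata, and should be
  revisited against any empirical anchoring.
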