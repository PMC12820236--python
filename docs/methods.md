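# Methods

## Model and assumptions

The package simulates a minimal, deliberately generic model of an
incurable tumor under systemic therapy.  Two subpopulations — drug
sensitive S(t) and drug resistant R(t) — grow logistically toward a
shared carrying capacity K and compete:

    S' = α_S S (1 − (S+R)/K) − δ C S
    R' = α_R R (1 − (β S + R)/K)
    C' = −λ C                       (dosing enters as impulses)
    T' = μ C − γ T

Assumptions worth keeping in mind:

* resistance is **pre-existing** (1% of the initial burden) and fully
  refractory; there is no mutation or phenotype switching;
* resistance carries a fitness cost: α_R = ε α_S with ε ∈ (0, 1], so ε
  is the stored degree of freedom and α_R is always derived (an
  inconsistent pair is unrepresentable);
* the drug kills only sensitive cells, at rate δ per unit concentration;
* pharmacokinetics are one-compartment with linear clearance λ; each
  dose is an instantaneous unit impulse on C;
* toxicity is an abstract accumulated-exposure variable: it rises
  proportionally to C (rate μ) and resolves linearly (rate γ).  Its
  absolute scale is arbitrary — jointly rescaling μ and both toxicity
  thresholds leaves tumor dynamics and every dosing decision unchanged,
  which is why μ is fixed in the sensitivity and population analyses.

Burdens are expressed on a 0–100 scale (percent of carrying capacity).
Baseline parameters: α_S = 1 /day, ε = 0.4, K = 100, δ = 1 /day,
β = 2.4, λ = 0.693 /day, μ = 1 /day, γ = 0.4 /day; initial state
S₀ = 49.5, R₀ = 0.5, C₀ = T₀ = 0 (pre-dose values).

## Protocols and decision semantics

Decisions happen at discrete decision times t = 0, 1, 2, … days (the
course opens with a decision, and the first dose is administered at
t = 0 unless the rule pauses immediately).  Each rule is a hysteresis
state machine initialized to *treating*:

* `daily` — always treats;
* `adaptive` — pause when S+R falls below Rx_off (default 20, i.e. 40%
  of the initial burden of 50), resume when it exceeds Rx_on (default
  50, the initial burden);
* `daily_tox` — pause when T surpasses Tox_off (2), resume when T drops
  below Tox_on (1);
* `adaptive_tox` — pause conditions OR-ed, resume conditions AND-ed, so
  toxicity acts as an override on the tumor-size rule.

Threshold comparisons are strict; exact equality leaves the status
unchanged (deterministic tie handling that matches the "falls below" /
"surpasses" reading of the rules).  Because decisions are only taken at
the discrete decision times, the tumor can overshoot Rx_on between
checks — a real feature of discretely monitored adaptive schedules, not
an artifact.

Treatment failure is the first upward crossing of S+R through the
failure size (75, i.e. 150% of the initial burden, mirroring
RECIST-style progression).  The crossing is located **continuously** by
root-finding during integration; the daily check governs dosing only.
TTP is reported on the simulation clock; courses that do not fail
within the 100-day horizon record the sentinel value 150, which also
participates in population means (a deliberate convention: it rewards
durable control in threshold optimization while keeping a finite
scale).

A consequence of discrete decisions worth flagging: TTP is a
**piecewise-constant, cliff-ridden function of the protocol
thresholds**.  A threshold change matters only when it flips some daily
decision, so TTP landscapes contain plateaus separated by jumps, and a
course whose toxicity at some decision time lies within a fraction of a
percent of a threshold can land on either side of a large cliff
depending on integration accuracy.  The package's integrators resolve
the decision observables far below that level (see below), so its
plateau assignments are reliable; solvers with percent-level error can
report a neighboring plateau.

## Numerical integration

Two engines, cross-validated against each other in the test suite:

* **Event engine** (`simulate`): SciPy LSODA (stiff-capable,
  variable-step) at rtol 1e-8 / atol 1e-10, restarted at every decision
  time so a dose impulse never sits inside a solver step, with terminal
  event detection on S+R − failure_size (direction: upward).  The
  integrated state is (S, R, C); toxicity is propagated by its exact
  per-interval closed form (between impulses C is exactly exponential,
  so T(t) = T₀ e^{−γΔ} + μ C₀ (e^{−γΔ} − e^{−λΔ})/(λ − γ), with the
  λ = γ limit μ C₀ Δ e^{−γΔ}).  This is algebraically equivalent to
  integrating the four-state system — the suite checks it against an
  independent four-state solve at tighter tolerance — and makes the
  μ-rescaling invariance hold to machine precision.  Halving the
  tolerances moves baseline TTPs by well under 0.05 days.
* **Batch engine** (`ttp_batch`): a fixed-step classical Runge–Kutta
  scheme (step 0.01 days) on (S, R) with C evaluated in closed form at
  the stage times and T by the same exact recurrence, vectorized over
  thousands of parameter/threshold sets at once.  Failure crossings are
  located by linear interpolation inside the bracketing step; agreement
  with the event engine at baseline is at the millidays level.  Sweeps
  default to the event engine; the sensitivity and population layers
  use the batch engine.

Dense output (0.01-day grid plus all decision/dose/event times)
duplicates rows at dose instants — the honest representation of a jump
in C.  Integrator round-off can leave state components microscopically
negative as S decays toward zero under sustained dosing; values above
−100·atol are clipped to zero and anything more negative raises, so
genuine model errors are never silently hidden (the cutoff is tied to
the solver tolerance because absolute round-off scales with it).

Closed-form oracles (`analytic_C`, `analytic_T`) back the integrators:
the suite requires the numerically integrated C to match exponential
decay to 1e-6 relative and T to match the convolution closed form to
1e-5 relative, and verifies the closed form itself against numerical
quadrature.

## eFAST sensitivity analysis

The extended Fourier Amplitude Sensitivity Test treats TTP (sentinel
included) as the model output.  Parameters and ranges: α_S ∈ [0.5, 1.5],
ε ∈ [0.2, 1], δ ∈ [0.5, 1.5], β ∈ [0.5, 3.5], γ ∈ [0.2, 0.8], plus one
inert dummy parameter; μ is excluded as non-identifiable (rescaling
argument above).  Defaults M = 4, Ns = 257 points per curve, Nr = 5
resampling curves with fresh random phases — customary template values,
all configurable.  The parameter of interest carries the largest
frequency admissible under the Nyquist criterion Ns ≥ 4·M·ω_max + 1
(ω_max = 16 at the defaults); complementary parameters get maximally
spread frequencies in [1, ω_max/(2M)].  First-order indices come from
the spectral power at the interest frequency and its first M harmonics,
total-order indices from one minus the complementary (low-frequency)
power fraction; indices are averaged over curves, and per-curve values
feed Welch t-tests against the dummy (the dummy calibrates the noise
floor — eFAST assigns small nonzero indices even to inert inputs).

The engine is validated against analytic Sobol indices of additive test
functions (recovered within 0.05 absolute at the default settings).  On
the treatment model, β dominates TTP variance under the adaptive
protocols and ε under daily dosing.  One caveat: in the dual-feedback
protocol every first-order index except β's is below ≈0.08, so the
*ranking* among γ, α_S and ε there is a near-tie and can reorder
between runs; only the dummy-calibrated significance pattern is stable.

## Sweeps and the γ scan

Threshold sweeps mask combinations violating Rx_on > Rx_off or
Tox_off > Tox_on as infeasible rather than skipping them silently.
Default grids are 13 evenly spaced points per axis — toxicity axes over
[0.25, 2.25], Rx_off over [5, 70], Rx_on over [30, 80] — and are fully
configurable; grids are recorded in the output manifest.  Optimal
protocol maps keep exact TTP ties as sets (ties are common at the
sentinel).

The cause-of-failure classification uses a majority rule: a course is
resistant-driven if R/(S+R) > 0.5 at the crossing, else
sensitive-driven (the simplest faithful discretization of tumor
composition at failure).  The γ bifurcation scan defaults to 20 points
over [0.05, 1.0], wide enough to show all three regimes at low drug
efficacy: sensitive-driven failure at slow recovery, a no-failure
window at intermediate γ, resistant-driven failure at fast recovery —
and the window's disappearance at high efficacy.

## Virtual populations

A virtual patient is (α_S, ε, δ, β, γ) drawn from independent
lognormals; K, λ, μ stay at baseline (K cannot affect TTP when the
initial and failure burdens are fractions of it; μ and λ trade off
against γ and δ).  Each lognormal's **mode** sits at the baseline value
and its log-scale σ is set so the central 95% interval spans that
parameter's eFAST range (σ = ln(hi/lo)/(2·1.96)); both choices are
config defaults recorded in output metadata.  ε draws above 1 are
rejected and redrawn, preserving the lognormal shape within (0, 1]
instead of piling mass at the boundary.  Note that mode-anchoring of a
wide lognormal pushes the median above the mode — for β the population
median is ≈3.1 — so the population is more treatment-controllable than
the baseline patient; population-level numbers should be read as
order-level, not calibrated, results.

Threshold optimization is an exhaustive search over feasible grid
combinations (up to the four-dimensional space of the dual-feedback
protocol), maximizing mean TTP with sentinels included; ties break to
the first combination in lexicographic grid order, with the tie count
reported.  When comparing optimized protocols, the dual-feedback search
grid includes a toxicity-disabling level (Tox_off = ∞ with a very large
Tox_on) so that the adaptive protocol's search space is nested inside
it and optimization dominance holds by construction.

Kaplan–Meier curves use the raw progression times: with no censoring
before the administrative end of study at day 100, the estimator
coincides with the empirical fraction not yet progressed (cross-checked
against lifelines in the suite); sentinel patients are non-events
carried to the horizon.

## What the generators do and do not emulate

Synthetic inputs are parameter sets and virtual populations — there is
no measurement noise, no sampling correlation between parameters, no
monitoring error on burden or toxicity, and no patient dropout.
Passing tests therefore demonstrate correctness of the dynamics,
decision rules and estimators under the model's own assumptions, not
robustness to real-world observation noise or model misspecification.

## Known limitations

* Dose skipping only: no dose modulation, no non-daily monitoring
  intervals, no drifting threshold bands.
* Toxicity is a single abstract exposure variable, not a
  biomarker-calibrated PK/PD quantity.
* Near-threshold decision times make single cells of threshold space
  sensitive to integration accuracy (see the cliff discussion above);
  conclusions should be drawn from plateaus, not single cells.
* The batch engine's fixed step (0.01 days) bounds its crossing-time
  resolution; it is for landscapes and populations, while single-course
  reference numbers should use the event engine.
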