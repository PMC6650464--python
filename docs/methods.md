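# Methods

## Model and assumptions

The package implements a two-compartment (S, I) epidemic model with
ratio-dependent incidence g(S, I) = β S^h I / (S^h + α I^h) under two
environmental noise sources: a continuous-time Markov chain r(t) that
switches the full parameter set between N regimes, and one Brownian motion
perturbing the transmission coefficient (β dt → β dt + σ dB). The noise
enters S and I with opposite signs, so the diffusion matrix is degenerate
and S+I evolves deterministically given the regime path. The chain is
assumed irreducible — strong connectivity of the positive-rate digraph, not
positivity of every off-diagonal rate — and independent of the Brownian
motion. The incidence family is usually stated for h ≥ 1; values h < 1 are
accepted with a warning because the shipped reference parameterization uses
h = 0.002.

Boundary conventions: incidence, diffusion and the Milstein correction are
defined as 0 whenever S = 0 or I = 0 (the continuous limit for h > 0), so
the vector field is defined on the closed quadrant and the I = 0 axis is
invariant.

## Threshold quantities

With π solving π Γ̃ = 0, Σπᵢ = 1 (computed by replacing one balance
equation with the normalization and solving the linear system — no
eigen-decomposition, hence bit-stable):

* R₀ᵢ = βᵢ/(μᵢ+γᵢ+εᵢ), the deterministic basic reproduction number of
  regime i;
* R₀^S = Σπᵢβᵢ / Σπᵢ(μᵢ+γᵢ+εᵢ+σᵢ²/2); R₀^S > 1 ⇒ unique ergodic
  stationary distribution (persistence);
* R̄* = Σπᵢβᵢ²/(2σᵢ²) / Σπᵢ(μᵢ+γᵢ+εᵢ); R̄* < 1 ⇒ almost-sure extinction,
  as does {R₀^S < 1 and σᵢ² ≤ βᵢ ∀i}.

`classify_dynamics` reports `persistent` when R₀^S > 1, else `extinct_i`
when R̄* < 1, else `extinct_ii` when R₀^S < 1 with σᵢ² ≤ βᵢ everywhere,
else `indeterminate`. The precedence (persistent first, then condition (i),
then (ii)) makes the report deterministic when several sufficient
conditions hold simultaneously. R̄* is undefined (and reported as such)
when any σᵢ² = 0.

For the shipped reference cases this yields: case a — R₀^S = 76/70 ≈ 1.086,
persistent; case b — R̄* = 0.38/0.52 ≈ 0.731, extinct_i; case c — direct
evaluation of the R₀^S formula gives 19/18 ≈ 1.056 > 1, hence persistent.
The case-c fixture carries a note: the analysis it reproduces reports the
same parameterization as sub-threshold with the value 0.76, which equals
the numerator Σπᵢβᵢ alone; the package always reports the full formula
value and surfaces the discrepancy rather than guessing intent.

## Equilibria of the deterministic skeleton

E₀ = (Λ/μ, 0) always exists. For R₀ > 1 the endemic point solves the
balance equations I* = k S*, k = ((R₀−1)/α)^(1/h), and
Λ − μS* − (μ+γ+ε)I* = 0, giving S* = Λ/(μ + k(μ+γ+ε)). (A closed form
S* = Λμ/(Λμ + k(μ(μ+ε)+μγ)) sometimes quoted for this system is a drift
fixed point only when Λ = μ; the balance-equation solution is verified
against the drift field to 1e-10 at construction.) k is evaluated in log
space; for small h it can overflow double precision (at h = 0.002, regime 1
has S* ≈ 1.7e-239), in which case the endemic equilibrium is reported as
not representable with a diagnostic instead of returning infinities.

## Numerical scheme

**Chain first, SDE second.** The regime path is sampled exactly —
holding times Exponential(−γᵢᵢ), embedded-chain jump probabilities
γᵢⱼ/(−γᵢᵢ) — and the SDE is integrated within each constant-regime segment,
the last sub-step truncated at the jump time. This avoids the O(dt) regime
discretization bias of per-step switching.

**Milstein with scalar noise.** One Brownian motion drives both components,
so strong order 1 needs no Lévy areas: X' = X + a dt + b dB +
½(b·∇)b (dB²−dt) with the analytic correction. Brownian increments have
variance equal to the actual sub-step length. The I-update is computed from
the conservation identity S'+I' = S+I+(aS+aI)dt, enforcing the degeneracy
(noise and correction cancel in the sum) up to a final rounding (≤ ~2 ulp).

**Correction validity guard.** For h < 1 the diffusion derivative
∂b/∂S ~ S^(h−1) is singular at S = 0, while the model legitimately drives S
to extremely small values (see above). Near the boundary the correction
coefficient c = (b·∇)b grows like 1/S and the stochastic-Taylor
linearization behind Milstein is invalid: unguarded, a step from S ≈ 1e-12
can catapult the state by |½ c (dB²−dt)| ~ 1e5. Path stepping therefore
applies the correction only where |c|√dt ≤ |b| and degrades to
Euler–Maruyama otherwise. The guard region vanishes as dt → 0, so the
strong order away from the degeneracy is unaffected (measured order ≈ 1.05
for reference case a). The public `milstein_step` remains the unguarded
textbook update.

**Positivity policy.** The exact solution stays in the open quadrant;
violations are discretization artifacts. If a sub-step takes I below 1e-12
it is absorbed to exactly 0, permanently (incidence and noise vanish
there). If a sub-step takes S ≤ 0 the Brownian increment is resampled once,
then S is clamped to 1e-12 and the event counted. The deterministic RK4
integrator clamps negative I undershoot to 0 and counts it.

**Deterministic integration** uses classical fixed-step RK4 (bit
reproducible, clean 4th-order convergence surface; verified slope ≈ 4).

**Strong-order diagnostic.** Refinements are coupled: per path, one
Brownian path and one regime path are frozen on the finest grid (jump times
snapped to that grid so all resolutions split steps at identical points);
coarse increments are sums of fine ones, and the endpoint error is measured
against the finest resolution. Because the reference sits at the finest dt,
purely deterministic truncation errors fit with an apparent slope slightly
above 1 (error ∝ dt − dt_fine); the stochastic fits are insensitive to
this.

**Seeding.** Every stochastic operation takes an explicit seed; a path
derives two independent sub-streams (chain, Brownian) from
SeedSequence(seed, spawn_key), and ensemble path k uses spawn_key=(k,), so
growing an ensemble never changes earlier paths and every array is
bit-reproducible.

## Ensemble diagnostics

`simulate_ensemble` (defaults: T = 1000, dt = 0.01, 200 paths, matching the
reference experiment's horizon) reports the extinction fraction
(I(T) < floor, default 1e-4), per-path time averages of I over an analysis
window (default [T/2, T]), and per-regime 2-D histograms of (S, I) — the
empirical counterpart of the invariant density u*(x, y, i). Default
histogram ranges are [0, 3.5]² with 40 bins: S+I is pulled below
max(Λᵢ/μᵢ) = 3 by the drift, so the state rarely leaves [0, 3]². The
stationarity diagnostic compares regime-stacked empirical densities on the
windows [T/2, 3T/4] vs [3T/4, T] and [0, T/4] vs [3T/4, T] in L1; approach
to an invariant density shows as the late-late distance falling below the
early-late one.

## What the reference parameterization does and does not show

With h = 0.002 the incidence ratio q = S^h/(S^h + αI^h) is nearly constant
(≈ 0.84 and 0.91 in the two regimes) over the entire double-precision range
of S and I, because S^h and I^h move only on scales e^(±1/h). Two practical
consequences, confirmed by simulation and by an independent Euler–Maruyama
cross-check:

* S legitimately collapses to extremely small values whenever regime 1
  dominates (the regime-1 endemic S* is ~1e-239), so the S-positivity
  clamp is exercised routinely in case a; it acts as a reflecting floor.
* The persistence margin of case a (R₀^S ≈ 1.086 > 1) rests on q → 1 as
  I → 0, which materializes only below I ~ e^(−1/(2h)) ≈ e^(−250). At
  representable I the effective boundary growth rate Σπᵢ(βᵢqᵢ − (μᵢ+γᵢ+εᵢ)
  − σᵢ²qᵢ²/2) is ≈ −0.005…0: log I diffuses essentially without drift
  (sd ≈ 16 per 1000 time units). Finite-horizon ensembles of case a
  therefore show a substantial fraction of paths below any practical
  extinction floor by T = 1000 (≈ 0.74 at 200 paths, dt = 0.01, floor
  1e-4), even though the infinite-precision model is ergodic. Case b's
  almost-sure extinction, by contrast, is reproduced cleanly
  (extinction fraction 1.0 under the same protocol).

Passing ensemble tests therefore demonstrate the direction of the
dichotomy (case b dies out; case a retains mass and its late-time empirical
densities stabilize), not literal positivity of every finite-precision
path in case a.

The synthetic regime/Brownian generators emulate exactly the model's own
noise structure; they do not emulate features of real epidemic data
(demographic stochasticity, reporting noise, seasonality), so agreement
here validates the mathematics and the integrator, not fit to data.

## Known limitations

* No Fokker–Planck/PDE route to the invariant density; it is accessed only
  empirically through histograms.
* No schemes above strong order 1; no adaptive stepping.
* The boundary policy (floors at 1e-12) is a pragmatic reflection of
  double precision, not a claim about the exact process; with h ≪ 1 the
  region near S = 0 is numerically delicate and clamp counts are reported
  so runs can be audited.
* Threshold classifications cover only the proven sufficient conditions;
  parameter sets outside them are labelled indeterminate rather than
  decided by simulation.
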