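# Methods

## Circuits and normalization

Two species: the regulated species *Y* and its proxy *X*, co-produced
under a common input *u* with production law `f(u)` (affine, `f(u)=a·u+b`,
is first-class; other monotone laws enter through a function descriptor
and numeric steady states).  Reaction schemes:

| motif | production (coupled) | production (decoupled) | degradation |
|---|---|---|---|
| FB | `∅ → X+Y` at `f(u)·g(x)` | two channels, same law | `l1·x`, `l2·y` |
| IFF | `∅ → X+Y` at `f(u)` | two channels | `k1·x`, `k2·y`, `k12·x·y` |
| combined | `∅ → X+Y` at `f(u)·g(x)` | two channels | `l1·x`, `k2·y`, `k12·x·y` |
| direct FB | `∅ → Y` at `f(u)·g(y)` | — | `l2·y` |

Normalization (`k1=l1`, `k2+k12·x̄=l2`, `g(x̄)=1`) pins every variant to
the same means `x̄=f(ū)/l1`, `ȳ=f(ū)/l2` and the same stationary fluxes, so
comparisons at equal effective gain are resource-fair.  Gains map to rates
as `k2=l2/(1+α_ff)`, `k12·x̄=l2·α_ff/(1+α_ff)`; `α_ff=∞` is represented
exactly as `k2=0` (never as a float infinity), and `α_fb=∞` by the finite
stand-in `1e6` with a warning, since a ramp cannot realize an infinite
slope with finite rates.

Two inhibition families, both anchored at `g(x̄)=1`:

* **ramp** `g_R(x) = max(1+α−α·x/x̄, 0)`, zero beyond
  `x0=((1+α)/α)·x̄`.  Its virtue is exactness: the production propensity
  is affine on the whole reachable lattice, so the moment hierarchy closes.
* **Hill** `g_H(x) = (1+c)/(1+c(x/x̄)^n)`.  The user-facing knob is the
  gain α; the exponent is solved from the anchor slope, `n = α(1+c)/c`, at
  fixed `c = 10`.  This keeps FB/IFF comparisons gain-matched by
  construction.

## Deterministic analysis

Steady states are closed-form; `integrate_ode` uses fixed-step classical
RK4 with step `0.5/λ_max` (`λ_max` the fastest linearized rate).  The ramp
right-hand side is continuous and piecewise smooth, and all fixed points
sit strictly inside the linear branch, so no special event handling is
needed at the kink.  Dynamic inputs are piecewise-constant (birth–death
trajectories); `u` is evaluated once per step, so switching times are
resolved to one step (negligible against the thousands of events per
trajectory).

For ramp inhibition the steady-state curve
`y_ss(u) = ȳ(1+α)f(u)/(f(ū)(1+α·f(u)/f(ū)))` holds identically for FB,
IFF and the combined motif; it was verified against ODE fixed points (its
three limits — `u=ū`, `α=0`, `α→∞` — pin the form).  The local sensitivity
`ȳ·f′(ū)/(f(ū)(1+α))` uses `α = α_comb = α_fb+α_ff+α_fb·α_ff` for the
combined motif; the tests confirm it against centered finite differences
of the integrated steady state over a 4×4 grid of gain pairs.

## Exact FB moments (ramp)

Because the ramp propensity is affine up to its own zero, the stationary
first and second moments solve a linear system (implemented generically in
`affine_stationary_moments` for any affine-propensity network).  The
resulting decomposition

```
var(y) = ȳ/(1+α) + P_proxy [+ P_decouple]
P_proxy    = ȳ·α(α+r)/((1+α)(1+α+r)),   r = x̄/ȳ
P_decouple = ȳ·α/(1+α+r)
```

is *derived* from the moment equations at run time (the closed forms above
are only cross-checked in tests, and against FSP to 1e-3 relative).
Consequences: optimal coupled gain `α*→1` with a 25% reduction as `r→0`,
`α*=√2` with ≈17.16% at `r=1`, nothing as `r→∞`; any decoupled feedback
hurts.  The exact solution presumes an integer ramp cutoff;
`fb_stationary_moments` snaps the requested gain to the nearest gain whose
cutoff is an integer (`α_eff = x̄/(x0−x̄)`) and reports both.  Gain
*optimization* uses the continuous closed form.

The direct-feedback circuit (one species) has a binomial stationary law
with `var(y)=ȳ/(1+α)`; validated against FSP rather than re-proved.

## Static input mixtures

With `u ~ Poisson(ū)` frozen per cell, total variance follows the law of
total variance.  The `finite` realization mixes exact per-`u` conditional
ramp moments (the inhibition stays anchored at the nominal `x̄`) over the
Poisson support truncated at mass `1−1e-10`.  The named strong-feedback
realizations return the idealized `α→∞` forms `(C+b)/l2 − 1` (coupled) and
`2(C+b)/l2 − 1` (decoupled), `C=a·ū`.  The exact maximal-integer-gain
variance differs from these by O(1) counts (the coupled form is within one
count; the decoupled one ~2 counts below the idealization at `x̄=ȳ=50`) —
SSA tests therefore validate the coupled/no-feedback forms at 3 bootstrap
SEs and the decoupled case against the exact finite mixture.  The
decoupled-vs-none preference threshold is returned as the exact crossing
of the two closed forms, `ū* = C²/(l2(C+b−l2))`.

## IFF moment closure (derivative matching)

The bilinear degradation `k12·x·y` leaves `<xy>` depending on `<x²y>` and
`<y²>` on `<xy²>`.  Derivative matching closes them with the lognormal
product rule

```
<x²y> ≈ <x²><xy>²/(<x>²<y>),    <xy²> ≈ <y²><xy>²/(<y>²<x>).
```

`<x>` and `<x²>` are exact (the x-marginal is a plain birth–death
process).  The remaining 3-unknown algebraic system is solved by `hybr`
root-finding with geometric continuation in the gain from the analytic
`α_ff=0` start; negative-variance roots are rejected.  Special cases
bypass the closure: `α_ff=0` gives `var(y)=ȳ` exactly; `k2=0` gives
`var(y)=ȳ` for coupled production (FSP confirms this *exactly*) and
`ȳ + ȳ/(1+x̄/ȳ)` for decoupled production (a reconstruction pinned by FSP
to ~5% and by its two limits: the penalty doubles the variance as `x̄→0`
and vanishes as `x̄→∞`).

Closure accuracy against FSP at `(x̄,ȳ)=(50,50)`: variances within 5%
(typically 0.3%), means within 2%.  At means of order one the closure
over-estimates the achievable reduction by several points — hence the
reduction-cap scan (below) reports closure values, the quantity the caps
refer to.

The closed-form optimal gain `α* = (x̄+ȳ)/(1+x̄+ȳ)` agrees with the numeric
minimizer of the closure variance within 2%.

### Reduction-cap scan

The scan grid covers gains `α_ff ∈ [0,20]` (log/linear mix refined near 1,
plus the closed-form optimum at each grid point) and mean populations
`x̄, ȳ ∈ {1, 2, 5, …, 200}`.  One molecule is taken as the smallest
meaningful mean count; with that floor the maximal coupled-closure
reduction is ≈25.1%, and ≈24.9% when both means are ≥ 2.  The cap is not
robust to sub-molecule means: pushing the means toward zero, the closure
reduction keeps growing (≈40% at means of 0.2), but there the closure's
own error is large (FSP gives ≈34%) and the mean itself collapses, so
those operating points are not biologically interpretable and are excluded
by design.

## Linear noise approximation and decomposition

Fluctuations about the steady state follow `dξ = A·ξ dt + S·diag(w̄)^{1/2} dW`
with `A` the drift Jacobian and `w̄` the stationary propensities; the
stationary covariance solves `AΣ + ΣAᵀ + D = 0`, `D = S·diag(w̄)·Sᵀ`.  For
the affine ramp schemes the LNA is *exact* (the tests exploit this as an
internal consistency check).  Linearity in `D` lets the variance split into
per-channel contributions (one Lyapunov solve per channel), which exposes
the control limit: at zero gain the two degradation channels carry exactly
50% of `var(y)`, untouched by any gain; the optimum halves the remaining
(production-correlated) half — 25% overall.  The controllable-portion
reduction is reported as (variance saved)/(zero-gain controllable share),
since the gain also re-injects proxy-degradation noise and a
channel-by-channel attribution at the optimum would double-count that
side effect.

The combined circuit (production `f(u)g(x)` for both species, degradation
`l2 = k2 + k12x̄` split by `α_ff`) adds nothing against intrinsic noise:
the 2-D gain optimization at `r=1e-3` finds a flat optimal ridge
`(1+α_fb)(1+α_ff)=2` — i.e. `α_comb=1` — at the same 25% cap.  Its
sensitivity to static inputs, however, carries the super-additive gain
`α_comb`, which is the combined circuit's real advantage.

## Frequency-domain analysis

For `u(t)=ū+δ(t)` the linearized input→y map has squared H2 norm
`C·P·Cᵀ` with `AP+PAᵀ+BBᵀ=0`.  Noise enters additively as `σ·[1,1]ᵀ·ẇ`
(one shared Wiener process on both equations; mode `input_derivative`
replaces `σ` by `f′(ū)`).  FB drives the output variance to zero with
gain; every IFF obeys the floor `σ²/(2(l1+l2))`, attained as `α_ff→∞`
(the σ² prefactor was confirmed by the Lyapunov solve's limit before the
floor test was locked in).

The Euler–Maruyama ensemble (dt ≤ min(1e-3, 0.1/λ_max), clipping at 0)
validates the H2 predictions in the small-noise regime (σ=1 for the
default circuit scale): all predictions fall inside 95% bootstrap CIs for
gains 0–100 and both motifs.  At large σ (e.g. 50 on a circuit with
x̄=10) the ramp saturates — `g` cannot exceed `1+α` or go below 0 — and
the true variance at high gain sits well above the linear prediction;
the figure-style experiment reports this regime as-is, and the
quantitative CI test is run where linearization is valid.

## Oracles

**FSP**: stationary distribution of the truncated CME as the null vector
of the truncated generator (sparse LU; the state space is enumerated with
the largest axis outermost so the bandwidth is the smaller axis).
Truncation reflects per dimension — a jump's out-of-box components are
clipped rather than the whole transition dropped, which matters for
coupled production at a boundary (dropping it entirely would strand the
chain in a corner).  The error indicator ε is the stationary mass on
boundary layers with outgoing flow; bounds auto-expand until ε ≤ 1e-8
(heavy-tailed cases, e.g. decoupled `k2=0`, accept 1e-6/1e-7 with explicit
bounds).  The ramp's cutoff is a hard support bound, so the x direction is
truncated exactly.

**SSA**: Gillespie's direct method, vectorized across runs (all runs
advance in lockstep draws).  Input regimes: fixed `ū`; one static
`u ~ Poisson(ū)` per run (cell-to-cell variability, production propensities
scaled by `f(u)/f(ū)`); or a birth–death input co-simulated as a third
species.  Ensemble moments of `y(t_final)` carry bootstrap SEs; per-run
time averages over the second half of each trajectory give stationary-path
statistics (the cv reported for dynamic inputs is the median across runs).
Default replicate counts are 4,000 (a tenth of the published scale), with
SEs quantifying the precision loss; `t_final` defaults to `20/min(l1,l2)`.

## Reproducibility

All generators take integer seeds (numpy `default_rng`); per-replicate
streams derive deterministically from the master seed.  Experiment runs
write a JSON manifest (config, seed, package version) next to their CSV
tables, and re-running a config is byte-identical.

## Known limitations

* Ramp-exactness arguments do not extend to Hill inhibition; Hill circuits
  are handled numerically (FSP/ODE) only.
* The closure is second-order derivative matching; no higher-order
  closures, bursty production, or stoichiometric consumption of the proxy.
* Stationary analysis only (time-dependent moments appear solely through
  the simulation oracles).
* Two regulated species at most; no general network topologies.
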