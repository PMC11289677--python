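# Methods

## Model and assumptions

The cell is a perfectly absorbing sphere of radius *a* moving at
constant speed *v*; the chemoattractant source is a fixed point
releasing cue molecules at Poissonian rate *α*; cues diffuse with
diffusivity *D*, never decay, and are removed on contact with the cell.
The cell carries no memory and reorients instantaneously along the
incidence direction of the most recently absorbed cue.  The cell itself
experiences no translational or rotational diffusion, and reorientation
takes zero time.  Imperfect reception is not a separate parameter: a
cell that responds to a fraction *f* of arrivals is modelled by
rescaling α → f·α.

All lengths, times and rates are carried in the user's units; nothing
is nondimensionalised internally.  The two derived quantities are
ε = αa/v (release rate over the inverse time to travel one radius) and
the homing radius r_h = aε.

## Closed forms

The steady-state cue density is the method-of-images solution around
the absorbing sphere: a free point source plus an image source of
strength −αa/r_s at distance a²/r_s from the cell centre.  Everything
else is derived from it analytically; the only piece that required
fresh derivation is the cumulative hazard of the run-duration law.
Along a straight run that starts at distance r_s at polar angle φ from
the source direction, the arrival rate is αa/dist(t), and its integral
has the closed form (c = cos φ, s = sin φ)

    Λ(Δt) = ε [ asinh((vΔt − r_s c)/(r_s s)) + asinh(c/s) ],

with logarithmic limits ε·ln(1 + vΔt/r_s) at φ = π and
−ε·ln(1 − vΔt/r_s) at φ = 0.  Λ is inverted in closed form
(Δt = (r_s/v)[c + s·sinh(Λ/ε − asinh(c/s))]), so run-duration sampling
is exact inverse-transform sampling, not root finding.  The closed form
is validated against adaptive quadrature of the rate (agreement ~1e−13)
and the sampler against the implied distribution by Kolmogorov–Smirnov
tests.

Sign conventions: the mean per-run radial displacement is
Δr̄ = (r_s − aε)/(ε²−1) — *negative* means net approach.  This sign was
fixed by a Monte-Carlo oracle (2×10⁶ sampled runs) and is the one
consistent with CI = −Δr̄/(vΔt̄) being positive inside the homing
radius.  `veff_finite` is computed literally as −Δr̄/Δt̄ so the identity
holds exactly, not merely to rounding.

Degenerate angles: for sin φ < 1e−12 the logarithmic limits replace the
arcsinh form (avoids 0/0).  For ε ≤ 1 the mean-run formulas raise
`DivergentStatisticsError` rather than returning non-finite values;
individual runs remain well defined and the simulators still work,
guarded by `max_time`.

## Event-driven simulator

A trajectory is a chain of (φ, Δt) draws.  The analytic run law never
terminates a run, so two truncations are imposed by the simulator:

* **source capture** — when r_s·sinφ ≤ a with cosφ > 0, the straight
  run's distance dips to a at
  t_hit = [r_s cosφ − √(a² − r_s² sin²φ)]/v; if t_hit precedes the
  sampled duration, the run stops there and the trajectory succeeds;
* **outer cut-off** — a run crossing R_c stops there and the cell is
  deemed lost (mirrors the particle protocol).

How the original numerics handled mid-run crossings is not documented
anywhere we could check; truncation is this package's choice and is
flagged per event in the output (`terminated` column).  Seeding: a
master `SeedSequence` spawns one child stream per trajectory, so
ensembles are reproducible and trials independent.  Within-run
positions are evaluated exactly from the run geometry at requested
times; ensemble mean curves have no interpolation error.

## Brownian-particle simulator

Lab frame, source at the origin.  Per step dt: Poisson(α·dt) births at
the origin, isotropic Gaussian displacement with per-axis variance
2D·dt, end-of-step overlap absorption at the cell (contact point =
segment–sphere intersection, falling back to radial projection),
removal at |x| ≥ R_c, then the cell moves v·dt along its current
direction (absorb-then-move; ties among multiple absorptions in one
step are broken uniformly at random and logged).  No Brownian-bridge
correction is applied in this synchronous sweep; the discretisation
bias is O(√(2D·dt)) and the step rule √(2D·dt) ≤ a/10 is enforced.
The default cut-off is 10× the largest length scale; note that a finite
absorbing shell depresses the stationary capture rate by a factor
≈ (1 − r_s/R_c), which is visible when comparing against αa/r_s with a
small R_c (the D-independence comparison is unaffected because the
truncation bias does not depend on D).

Burn-in equilibrates the cue field around a stationary absorbing cell:
under the default `flux_converged` policy it runs until two consecutive
~100-event blocks measure an absorption rate within 10% of αa/r₀, with
a hard fallback at 1.5·R_c²/D (~the diffusive relaxation time of the
domain); non-convergence warns and proceeds.

For stationary-cell flux measurements the synchronous sweep is
needlessly expensive, so `stationary_capture` follows each released cue
independently with per-particle adaptive steps
σ = clip(0.25·(d − a), a/50, ∞) that shrink near the absorbing surface,
plus the flat-wall bridge-crossing probability exp(−2h₀h₁/σ²) for
mid-step crossings.  Step sizes only rescale time, which the capture
probability does not depend on, so the scheme is exact in distribution
for hit probabilities and contact points up to the O(σ_min) wall
discretisation; with R_c = 100·r_s the measured rate lands within ~2%
of αa/r_s at r_s/a up to 20 (tested).  The absorption *rate* is α times
the capture probability, because releases are Poissonian and fates are
independent.

## Estimators

* Mean-distance curves: default censoring **hold** (terminated
  trajectories parked at their terminal distance, ensemble size
  constant — the interpretation that keeps a 1000-trajectory mean well
  defined at all times); **drop** (average over still-running
  trajectories, report n_alive) is also emitted.  Both agree before the
  first termination, which is tested.  Standard errors by
  nonparametric bootstrap over trajectories (200 resamples by default)
  — needed because the closed forms are tested against Monte-Carlo
  output and the Monte-Carlo error must be quantified.
* Empirical chemotactic index: −mean(Δr)/(v·mean(Δt)) over first runs
  with a delta-method standard error including the covariance of the
  two means.
* Homing-radius estimation: bisection on the sign of the empirical mean
  first-run displacement.  Near r_h the mean is statistically
  indistinguishable from zero, so bisection stops at the resolution
  limit z·SE/slope (slope estimated from the bracket endpoints) and the
  returned interval has at least that half-width; the width therefore
  shrinks as 1/√n, which is tested.

## Numerical choices

* Divergence-threshold location (the ε = 1 boundary): the truncated
  expectation of the run duration is integrated by Gauss–Legendre
  quadrature (128 angle nodes × 64 log-spaced time nodes per panel)
  over geometric truncation panels T_k = (r_s/v)·10^k, k ≤ 7.  The
  panel-increment ratio tends to 10^(1−ε), so an ε is classified
  divergent when the last ratio exceeds 1; the boundary is bisected to
  width 0.01.  The O(r_s/(vT)) pre-asymptotic corrections at the last
  panel (~1e−6) are far below the bisection width.
* Tail-exponent recovery fits the empirical survival of φ = π run
  durations in the shifted variable 1 + vΔt/r_s, in which the Lomax law
  is an exact power law; fitting raw Δt instead would need several more
  decades of data to escape pre-asymptotic curvature at large ε.
* Trajectory CSVs serialise floats with 17 significant digits and are
  read back with pandas' round-trip parser, so write∘read is the
  identity on IEEE doubles.

## Problem sizes in the test suite

Closed-form identities are checked to 1e−9–1e−12; Monte-Carlo
comparisons use 3-standard-error bands.  First-run statistics use 10⁵–10⁶
vectorised draws.  The deterministic-limit check uses 200 trajectories
at ε = 1000 started at r₀ = 5a (the ensemble-mean curve then tracks the
smooth-field trajectory to better than 1% down to 2a; single
trajectories disperse ~√(2r₀³/9aε) and are not a fair comparison).
Particle-simulation cross-checks use 40–60 moving-cell trials at ε = 10,
r₀ = 2a, D/(av) = 10, and 4–12×10⁴ released particles per stationary
flux point.

## What the simulators do and do not emulate

The event-driven simulator *is* the quasistatic theory with capture and
cut-off added; agreement with the closed forms validates the sampling
machinery, not the quasistatic assumption itself.  The particle
simulator is the model without the quasistatic assumption and validates
it at D/(av) = 10.  Neither includes cell diffusion, finite
reorientation time, cue decay, or the depleted "shadow" a moving cell
leaves when D/(av) is not large — so passing tests say nothing about
chemotaxis outside the quasistatic, non-decaying, memoryless regime.
Real cells also violate the perfect-absorber idealisation; only the
α-rescaling hook is provided.

## Known limitations

* Mean-curve predictions from the per-run effective velocity describe
  the fixed-time ensemble mean only over a few mean run durations (and
  poorly for small ε, where in-progress heavy-tailed runs dominate the
  fixed-time average); this is a property of the theory, not of the
  implementation, and the tests probe the slope in the regime where the
  correspondence holds (ε = 100).
* The particle simulator's synchronous sweep is O(population × steps)
  and is practical only for desk-scale parameter sets; the adaptive
  capture mode exists precisely because stationary-flux validation at
  r_s = 20a would otherwise be prohibitive.
* `stationary_capture` treats released cues independently, which is
  exact for a stationary cell but cannot be used once the cell moves
  (the moving absorber couples particle fates through its trajectory).
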