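# Methods

## Model

A two-stage, two-arm group sequential trial with a binary endpoint and early
stopping for efficacy only. The effect is the difference in success
proportions, `θ = p_T − p_C`. At analysis `k ∈ {1, 2}` the standardized Wald
statistic is `Z_k = θ̂_k √I_k`, where `θ̂_k` is the cumulative MLE and `I_k`
the statistical information. Asymptotically `(Z_1, Z_2)` follows the
canonical joint distribution: bivariate normal, means `(θ√I1, θ√I2)`, unit
variances, correlation `ρ = √(I1/I2)`. The trial stops at the interim iff
`Z_1 ≥ e`. Every estimator in the package is a function of the sufficient
summary `(I1, I2, z1, z2, θ̂1, θ̂_obs, e)` (the `TrialInformation`
container), so endpoints other than binary can be used by supplying the
informations directly.

### Information convention

For the binary endpoint the package uses pooled-variance (score-test)
information,

    I = [ p̄(1−p̄)(1/n_C + 1/n_T) ]⁻¹ ,

with `p̄` the pooled success proportion at that analysis. This is the unique
standard convention under which the bundled trial's counts reproduce its
reported standardized statistics (2.540 and 2.718; the unpooled variance
gives 2.598 at the interim). Estimation conditions on the *observed*
information fraction (0.795 here), which is deliberately decoupled from the
planned fraction (0.5) used to set the boundary.

### Boundaries

O'Brien–Fleming z-scale boundaries `e_k = C(K, α)√(K/k)`. `C` is found by a
bracketed Brent solve on `[0.5, 6]` so the overall crossing probability under
`θ = 0` equals `α` (tolerance well below 1e-8). That crossing probability is
computed with the classical continuation-density recursion on the score
scale, propagated by a 600-node Gauss–Legendre rule — deterministic, accurate
to ~1e-10, valid for any number of stages (estimators themselves are
two-stage, matching their closed forms). The bundled trial's design is the
two-stage one-sided `α = 0.025` case: `C = 1.9774`, boundaries
(2.7965, 1.9774). Estimation uses the full-precision interim boundary; the
3-dp display value 2.797 changes only the MUE, and only in its 4th decimal.

## Estimators

Replicates/trials that stop at stage 1 report the stage-1 MLE for every
unconditional estimator (definitionally for the MLE, MUE and UMVUE; by
convention for the UBC-MLE, whose correction would need the unobserved `I2`).
After continuation:

* **Marginal bias and UBC-MLE.** `bias(θ) = ((I2−I1)/(I2√I1))·φ(e−θ√I1)`.
  The UBC-MLE solves `θ = θ̂_obs − bias(θ)`; because `|bias′| < 1` the
  fixed-point equation has a unique root, bracketed within
  `[θ̂_obs − φ(0)·(I2−I1)/(I2√I1), θ̂_obs]`.
* **UMVUE.** Conditional on `(T=2, θ̂_obs)` the stage-1 MLE is normal with
  mean `θ̂_obs`, SD `σ_c = √(1/I1 − 1/I2)`, truncated above at `e/√I1`; the
  UMVUE is that truncated mean, `θ̂_obs − σ_c·φ(a)/Φ(a)` with
  `a = (e/√I1 − θ̂_obs)/σ_c`.
* **MUE.** Stagewise ordering ranks stage-1 rejections as more extreme than
  any stage-2 outcome, so
  `P(θ) = Pr_θ(Z1 ≥ e) + Pr_θ(Z1 < e, Z2 ≥ z2)`, which collapses to
  `1 − Φ₂(e−θ√I1, z2−θ√I2; ρ)`. `P` is strictly increasing; the MUE is the
  root of `P(θ) = ½`. (The stage-1 term is essential: without it the
  equation has no root near the data.)
* **Conditional bias and CBC-MLE.** `−(√I1/I2)·φ(d)/Φ(d)`, `d = e−θ√I1`,
  always negative; the CBC-MLE solves its fixed-point equation, with an
  upper bracket grown geometrically until the sign change (the derivative
  bound `|d bias/dθ| ≤ I1/I2 < 1` again gives uniqueness).
* **UMVCUE.** From the information decomposition
  `θ̂_obs = (I1 θ̂1 + (I2−I1) θ̂2)/I2`,
  `E[θ̂2 | T=2, θ̂_obs] = (I2 θ̂_obs − I1 m)/(I2−I1)` with `m` the UMVUE's
  truncated mean; the identity `I1·UMVUE + (I2−I1)·UMVCUE = I2·θ̂_obs` holds
  to machine precision and is asserted in tests.
* **CMUE.** The conditional law of `θ̂_obs` given continuation has density
  `√I2·φ(v)·Φ((d−ρv)/√(1−ρ²))/Φ(d)` (`v = (m−θ)√I2`) and CDF
  `Φ₂((m−θ)√I2, d; ρ)/Φ(d)` — a closed bivariate-normal reduction whose
  normalization and shape are checked against quadrature and a Monte-Carlo
  oracle. The CMUE solves `CDF(θ̂_obs; θ) = ½`; the CDF is strictly
  decreasing in `θ` (stochastic ordering), so the root is unique.

On real binary data the stage-2 MLE is computed from the incremental
post-interim counts (0.1139 for the bundled trial); the information-weighted
decomposition gives a slightly different value (0.1113) because the pooled
variance is re-estimated at each analysis. Both paths are exposed; the
canonical (simulation) scale uses the decomposition, where the two coincide
by construction.

## Numerics

* All `φ/Φ` quotients (Mills ratios) are evaluated through `erfcx`, so they
  are exact and stable arbitrarily deep into either tail; no asymptotic
  switchover is needed.
* The bivariate normal CDF is the conditioning integral
  `∫^a φ(v)Φ((b−ρv)/√(1−ρ²)) dv` on a fixed 96-node Gauss–Legendre rule over
  `[−9, a]` (error ≲ 5e-15 against scipy's implementation), chosen over a
  library call because per-replicate root-finding needs it broadcast across
  10⁵-element arrays.
* Root solves for the MUE, CMUE and both bias corrections use vectorized
  bisection (60 halvings of an O(1) bracket → machine precision), with
  geometric bracket widening and explicit failure if no sign change is found.
* Saturation: beyond `|z| ≈ 9` normal tail probabilities are exact 0/1 in
  floats; strict-monotonicity checks therefore apply on the non-saturated
  range, and degenerate inputs (zero or unit pooled proportions, equal
  informations, non-monotone cumulative counts) raise explicit errors.

## Simulator

`simulate_replicates` draws `(Z1, Z2)` directly from the canonical joint
distribution at a chosen true effect and applies the efficacy rule — it
emulates the *asymptotic* behaviour of the trial statistics, not the
finite-sample binomial data: no per-replicate variance re-estimation, no
discreteness, no overdispersion, and information treated as fixed at its
observed value. Passing tests therefore validate the estimator theory on the
canonical scale; they do not certify finite-sample binomial behaviour, where
the normal approximation itself is the residual assumption. Parametric
bootstrap SEs are the replicate SDs at an assumed effect (unconditional
estimators over all replicates; conditional estimators over continuing ones,
whose SEs are correspondingly larger). The default test/analysis profile is
10⁴ replicates per effect (MC error on estimator means ≈ 0.0005–0.001,
comfortably resolving the corrections being studied); 10⁵ replicates
reproduce the published SE column and remain minutes-scale.

Known reproduction boundary: at 5×10⁴–10⁵ replicates every published
simulation summary is matched within Monte-Carlo error *except* the CMUE
summary row at the two smaller effects, where the converged mean/SD sit a few
thousandths below the published ones. The package's CMUE exactly reproduces
the published point estimate, passes the density normalization and
Kolmogorov–Smirnov oracles, and satisfies the defining conditional-median
property `Pr(CMUE < θ | T=2) = ½` in simulation; alternative plausible CMUE
definitions reproduce neither the point estimate nor the summaries, so the
difference is attributed to the reference simulation code (not available)
rather than the estimator definition, and the corresponding acceptance test
is left failing rather than loosened.

## Design choices that were genuinely open

* **Figure-style normal-outcome scenarios** use `I = n_per_arm/(2σ²)` with
  equal allocation; the stated 80%-power pairings (total N 620/100/40
  detecting effects 0.2/0.5/0.8 at one-sided α = 0.05) pin this convention
  down and are asserted as a sanity check.
* **Profiles are data, not plots**: the four bias/stopping curves are
  returned as arrays (and CSV via the CLI); rendering is left to the caller.
* **Strict configuration**: unknown design-config keys are rejected, since a
  silently ignored boundary option is a safety problem in this domain.
* **Peak-bias ordering**: the marginal bias curves of different sample sizes
  cross pointwise (each peaks where the boundary sits on its own effect
  scale), so "smaller trials are more biased" is asserted as an ordering of
  curve maxima.

## Limitations

Two-stage efficacy-only stopping for the estimator suite (boundary solving
itself handles any K); no futility boundaries, no confidence intervals, no
sample-size re-estimation, single ordering (stagewise) for the MUE, and the
canonical-scale caveats above.
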