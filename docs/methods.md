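# Methods

This note records the model, its assumptions, the numerical choices, and
the places where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model

### Observation model

Detection/non-detection lists are aggregated per site-year: `J` visits,
`d` visits with a detection. Detection is abundance-induced: with
per-individual detection probability `r`, a site holding `N` birds yields a
detection on a visit with probability `p = 1 − (1−r)^N`. Latent abundance
is negative binomial with year mean `μ_t` and shape `ψ` (variance
`μ + μ²/ψ`; large `ψ` approaches Poisson). The site-year likelihood is the
finite mixture over `k = 0..K`:

    L(d) = Σ_k Binomial(d | J, 1−(1−r)^k) · NegBin(k | μ_t, ψ)

Site-years are conditionally independent given the annual means; there is
no spatial or per-visit temporal structure.

**Truncation K.** Default `K = 10` (configurable; `K = 5` supported),
reflecting a realistic upper bound on birds per pentad for a rare harrier.
The truncation error of the log-likelihood decays rapidly in `K` (about
`3·10⁻⁵` at `d=0, J=5` for `K=10` under the estimated parameters, below
`10⁻⁹` by `K=40`; see `tests/test_likelihood.py`). One caveat matters for
simulation studies: when data are *generated* from an unbounded negative
binomial, fitting with `K = 10` censors the informative high-abundance tail
and biases `r` upward with `ψ` compensating. Parameter-recovery experiments
therefore fit with `K = 40`, which covers the simulated abundance support;
for field data the bound is a statement about the species and `K = 10` is
appropriate.

### Demographic coupling

Stages: fledgling (year 0), sub-adult (year 1), adult (2+); only adults
breed. The transition matrix (README) has identical sub-adult and adult
columns, so removing birds from either class perturbs the projection
identically — a structural property we preserve exactly (see Viability).
Fecundity `ρ_t = 1.5·logit⁻¹(β₀ + β₁·rain_t + γ_t)` uses the standardized
annual rainfall covariate (mean 0, sd 1 across study years, sample sd with
n−1) and an annual random effect `γ_t ~ Normal(0, σ_γ)`. The 1.5 ceiling
encodes a maximum of three offspring per pair. Survival is constant over
time; `φ₂ = exp(−h)` with `h` the constant annual hazard informed by
telemetry (deaths are events, survivors censoring, exposure in bird-years =
days/365); `φ₁ = φ₂·u, u ∈ (0,1)` enforces lower first-year survival.

**Coupling of μ to the stage structure.** The scalar mean abundance grows
by `λ_t`, the one-step total growth of the stage-structured population. We
track a normalized stage-distribution vector `s_t`, starting at the stable
stage distribution of the average-conditions matrix:
`λ_t = sum(A_t s_t)`, `s_{t+1} = A_t s_t / λ_t`. This is the minimal
coupling consistent with the projection model and carries transient stage
structure between years. A `method="eigenvalue"` option uses each year's
dominant eigenvalue instead (no transients); under constant conditions the
two coincide, since the closed-form dominant eigenvalue is
`λ = (φ₂ + √(φ₂² + 4ρφ₂φ₁))/2`.

### Inference

Joint posterior over `(r, μ₀, ψ, h, u, β₀, β₁, σ_γ, γ_{1..T−1})`. Priors
(weakly informative defaults, documented rather than canonical):
`r ~ Beta(1,1)`, `μ₀ ~ HalfNormal(5)`, `ψ ~ HalfNormal(5)`,
`h ~ HalfNormal(2)`, `u ~ Beta(1,1)`, `β ~ Normal(0, 1.5)`,
`σ_γ ~ HalfNormal(1)`, `γ` non-centered (`γ_t = σ_γ z_t, z_t ~ N(0,1)`),
which keeps the `σ_γ → 0` funnel tractable.

Sampling uses an affine-invariant ensemble (emcee) with an 80/20 mixture of
differential-evolution and snooker moves — markedly better than stretch
moves on this posterior's curved `(r, μ₀, ψ)` ridge. Walkers start in a
small ball around an approximate posterior mode found by Nelder–Mead over
the eight structural parameters with the random-effect innovations pinned
at zero (the full MAP of a hierarchical model overfits the random effects).
Each walker is treated as a chain for split-R̂ and ESS (ArviZ); a fit is
flagged unconverged if any R̂ > 1.01, a deliberately strict bar that short
ensemble runs will trip even when posterior moments are stable. Defaults
mirror a 4-chain, 2000-iteration, 1000-warmup regime.

**Identifiability.** The `(r, μ₀, ψ)` ridge is intrinsically flat for a
rare species: profile log-likelihood differences of a few nats persist even
at 2·10⁵ site-years across ~±20% parameter shifts (the data pin the product
`r·μ` much better than the factors). Posterior standard deviations, not
point estimates, carry this information; recovery checks are therefore
posed in posterior-sd units. The random-effect scale `σ_γ` absorbs
finite-site sampling fluctuations of the realized yearly mean abundance and
is only weakly informed at T ≈ 12 years.

### Posterior predictive check

For each posterior draw and year, latent abundances and detections are
re-simulated at the observed visit effort; the statistic is the fraction of
pentads with at least one detection. Per-year central predictive intervals
are compared with the observed fractions.

## Viability simulation

Per trajectory: draw one parameter set; start `N₀ = initial_population ×`
stable stage distribution of that draw's average-conditions matrix (default
initial population: pentads-with-detections × drawn mean per-pentad
abundance); each year draw a rainfall covariate (resampled from a supplied
pool, or standard normal — matching the covariate's standardization) and a
fresh `γ_t`; project; subtract the scenario's removals. Projection is
deterministic given parameters — no demographic stochasticity — so with
zero removals and threshold 0 extinction probability is exactly 0.

**Removal accounting.** Removals are subtracted linearly from the chosen
stage and a trajectory is extinct — clamped to 0, absorbing — when its
*total* falls to or below the quasi-extinction threshold (default 0,
configurable, e.g. one bird). We deliberately do not floor the removed
stage at zero mid-trajectory: a hard floor would (a) make extinction
unreachable under adult-only removals with a continuous projection (other
stages stay positive forever), and (b) break the exact equivalence of
sub-adult and adult removals, which is a structural property of the life
cycle (identical matrix columns). Internally the dynamics are propagated as
(fledglings, breeder pool), so a breeder-stage removal is subtracted from
the pooled sum and sub-adult and adult removals are bit-for-bit identical.
Populations are kept continuous (no integer rounding); both the threshold
and rounding were open choices, and continuous-with-threshold-0 is the
configuration-free default.

Scenario ensembles seed each trajectory as `(scenario seed, trajectory
index)`, so scenarios sharing a seed see identical parameter draws and
rainfall sequences ("matched seeds"); differences between removal levels
are then purely treatment effects, and the extinction curve is monotone in
the removal level by construction of the comparison.

**Marginal-approximation caveat.** When only published marginal posterior
summaries are available, parameters are drawn as independent truncated
normals (survival to (0,1), `φ₁` capped below the drawn `φ₂`, positive
parameters to (0,∞)). This loses posterior correlations and widens the
draw-level spread of the long-run growth rate; extinction-vs-removals
curves computed this way are flatter (higher risk at small removals, lower
at large) than a joint-posterior computation would give. Elasticities and
the mean growth rate are far less sensitive to this approximation.

## Elasticities

Entrywise eigenvalue elasticities `e_ij = (a_ij/λ) v_i w_j/(v·w)` with `w`,
`v` the right/left dominant eigenvectors; they sum to 1. Stage-level values
group entries by the transition they represent — reproduction row →
fecundity, `a₂₁` → fledgling survival, third-row entries → adult/sub-adult
survival — so the three groups partition the total. Because a breeder must
survive the year to produce a brood, the reproduction entries also contain
`φ₂` algebraically; the raw-parameter elasticity to `φ₂` (the stage value
plus the fecundity group) is exposed as `phi2_total`. The life cycle
implies `e₂₁ = e₁₂ + e₁₃` (one reproductive loop), i.e. fledgling-survival
and fecundity elasticities are identical draw by draw. Posterior summaries
evaluate each draw's matrix at average rainfall, optionally with a drawn
annual effect (used when mimicking the matrices realized during
simulation).

## Synthetic data

The generator mirrors the fitted model exactly (unbounded negative-binomial
abundance, binomial detections, standard-normal rainfall covariates,
exponential survival with end-of-tracking censoring) with two deliberate
realism choices: visits per site-year follow a zero-truncated negative
binomial whose defaults give a right-skewed effort distribution (mean ≈ 6,
median ≈ 2–3), and the default scale is 250 sites × 12 years, matching a
filtered national-atlas analysis for this species. It does not emulate
observer heterogeneity, site covariates, spatial structure, or movement
between sites — the model has none — so passing recovery tests demonstrate
internal consistency of the estimator, not robustness to those real-data
features.

## Problem sizes used in the checks

Closed-form checks are instant. Sampling-based summaries use 10⁴–10⁵
draws; extinction scenarios use 1000 trajectories × 100 years (Monte-Carlo
se ≈ 0.016 at p = 0.5). The parameter-recovery check runs one replicate at
250 sites × 12 years with a 128-walker, 2500-step ensemble and asserts
recovery of `r, μ₀, ψ, φ₂` within 3 posterior sd; the fuller 20-replicate
95%-interval coverage experiment uses the same API at twenty seeds.

## Known limitations

- No density dependence, senescence, sex structure, or spatial variation in
  vital rates; constant-per-year removals imply no behavioural response.
- Ensemble MCMC mixes slowly along the `(r, μ₀, ψ)` ridge; R̂ ≤ 1.01
  requires long runs. A gradient-based sampler would be preferable if
  available.
- Posterior-summary-driven viability analyses inherit the independence
  approximation described above.
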