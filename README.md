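# harrierpva

Integrated population viability analysis for the Black Harrier (*Circus
maurus*) — and, more generally, for rare species whose only long-term
population signal is citizen-science detection/non-detection data.

The Black Harrier is an endangered, range-restricted raptor of southern
Africa with no systematic count programme. This package infers its
population size, trend and vital rates jointly from three weak data sources
— atlas checklists (detections per visits, per pentad and year), a handful
of telemetry survival records, and an annual rainfall covariate — and then
projects the population forward under constant additional mortality (for
example turbine collisions at wind farms) to estimate extinction risk.

## The model

**Abundance from detection/non-detection.** If `r` is the probability of
detecting one individual on one visit, a site holding `N` birds is detected
with probability `p = 1 − (1−r)^N` (a Royle–Nichols model). Site abundance
in year `t` is negative binomial with mean `μ_t` and over-dispersion `ψ`
(variance `μ + μ²/ψ`), and the likelihood of `d` detections in `J` visits
marginalizes the latent count up to a bound `K`:

    L(d) = Σ_{k=0..K} Binomial(d | J, 1−(1−r)^k) · NegBin(k | μ_t, ψ)

**Demographic coupling.** Mean abundance evolves as `μ_{t+1} = λ_t μ_t`,
with `λ_t` generated by a three-stage life cycle (fledgling, sub-adult,
adult; only adults breed):

    A_t = [ 0      ρ_t φ₂   ρ_t φ₂ ]
          [ φ₁     0        0      ]
          [ 0      φ₂       φ₂     ]

Fecundity is rainfall-driven on the logit scale, bounded by 1.5 offspring
per adult (three per pair): `ρ_t = 1.5·logit⁻¹(β₀ + β₁·rain_t + γ_t)`,
`γ_t ~ Normal(0, σ_γ)`. Adult survival `φ₂ = exp(−h)` is informed by an
exponential survival model fitted to telemetry exposure; fledgling survival
is constrained `φ₁ < φ₂`. All parameters are estimated jointly by MCMC
(ensemble sampler with differential-evolution moves, R̂/ESS diagnostics via
ArviZ).

**Viability scenarios.** Monte-Carlo trajectories draw parameters from the
posterior (or from truncated-normal approximations of published posterior
summaries), resample rainfall every year, project the stage vector, and
subtract a fixed number of birds from a chosen stage each year. Extinction
probability is the fraction of trajectories whose total reaches zero.
Growth-rate elasticities identify the life-history stage that matters most.

## Worked example

```bash
python examples/elasticity_analysis.py
```

```
fecundity at average rainfall: 0.784 fledglings per adult per year
annual growth rate lambda:     0.985

posterior elasticities (mean +- sd over 10000 draws):
  adult survival       0.569 +- 0.069
  fledgling survival   0.216 +- 0.034
  fecundity            0.216 +- 0.034
```

At the published posterior means the population declines a little over 1%
per year (λ = 0.985 at average rainfall; averaging over parameter and
rainfall uncertainty gives ≈ 0.977), and λ is more than twice as sensitive
to adult survival as to fecundity or fledgling survival — mortality of
adult birds is the worst-case impact.

```bash
python examples/extinction_scenarios.py
```

```
removals/yr   P(extinct <=25y)  P(<=50y)  P(<=75y)  P(<=100y)
         0      0.000     0.000     0.000     0.000
         1      0.007     0.192     0.357     0.454
         3      0.043     0.306     0.460     0.529
         5      0.080     0.380     0.514     0.579
```

With no additional mortality the (deterministic-projection) population
never reaches zero within a century; each additional adult removed per year
raises the 100-year extinction probability substantially. Removing
sub-adults is exactly as harmful as removing adults; removing fledglings is
less so. See `docs/methods.md` for why these probabilities — computed from
independent marginal approximations of the posterior — are flatter across
removal levels than a joint-posterior computation would give.

Other examples: `examples/generate_dataset.py` (write synthetic CSVs),
`examples/fit_model.py` (fit the joint model and run a posterior predictive
check).

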