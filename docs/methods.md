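# Model and methods

## The model

`pggsim` simulates a community of two behavioural phenotypes — selfish
risk-seekers (S) and generous risk-averse agents (G) — that harvest a
common resource, play a public goods game, reproduce in proportion to
fitness and pass on mutating reproduction probabilities, over
non-overlapping generations. The population size is endogenous: it is
set entirely by how many offspring the resource economy supports, and
extinction (an empty cohort) is absorbing.

A generation proceeds as:

1. **Mutation** of every agent's heritable traits (ϕ, γ, ω) — equivalent
   to offspring inheriting their parent's traits and mutating before
   they reproduce themselves.
2. **Harvesting with mortality.** Each selfish agent independently dies
   with probability `m_S` (generous agents bear no risk, `m_G = 0`).
   Each survivor of phenotype *p* harvests `min(h_p · e_t, e_max)`,
   where `e_t = e_tot / N_t`.
3. **Public goods game.** Participants contribute a phenotype-specific
   fraction of their harvest; the pot loses `lam/100` resource units
   per selfish participant (the community cost), floored at zero, then
   is multiplied by ρ and shared equally. Fitness = share + retained
   harvest − individual cost (selfish agents, variant only).
4. **Reproduction.** Offspring counts are a capped, thresholded ceiling
   function of fitness; offspring phenotypes are independent draws from
   the parent's 2×2 transmission matrix built from (ϕ, γ, ω). Parents
   die; offspring form the next cohort.

## Parameters

| Parameter | Meaning | Default |
|---|---|---|
| `N0` | initial population size | 250 |
| `T` | generations | 10 000 |
| `e` | environmental offer per initial agent (resource units) | 4.5 abundant / 1.2 scarce |
| `e_tot` | total offer per generation, fixed at `e·N0` for the whole run | 1125 |
| `e_max` | per-agent harvest cap (units) | 4.5 |
| `rho` | pot multiplier | 1.5 |
| `lam` | community cost level (%), units removed per selfish participant | 0 / 50 / 100 |
| `S0` | initial selfish fraction | 0.10 |
| `h_S`, `h_G` | harvest fractions of the per-capita share | 0.8, 0.5 |
| `c_S` | selfish contribution fraction (generous agents: 1, or conditional) | 0.2 |
| `m_S` | selfish harvesting mortality | 0.25 (0 / 0.25 / 0.5 studied) |
| `o`, `s` | max offspring; survival threshold (units) | 10, 1 |
| `M` | fitness giving `o` offspring, derived `s·o + s` | 11 |
| `phi0`, `gamma0`, `omega0` | initial trait values | 0.1, 0.01, 0.01 |
| `sigma2_*` | mutation variances | 0.01 each |
| `alpha` | individual cost for selfish agents (variant) | 0.1 |

`m_S` defaults to 0.25 because that is the canonical surviving baseline
scenario; the zero- and high-mortality settings are sweep values.
At the initial trait values a generous parent produces a generous
offspring with probability `1 − ϕ + ω = 0.91` and a selfish parent a
selfish offspring with probability `ϕ + γ = 0.11`.

## Conventions the description leaves open

Several mechanistic details are fixed here as package conventions:

* **Mortality before harvest; pre-mortality share.** Mortality draws
  precede harvesting, and the share `e_t = e_tot / N_t` uses the
  head-count at the start of the generation. Agents who die harvest
  nothing, contribute nothing and leave no offspring.
* **Cap on the realized harvest**: `min(h_p e_t, e_max)`, not
  `h_p · min(e_t, e_max)`.
* **Community cost form**: `lam/100` resource units per selfish
  *participant*, deducted from the pot before multiplication by ρ and
  floored at zero. This is dimensionally consistent with the survival
  threshold `s = 1` unit and reproduces the ordering "more community
  cost → smaller equilibrium population" (≈520 → ≈405 → ≈355 agents at
  λ = 0/50/100 in the abundant baseline).
* **Redistribution divisor** is the number of game participants
  (post-mortality), as is the averaging population for the
  conditional-cooperation rule: conditional cooperators copy the mean
  contribution rate of the previous generation's participants
  (contributing 100% in the founding generation).
* **Clipping order after mutation**: ϕ into [0, 1] first, then γ into
  [0, 1−ϕ] and ω into [0, ϕ] against the clipped ϕ; this keeps all
  four transmission probabilities in [0, 1]. Noise is drawn even when a
  variance is zero, so the random stream does not depend on variance
  values.
* **Offspring ceiling taken literally**: the mathematical ceiling of
  the exact floating value, no epsilon adjustment. Negative fitness is
  allowed and simply yields zero offspring.
* **Deterministic initial composition**: exactly `round(S0·N0)` selfish
  founders (25 of 250), removing initial-composition sampling variance.
* **Recorded observables** snapshot the cohort *as born* (pre-mutation
  trait means, pre-mortality composition); the pot, the generous
  contribution rate and the mean contribution are recorded for the
  generation in which they occur. A trajectory's final record snapshots
  the terminal cohort and carries no within-generation dynamics.

## Reproducibility

One `numpy` PCG64 stream per realization, with a fixed in-generation
draw order: mutation noise (ϕ, γ, ω vectors, agent order), mortality
uniforms (selfish agents, agent order), one offspring-phenotype uniform
per offspring in parent order. Ensemble realizations use children of a
single `SeedSequence`; sweep cells spawn one child per cell. A run
manifest (config, master seed, package version) therefore determines
every output byte-for-byte.

## Equilibrium statistics

Equilibrium values time-average each observable over the final 10% of
generations (configurable window) within each realization, then average
across realizations that survived to `T`; extinct realizations
contribute only to the extinction fraction and mean extinction
generation. Cross-realization means condition on survival, so ensemble
trajectory means continue past individual extinctions. A sweep cell is
classified extinct when every realization dies before `T`.

The equilibrium window is a package choice: the composition and
reproduction-rate trajectories plateau within the first ~1,000
generations in all surviving scenarios, so any late window is
representative; the tests and the acceptance script use 2,000-generation
horizons for reproduction-rate quantities and 10,000 for composition
and population-size quantities, with 20 realizations.

## A conservation bound on extinction

With zero community and individual costs the public goods game conserves
resources: total fitness paid out equals ρ·pot + total retained
harvest, which is at most `0.88 · e_tot` (the all-selfish limit of
`e_tot · [(1−g)·h_S(1−c_S+ρc_S) + g·ρc_G h_G]`, `g` the generous
fraction). Because the ceiling rule gives every agent with fitness above
the survival threshold at least one offspring, and `⌈f−s⌉ < f` for
`s = 1`, the next cohort is strictly smaller than total fitness, hence
`N_{t+1} < 0.88·e_tot = 990` in the abundant environment. But all
selfish agents share one fitness value, which is never below the
population mean, so simultaneous selfish starvation (`f_S ≤ s`) requires
`N_t ≥ 1125·(0.88 + 0.51g) ≥ 990` — unreachable. **Extinction is
therefore impossible at `m_S = 0, λ = 0`** in this implementation: the
population settles into overshoot-and-recovery oscillations (roughly
N ∈ [480, 930]) instead of dying out. Reported extinction of such
communities elsewhere is consequently not reproduced here; the
extinction scenario reports a censored mean extinction time equal to
the simulated horizon. Alternative offspring integerizations
(nearest-integer, floor) do produce that extinction but destroy several
other equilibrium regimes (conditional-cooperation survival, the
generous-majority flip, scarce-environment survival), so the ceiling
rule is retained.

## What the simulations do and do not show

The model's "data" are entirely synthetic: agents are identical within
phenotype, the environment is constant and well-mixed, and there is no
spatial or network structure, no overlapping generations, and no
within-generation harvesting order. Passing tests therefore validate
the internal dynamics of this stylized economy — not any claim about
empirical populations. Known limitations:

* the community-cost constant is a convention (see above); only its
  qualitative ordering is meaningful;
* equilibrium generous-parent effects (ω, hence φ_GG) plateau ~5–10
  percentage points above the published range (e.g. φ_GG ≈ 0.75 vs
  ~0.65 in the conditional-cooperation, high-mortality scenario), a
  sensitivity of the mutation–selection balance to unreported
  implementation details;
* extinction regimes that depend on overshoot beyond the resource
  budget are unreachable under the ceiling rule (see the conservation
  bound above);
* single-agent populations and other degenerate cases are handled
  (an agent receives its own multiplied contribution; empty populations
  raise `ExtinctPopulationError` and mark the trajectory extinct).
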