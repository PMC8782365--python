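"""The four lifecycle phases of one generation.

Order within a generation: mutation of the reproduction probabilities,
harvesting with mortality for selfish risk-seekers, the public goods game
with a community cost, and fitness-proportional reproduction through a
parental-influence phenotype matrix.  All phases are pure functions of
(arrays, config, rng); the engine composes them.

Conventions that the published description leaves open are fixed here and
documented in ``docs/methods.md``:

* mortality is drawn before any harvesting, and the per-capita offer
  ``e_t = e_tot / N_t`` uses the pre-mortality head-count;
* the harvest cap applies to the realized amount,
  ``min(h_p * e_t, e_max)``;
* the community cost removes ``lam/100`` resource units per selfish
  participant from the pot before multiplication by ``rho``, floored at
  zero;
* the redistribution divisor is the number of game participants
  (post-mortality), as is the mean contribution used by the
  conditional-cooperation rule;
* after mutation the components are clipped in the order: ``phi`` into
  [0, 1], then ``gamma`` into [0, 1 - phi], then ``omega`` into [0, phi].
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .config import ModelConfig
from .state import PopulationState

__all__ = [
    "ExtinctPopulationError",
    "HarvestOutcome",
    "PGGOutcome",
    "ReproductionMatrix",
    "contribution_rates",
    "draw_offspring",
    "generous_rate",
    "harvest_phase",
    "mutate_probabilities",
    "offspring_count",
    "offspring_counts",
    "public_goods_phase",
    "reproduction_matrix",
]


class ExtinctPopulationError(RuntimeError):
    """A phase was asked to act on an empty (extinct) population."""


# ---------------------------------------------------------------------------
# Harvesting with mortality
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HarvestOutcome:
    """Result of the harvesting phase, full-length over the cohort.

    ``alive`` marks agents that survived the mortality draw; dead agents
    have zero ``harvest`` and take no further part in the generation.
    """

    alive: np.ndarray    # bool, shape (N,)
    harvest: np.ndarray  # float, shape (N,); 0 for dead agents
    e_t: float           # per-capita environmental offer this generation


def harvest_phase(
    state: PopulationState, config: ModelConfig, rng: np.random.Generator
) -> HarvestOutcome:
    """Mortality draws for selfish agents, then capped harvesting.

    Each selfish agent independently perishes with probability ``m_S``
    before harvesting (generous agents are not at risk when ``m_G = 0``).
    Each survivor of phenotype ``p`` harvests ``min(h_p * e_t, e_max)``
    where ``e_t = e_tot / N_t`` and ``N_t`` counts the cohort alive at the
    start of the phase, before mortality.

    Mortality uniforms are drawn for the selfish agents in agent order
    (and for generous agents only if ``m_G > 0``); this is part of the
    reproducibility contract.
    """
    n = state.size
    if n == 0:
        raise ExtinctPopulationError("cannot harvest with an empty population")
    e_t = config.e_tot / n

    alive = np.ones(n, dtype=bool)
    if config.m_S > 0.0:
        idx = np.flatnonzero(state.selfish)
        if idx.size:
            alive[idx[rng.random(idx.size) < config.m_S]] = False
    if config.m_G > 0.0:
        idx = np.flatnonzero(~state.selfish)
        if idx.size:
            alive[idx[rng.random(idx.size) < config.m_G]] = False

    harvest = np.zeros(n)
    rate = np.where(state.selfish, config.h_S, config.h_G)
    harvest[alive] = np.minimum(rate[alive] * e_t, config.e_max)
    return HarvestOutcome(alive=alive, harvest=harvest, e_t=e_t)


# ---------------------------------------------------------------------------
# Contribution rates and the public goods game
# ---------------------------------------------------------------------------

def generous_rate(t: int, prev_mean_contribution: float | None, config: ModelConfig) -> float:
    """Contribution rate of generous agents at generation ``t``.

    Unconditional cooperators always contribute everything.  Conditional
    cooperators contribute everything in the founding generation and
    thereafter copy the mean contribution rate of the previous
    generation's game participants.
    """
    if not config.conditional_cooperation or t == 0:
        return 1.0
    if prev_mean_contribution is None:
        raise ValueError(
            "conditional cooperation at t >= 1 requires the previous "
            "generation's mean contribution rate"
        )
    return float(prev_mean_contribution)


def contribution_rates(state: PopulationState, config: ModelConfig) -> np.ndarray:
    """Per-agent contribution fractions for the whole cohort.

    Selfish agents always contribute ``c_S``; generous agents follow
    :func:`generous_rate`.
    """
    c_g = generous_rate(state.t, state.prev_mean_contribution, config)
    return np.where(state.selfish, config.c_S, c_g)


@dataclasses.dataclass
class PGGOutcome:
    """Fitness and pot of one public goods game over the participants."""

    fitness: np.ndarray  # float, per participant
    pot: float           # communal pot after the community cost, before *rho
    payout: float        # per-capita share, pot * rho / N


def public_goods_phase(
    harvests: np.ndarray,
    selfish: np.ndarray,
    rates: np.ndarray,
    config: ModelConfig,
) -> PGGOutcome:
    """Pool contributions, charge the community cost, redistribute.

    The pot collects ``c_i * r_i`` from each participant, then loses
    ``lam/100`` resource units per selfish participant (floored at zero),
    is multiplied by ``rho`` and shared equally among the ``N``
    participants.  Each agent's fitness is its share plus the resources it
    retained, ``r_i * (1 - c_i)``, minus the individual cost ``alpha`` for
    selfish agents when that variant is on.  Fitness may be negative; the
    offspring rule then yields zero offspring.
    """
    harvests = np.asarray(harvests, dtype=float)
    selfish = np.asarray(selfish, dtype=bool)
    rates = np.asarray(rates, dtype=float)
    n = harvests.size
    if n == 0:
        raise ExtinctPopulationError("public goods game requires at least one participant")

    contributed = rates * harvests
    pot = float(contributed.sum()) - (config.lam / 100.0) * float(selfish.sum())
    pot = max(pot, 0.0)
    payout = pot * config.rho / n
    fitness = payout + harvests * (1.0 - rates)
    alpha = config.effective_alpha
    if alpha:
        fitness = fitness - alpha * selfish
    return PGGOutcome(fitness=fitness, pot=pot, payout=payout)


# ---------------------------------------------------------------------------
# Reproduction
# ---------------------------------------------------------------------------

def offspring_counts(fitness: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Number of offspring per parent as a piecewise function of fitness.

    Zero at or below the survival threshold ``s``; the maximum ``o`` at or
    above ``M = s*o + s``; in between, ``ceil(o / (M - s) * (f - s))``.
    The ceiling is the exact mathematical ceiling of the floating value.
    """
    f = np.asarray(fitness, dtype=float)
    mid = np.ceil(config.o / (config.M - config.s) * (f - config.s))
    n = np.where(f <= config.s, 0.0, np.where(f >= config.M, float(config.o), mid))
    return n.astype(np.int64)


def offspring_count(fitness: float, config: ModelConfig) -> int:
    """Scalar convenience wrapper around :func:`offspring_counts`."""
    return int(offspring_counts(np.asarray([fitness]), config)[0])


@dataclasses.dataclass
class ReproductionMatrix:
    """Parent-phenotype → offspring-phenotype probabilities.

    Built from the heritable components: ``phi`` (baseline propensity to
    produce selfish offspring), ``gamma`` (selfish-parent effect) and
    ``omega`` (generous-parent effect).  Rows sum to one exactly by
    construction.  Entries may be scalars or aligned arrays.
    """

    phi_GG: np.ndarray | float  # generous parent -> generous offspring
    phi_GS: np.ndarray | float  # generous parent -> selfish offspring
    phi_SS: np.ndarray | float  # selfish parent -> selfish offspring
    phi_SG: np.ndarray | float  # selfish parent -> generous offspring


def reproduction_matrix(phi, gamma, omega) -> ReproductionMatrix:
    """Evaluate the parental-influence matrix at (phi, gamma, omega)."""
    return ReproductionMatrix(
        phi_GG=1.0 - phi + omega,
        phi_GS=phi - omega,
        phi_SS=phi + gamma,
        phi_SG=1.0 - phi - gamma,
    )


def draw_offspring(
    selfish: np.ndarray,
    phi: np.ndarray,
    gamma: np.ndarray,
    omega: np.ndarray,
    counts: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Create the offspring cohort from per-parent offspring counts.

    Each offspring's phenotype is an independent draw from its parent's
    personal matrix — selfish with probability ``phi + gamma`` for a
    selfish parent and ``phi - omega`` for a generous one — except under
    perfect transmission, where offspring copy the parental phenotype.
    Offspring inherit the parent's (phi, gamma, omega) verbatim; mutation
    is applied separately, at the start of the generation in which they
    themselves reproduce.  One phenotype uniform is drawn per offspring,
    in parent order.

    Returns ``(selfish, phi, gamma, omega)`` arrays for the new cohort.
    """
    counts = np.asarray(counts, dtype=np.int64)
    rep = np.repeat(np.arange(counts.size), counts)
    child_phi = phi[rep]
    child_gamma = gamma[rep]
    child_omega = omega[rep]
    if config.perfect_transmission:
        child_selfish = selfish[rep].copy()
    else:
        p_selfish = np.where(selfish, phi + gamma, phi - omega)[rep]
        child_selfish = rng.random(rep.size) < p_selfish
    return child_selfish, child_phi, child_gamma, child_omega


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def mutate_probabilities(
    phi: np.ndarray,
    gamma: np.ndarray,
    omega: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Add zero-mean Gaussian noise to each component, then clip.

    Noise vectors are drawn component-wise (all phi perturbations, then
    gamma, then omega, each in agent order).  Clipping order: ``phi`` into
    [0, 1] first, then ``gamma`` into [0, 1 - phi] and ``omega`` into
    [0, phi] against the clipped ``phi``, which keeps all four matrix
    entries in [0, 1].  With mutation disabled this is the identity.
    """
    phi = np.asarray(phi, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if not config.mutation_enabled:
        return phi.copy(), gamma.copy(), omega.copy()
    n = phi.size
    new_phi = np.clip(phi + rng.normal(0.0, math.sqrt(config.sigma2_phi), n), 0.0, 1.0)
    new_gamma = np.clip(gamma + rng.normal(0.0, math.sqrt(config.sigma2_gamma), n), 0.0, 1.0 - new_phi)
    new_omega = np.clip(omega + rng.normal(0.0, math.sqrt(config.sigma2_omega), n), 0.0, new_phi)
    return new_phi, new_gamma, new_omega
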