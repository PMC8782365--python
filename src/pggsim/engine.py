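"""Generation stepping, single realizations and seed-controlled ensembles.

Reproducibility contract
------------------------
Each realization consumes exactly one ``numpy.random.Generator`` stream.
Within a generation the draws occur in a fixed order: mutation noise
(phi, gamma, omega vectors, each in agent order), mortality uniforms
(selfish agents in agent order), and one offspring-phenotype uniform per
offspring in parent order.  Ensemble realizations get independent streams
spawned from a single ``SeedSequence``, so (config, master seed) fully
determines every trajectory.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .config import ModelConfig
from .lifecycle import (
    ExtinctPopulationError,
    contribution_rates,
    draw_offspring,
    generous_rate,
    harvest_phase,
    mutate_probabilities,
    offspring_counts,
    public_goods_phase,
)
from .state import PopulationState, init_population

__all__ = [
    "EnsembleResult",
    "RECORD_FIELDS",
    "Trajectory",
    "run_ensemble",
    "run_realization",
    "step_generation",
]

logger = logging.getLogger(__name__)

#: Per-generation observables, in trajectory column order.  Snapshot fields
#: (N, composition, trait means) describe the cohort as born, before this
#: generation's mutation; ``pot``, ``c_G`` and ``mean_contribution`` are the
#: within-generation dynamics and are NaN on the trajectory's final record,
#: which only snapshots the terminal cohort.
RECORD_FIELDS = (
    "t", "N", "n_S", "frac_S",
    "mean_phi", "mean_gamma", "mean_omega",
    "mean_phi_SS", "mean_phi_GG",
    "pot", "c_G", "mean_contribution",
)

_NAN = float("nan")


def _snapshot(state: PopulationState) -> dict[str, float]:
    """Observables of the cohort at the start of a generation."""
    n = state.size
    if n == 0:
        return dict(
            t=state.t, N=0, n_S=0, frac_S=_NAN,
            mean_phi=_NAN, mean_gamma=_NAN, mean_omega=_NAN,
            mean_phi_SS=_NAN, mean_phi_GG=_NAN,
            pot=_NAN, c_G=_NAN, mean_contribution=_NAN,
        )
    n_s = state.n_selfish
    mean_phi = float(state.phi.mean())
    mean_gamma = float(state.gamma.mean())
    mean_omega = float(state.omega.mean())
    return dict(
        t=state.t, N=n, n_S=n_s, frac_S=n_s / n,
        mean_phi=mean_phi, mean_gamma=mean_gamma, mean_omega=mean_omega,
        mean_phi_SS=mean_phi + mean_gamma, mean_phi_GG=1.0 - mean_phi + mean_omega,
        pot=_NAN, c_G=_NAN, mean_contribution=_NAN,
    )


def step_generation(
    state: PopulationState, config: ModelConfig, rng: np.random.Generator
) -> tuple[PopulationState, dict[str, float]]:
    """Advance one full generation and return (next cohort, record).

    Phases in order: mutation of the cohort's reproduction probabilities,
    harvesting with mortality, contribution rates, the public goods game,
    offspring counts and offspring phenotype draws.  Parents die at the
    end of the generation; the returned state holds only the offspring.
    The record describes the generation just simulated.
    """
    if state.size == 0:
        raise ExtinctPopulationError(f"cannot step an extinct population (t={state.t})")

    rec = _snapshot(state)
    phi, gamma, omega = mutate_probabilities(state.phi, state.gamma, state.omega, config, rng)

    outcome = harvest_phase(state, config, rng)
    alive = outcome.alive
    if not alive.any():
        # everyone perished while harvesting: no game, no offspring
        rec["pot"] = 0.0
        return PopulationState.empty(state.t + 1, state.prev_mean_contribution), rec

    rates = contribution_rates(state, config)
    sel = state.selfish[alive]
    c = rates[alive]
    pgg = public_goods_phase(outcome.harvest[alive], sel, c, config)
    counts = offspring_counts(pgg.fitness, config)
    child_selfish, child_phi, child_gamma, child_omega = draw_offspring(
        sel, phi[alive], gamma[alive], omega[alive], counts, config, rng
    )
    mean_c = float(c.mean())

    rec["pot"] = pgg.pot
    rec["c_G"] = generous_rate(state.t, state.prev_mean_contribution, config)
    rec["mean_contribution"] = mean_c

    next_state = PopulationState(
        t=state.t + 1,
        selfish=child_selfish,
        phi=child_phi, gamma=child_gamma, omega=child_omega,
        prev_mean_contribution=mean_c,
        extinct=child_selfish.size == 0,
    )
    return next_state, rec


@dataclasses.dataclass
class Trajectory:
    """One realization: consecutive generation records plus metadata.

    ``columns`` maps each name in :data:`RECORD_FIELDS` to an array with
    one entry per recorded generation (``t = 0 .. min(T, extinction)``,
    inclusive — the final entry snapshots the terminal cohort).
    ``extinction_generation`` is the first ``t`` with ``N_t = 0``, or
    ``None`` if the population survived to ``T``.
    """

    config: ModelConfig
    seed: object
    columns: dict[str, np.ndarray]
    extinction_generation: int | None

    @property
    def n_generations(self) -> int:
        return len(self.columns["t"]) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.columns)


def run_realization(
    config: ModelConfig, seed: int | np.random.SeedSequence
) -> Trajectory:
    """Run a single realization to ``T`` generations or extinction."""
    rng = np.random.default_rng(seed)
    state = init_population(config, rng)
    cols: dict[str, list] = {k: [] for k in RECORD_FIELDS}
    extinction: int | None = None
    for _ in range(config.T):
        state, rec = step_generation(state, config, rng)
        for k in RECORD_FIELDS:
            cols[k].append(rec[k])
        if state.size == 0:
            extinction = state.t
            break
    final = _snapshot(state)
    for k in RECORD_FIELDS:
        cols[k].append(final[k])
    columns = {k: np.asarray(v, dtype=float) for k, v in cols.items()}
    columns["t"] = columns["t"].astype(np.int64)
    columns["N"] = columns["N"].astype(np.int64)
    columns["n_S"] = columns["n_S"].astype(np.int64)
    return Trajectory(
        config=config, seed=seed, columns=columns, extinction_generation=extinction
    )


@dataclasses.dataclass
class EnsembleResult:
    """Independent realizations of one scenario under a master seed."""

    config: ModelConfig
    master_seed: object
    trajectories: list[Trajectory]

    @property
    def n_realizations(self) -> int:
        return len(self.trajectories)

    @property
    def extinction_generations(self) -> list[int | None]:
        return [tr.extinction_generation for tr in self.trajectories]

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per generation per realization."""
        frames = []
        for i, tr in enumerate(self.trajectories):
            df = tr.to_frame()
            df.insert(0, "realization", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def mean_trajectory(self) -> pd.DataFrame:
        """Per-generation cross-realization means over surviving realizations.

        A realization contributes at generation ``t`` while it is still
        alive there (``N_t > 0``); extinct realizations drop out of the
        mean from their extinction generation onward.
        """
        df = self.to_frame()
        alive = df[df["N"] > 0]
        out = alive.groupby("t").mean(numeric_only=True).reset_index()
        out["n_surviving"] = alive.groupby("t").size().values
        return out.drop(columns=["realization"])


def run_ensemble(
    config: ModelConfig,
    n_realizations: int | None = None,
    master_seed: int | np.random.SeedSequence = 0,
) -> EnsembleResult:
    """Run independent realizations with streams spawned from one seed.

    Realization ``i`` uses the ``i``-th child of
    ``SeedSequence(master_seed)``, a collision-free counter-based
    derivation; two ensembles with the same (config, master seed) are
    identical.
    """
    n = config.I if n_realizations is None else int(n_realizations)
    if n < 1:
        raise ValueError("n_realizations must be >= 1")
    root = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    children = root.spawn(n)
    trajectories = []
    for i, child in enumerate(children):
        trajectories.append(run_realization(config, child))
        logger.debug("realization %d/%d done", i + 1, n)
    logger.info(
        "ensemble complete: %d realizations, %d extinct",
        n, sum(e is not None for e in (tr.extinction_generation for tr in trajectories)),
    )
    return EnsembleResult(config=config, master_seed=master_seed, trajectories=trajectories)
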