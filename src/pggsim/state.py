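"""Population state: the living cohort at one generation.

Agents are stored in struct-of-arrays form (one numpy array per trait)
because every lifecycle phase is a vectorized operation over the cohort.
Agent order is stable within a generation: the initial population lists
all selfish agents first, and offspring are appended in parent order.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import ModelConfig

__all__ = ["PopulationState", "init_population"]


@dataclasses.dataclass
class PopulationState:
    """The living cohort at generation ``t``.

    ``prev_mean_contribution`` is the mean contribution rate over the
    public-goods participants of generation ``t - 1``; it drives the
    conditional-cooperation rule and is ``None`` at ``t = 0``.
    Extinction (an empty cohort) is absorbing.
    """

    t: int
    selfish: np.ndarray  # bool, shape (N,)
    phi: np.ndarray      # float, shape (N,)
    gamma: np.ndarray
    omega: np.ndarray
    prev_mean_contribution: float | None = None
    extinct: bool = False

    @property
    def size(self) -> int:
        return int(self.selfish.size)

    @property
    def n_selfish(self) -> int:
        return int(self.selfish.sum())

    @classmethod
    def empty(cls, t: int, prev_mean_contribution: float | None = None) -> "PopulationState":
        """The absorbing extinct state at generation ``t``."""
        z = np.zeros(0)
        return cls(
            t=t,
            selfish=np.zeros(0, dtype=bool),
            phi=z.copy(), gamma=z.copy(), omega=z.copy(),
            prev_mean_contribution=prev_mean_contribution,
            extinct=True,
        )


def init_population(config: ModelConfig, rng: np.random.Generator | None = None) -> PopulationState:
    """Construct the founding cohort at ``t = 0``.

    Exactly ``round(S0 * N0)`` agents are selfish (a deterministic count,
    not a per-agent Bernoulli draw, so the initial composition carries no
    sampling variance); every agent starts with the same reproduction
    probabilities ``(phi0, gamma0, omega0)``.  ``rng`` is accepted for
    interface symmetry with the stochastic phases but is not consumed.
    """
    n = config.N0
    n_s = int(round(config.S0 * n))
    selfish = np.zeros(n, dtype=bool)
    selfish[:n_s] = True
    return PopulationState(
        t=0,
        selfish=selfish,
        phi=np.full(n, config.phi0),
        gamma=np.full(n, config.gamma0),
        omega=np.full(n, config.omega0),
        prev_mean_contribution=None,
        extinct=False,
    )
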