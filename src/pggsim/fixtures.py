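"""Hand-constructed miniature populations for oracle and conservation tests.

These are deliberately tiny (2–4 agents) with fixed trait values so exact
expectations can be computed by exhaustive enumeration of the offspring
phenotype outcomes.
"""

from __future__ import annotations

from .config import ModelConfig, build_config
from .state import PopulationState, init_population

__all__ = ["FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = ("tiny_mixed", "all_generous", "all_selfish", "neutral_symmetric")


def make_fixture(name: str) -> tuple[ModelConfig, PopulationState]:
    """Build a named miniature (config, population) pair.

    ``tiny_mixed``
        One selfish and one generous agent with the default reproduction
        probabilities; mortality and mutation off, so a single generation
        is deterministic up to offspring phenotypes.
    ``all_generous`` / ``all_selfish``
        Three agents of a single phenotype.
    ``neutral_symmetric``
        Three agents (one selfish) under fully symmetric rules: equal
        harvest and contribution rates, no mortality, no costs, and the
        neutral matrix phi = 0.5, gamma = omega = 0, so every offspring is
        an unbiased coin flip.  The environmental offer is set so each
        parent has exactly two offspring.
    """
    if name == "tiny_mixed":
        cfg = build_config(N0=2, S0=0.5, T=10, I=1, m_S=0.0, mutation_enabled=False)
    elif name == "all_generous":
        cfg = build_config(N0=3, S0=0.0, T=10, I=1, m_S=0.0, mutation_enabled=False)
    elif name == "all_selfish":
        cfg = build_config(N0=3, S0=1.0, T=10, I=1, m_S=0.0, mutation_enabled=False)
    elif name == "neutral_symmetric":
        # e = 4 -> e_t = 4, harvest = 0.5 * 4 = 2, fitness = rho * 2 = 3,
        # offspring per parent = ceil(3 - 1) = 2
        cfg = build_config(
            N0=3, S0=1 / 3, T=10, I=1,
            e=4.0, h_S=0.5, h_G=0.5, c_S=1.0,
            m_S=0.0, lam=0.0,
            phi0=0.5, gamma0=0.0, omega0=0.0,
            mutation_enabled=False,
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    return cfg, init_population(cfg)
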