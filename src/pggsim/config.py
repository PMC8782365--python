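"""Model configuration: the single source of truth for a simulation run.

The model is a generational public goods game played by two behavioural
phenotypes — selfish risk-seekers (S) and generous risk-averse agents (G) —
in an environment that offers a fixed resource budget ``e_tot = e * N0``
per generation regardless of the current population size.  All parameters
of the published baseline are fields of :class:`ModelConfig`; the three
model variants (conditional cooperation, individual cost for selfish
agents, perfect phenotype transmission) and the no-mutation control are
boolean switches on the same config.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from typing import Any, Mapping

__all__ = [
    "ConfigError",
    "ModelConfig",
    "VARIANTS",
    "apply_variant",
    "build_config",
    "load_config",
]


class ConfigError(ValueError):
    """Raised when a configuration value is out of range or inconsistent."""


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Validated parameter set for one simulation scenario.

    Instances should normally be built through :func:`build_config`, which
    fills defaults, derives ``e_tot`` and ``M``, and validates all bounds.

    Parameters
    ----------
    N0
        Initial population size.
    T
        Number of non-overlapping generations to simulate.
    I
        Default number of independent realizations in an ensemble.
    e
        Environmental offer: resource units per *initial* agent per
        generation (4.5 = abundant, 1.2 = scarce).
    e_tot
        Total resources offered per generation; fixed at ``e * N0`` for the
        whole run unless explicitly overridden.
    e_max
        Cap on the amount a single agent can harvest per generation.
    rho
        Public-goods-game multiplier applied to the communal pot.
    lam
        Community cost level, a percentage: the pot is reduced by
        ``lam/100`` resource units per selfish participant before
        multiplication.
    S0
        Initial fraction of selfish risk-seeking agents.
    h_S, h_G
        Harvest fractions of the per-capita offer ``e_t = e_tot / N_t``.
    c_S
        Contribution fraction of selfish agents (generous agents contribute
        everything, or conditionally under ``conditional_cooperation``).
    m_S, m_G
        Per-generation mortality probabilities during harvesting.
    o
        Maximum offspring count per parent.
    s
        Survival threshold: fitness at or below ``s`` yields no offspring.
    M
        Fitness at which the offspring count saturates at ``o``; always
        derived as ``s * o + s``.
    phi0, gamma0, omega0
        Initial reproduction-probability components.  ``phi`` is the
        baseline propensity to produce selfish offspring; ``gamma`` the
        extra effect of a selfish parent; ``omega`` the effect of a
        generous parent.
    sigma2_phi, sigma2_gamma, sigma2_omega
        Variances of the zero-mean Gaussian mutation noise.
    alpha
        Individual cost paid by selfish agents after redistribution;
        applied only when ``individual_cost`` is on.
    conditional_cooperation
        Generous agents copy the previous generation's mean contribution
        rate instead of always contributing 100%.
    individual_cost
        Selfish agents pay ``alpha`` after redistribution.
    perfect_transmission
        Offspring always inherit the parental phenotype.
    mutation_enabled
        Gaussian mutation of (phi, gamma, omega) each generation.
    """

    N0: int = 250
    T: int = 10_000
    I: int = 100
    e: float = 4.5
    e_tot: float = 1125.0
    e_max: float = 4.5
    rho: float = 1.5
    lam: float = 0.0
    S0: float = 0.10
    h_S: float = 0.8
    h_G: float = 0.5
    c_S: float = 0.2
    m_S: float = 0.25
    m_G: float = 0.0
    o: int = 10
    s: float = 1.0
    M: float = 11.0
    phi0: float = 0.1
    gamma0: float = 0.01
    omega0: float = 0.01
    sigma2_phi: float = 0.01
    sigma2_gamma: float = 0.01
    sigma2_omega: float = 0.01
    alpha: float = 0.1
    conditional_cooperation: bool = False
    individual_cost: bool = False
    perfect_transmission: bool = False
    mutation_enabled: bool = True

    @property
    def effective_alpha(self) -> float:
        """Individual cost actually charged: ``alpha`` only when the variant is on."""
        return self.alpha if self.individual_cost else 0.0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def with_updates(self, **updates: Any) -> "ModelConfig":
        """Return a new validated config with ``updates`` applied.

        ``e_tot`` is re-derived as ``e * N0`` when ``e`` or ``N0`` change
        (unless ``e_tot`` itself is given), and ``M`` is always re-derived
        from ``s`` and ``o``.
        """
        raw = self.to_dict()
        raw.pop("M", None)
        if ("e" in updates or "N0" in updates) and "e_tot" not in updates:
            raw.pop("e_tot", None)
        raw.update(updates)
        return build_config(raw)


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelConfig)}

_PROBABILITY_FIELDS = ("S0", "h_S", "h_G", "c_S", "m_S", "m_G", "phi0", "gamma0", "omega0")
_NONNEGATIVE_FIELDS = (
    "e", "e_tot", "e_max", "rho", "lam", "alpha", "s",
    "sigma2_phi", "sigma2_gamma", "sigma2_omega",
)
_BOOL_FIELDS = (
    "conditional_cooperation", "individual_cost", "perfect_transmission", "mutation_enabled",
)

#: Named variant presets: flag combinations studied in the model family.
VARIANTS: dict[str, dict[str, bool]] = {
    "baseline": dict(
        conditional_cooperation=False, individual_cost=False,
        perfect_transmission=False, mutation_enabled=True,
    ),
    "conditional_cooperation": dict(
        conditional_cooperation=True, individual_cost=False,
        perfect_transmission=False, mutation_enabled=True,
    ),
    "conditional_cooperation_individual_cost": dict(
        conditional_cooperation=True, individual_cost=True,
        perfect_transmission=False, mutation_enabled=True,
    ),
    "perfect_transmission": dict(
        conditional_cooperation=False, individual_cost=False,
        perfect_transmission=True, mutation_enabled=False,
    ),
    "no_mutation": dict(
        conditional_cooperation=False, individual_cost=False,
        perfect_transmission=False, mutation_enabled=False,
    ),
}


def apply_variant(config: ModelConfig, name: str) -> ModelConfig:
    """Return ``config`` with the flag preset of the named variant applied."""
    try:
        flags = VARIANTS[name]
    except KeyError:
        raise ConfigError(
            f"unknown variant {name!r}; expected one of {sorted(VARIANTS)}"
        ) from None
    return config.with_updates(**flags)


def build_config(raw: Mapping[str, Any] | None = None, **overrides: Any) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a name→value mapping.

    Unspecified parameters take the published defaults; ``e_tot`` is
    derived as ``e * N0`` unless given explicitly, and ``M`` is always
    ``s * o + s`` (an explicit inconsistent ``M`` is rejected).
    """
    merged: dict[str, Any] = {}
    if raw:
        merged.update(raw)
    merged.update(overrides)

    unknown = set(merged) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    defaults = {f.name: f.default for f in dataclasses.fields(ModelConfig)}
    values = dict(defaults)
    values.update(merged)

    # integer coercion for counts
    for name in ("N0", "T", "I", "o"):
        v = values[name]
        if not float(v).is_integer():
            raise ConfigError(f"{name} must be an integer, got {v!r}")
        values[name] = int(v)
    for name in _BOOL_FIELDS:
        values[name] = bool(values[name])
    for name in _FIELD_NAMES - set(("N0", "T", "I", "o")) - set(_BOOL_FIELDS):
        values[name] = float(values[name])

    # derived quantities
    if "e_tot" not in merged:
        values["e_tot"] = values["e"] * values["N0"]
    derived_M = values["s"] * values["o"] + values["s"]
    if "M" in merged and not math.isclose(float(merged["M"]), derived_M):
        raise ConfigError(
            f"M must equal s*o + s = {derived_M}, got {merged['M']!r}"
        )
    values["M"] = derived_M

    _validate(values)
    return ModelConfig(**values)


def _validate(v: dict[str, Any]) -> None:
    for name in ("N0", "I"):
        if v[name] < 1:
            raise ConfigError(f"{name} must be >= 1, got {v[name]}")
    if v["T"] < 0:  # T = 0 is a degenerate but legal run (initial state only)
        raise ConfigError(f"T must be >= 0, got {v['T']}")
    if v["o"] < 1:
        raise ConfigError(f"o must be >= 1, got {v['o']}")
    for name in _PROBABILITY_FIELDS:
        if not 0.0 <= v[name] <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1], got {v[name]}")
    for name in _NONNEGATIVE_FIELDS:
        if v[name] < 0.0:
            raise ConfigError(f"{name} must be >= 0, got {v[name]}")
    if v["gamma0"] > 1.0 - v["phi0"]:
        raise ConfigError(
            f"gamma0 must satisfy 0 <= gamma0 <= 1 - phi0; "
            f"got gamma0={v['gamma0']}, phi0={v['phi0']}"
        )
    if v["omega0"] > v["phi0"]:
        raise ConfigError(
            f"omega0 must satisfy 0 <= omega0 <= phi0; "
            f"got omega0={v['omega0']}, phi0={v['phi0']}"
        )


def load_config(path: str | pathlib.Path) -> ModelConfig:
    """Load a config from a YAML or JSON file (keys = ModelConfig fields)."""
    import yaml

    path = pathlib.Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration file {path} must contain a mapping")
    return build_config(raw)
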