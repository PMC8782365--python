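"""Equilibrium statistics and parameter sweeps.

The published results are equilibrium ensemble statistics: each observable
is time-averaged over a late window of each surviving realization and then
averaged across realizations.  Extinct realizations are excluded from the
equilibrium averages but counted in the extinction statistics.  A sweep
runs one ensemble per grid cell with independently derived seeds and
classifies each cell as extinct when every realization dies before ``T``.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig, apply_variant
from .engine import EnsembleResult, run_ensemble

__all__ = [
    "EquilibriumStats",
    "SweepResult",
    "equilibrium_summary",
    "summarize_frame",
    "sweep",
]

logger = logging.getLogger(__name__)

#: Observables averaged over the equilibrium window.
_WINDOW_FIELDS = (
    "N", "frac_S", "mean_phi", "mean_gamma", "mean_omega",
    "mean_phi_SS", "mean_phi_GG", "pot", "c_G", "mean_contribution",
)


@dataclasses.dataclass
class EquilibriumStats:
    """Equilibrium and extinction summary of one ensemble.

    Equilibrium fields are NaN when no realization survives.
    ``per_realization`` has one row per surviving realization (window
    time-averages) and is the basis for cross-realization standard
    errors.
    """

    T: int
    window_fraction: float
    window_start: int
    n_realizations: int
    n_surviving: int
    extinct_fraction: float
    mean_extinction_generation: float
    mean_population: float
    frac_S: float
    frac_G: float
    mean_phi: float
    mean_gamma: float
    mean_omega: float
    mean_phi_SS: float
    mean_phi_GG: float
    mean_pot: float
    mean_c_G: float
    mean_contribution: float
    per_realization: pd.DataFrame = dataclasses.field(repr=False)

    @property
    def all_extinct(self) -> bool:
        return self.n_surviving == 0

    def sem(self, field: str) -> float:
        """Cross-realization standard error of a window-averaged field.

        ``field`` is a column of ``per_realization`` (e.g. ``frac_S``).
        """
        x = self.per_realization[field].to_numpy(dtype=float)
        if x.size < 2:
            return float("nan")
        return float(x.std(ddof=1) / math.sqrt(x.size))

    def to_dict(self) -> dict[str, Any]:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "per_realization"
        }
        return d


def _window_start(T: int, window_fraction: float) -> int:
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must lie in (0, 1]")
    return max(T - max(1, int(round(window_fraction * T))), 0)


def summarize_frame(
    df: pd.DataFrame, T: int | None = None, window_fraction: float = 0.10
) -> EquilibriumStats:
    """Equilibrium summary from a tidy trajectory frame.

    The frame needs columns ``realization``, ``t``, ``N`` and the
    recorded observables; this is exactly the trajectory CSV the CLI
    writes, so stored runs can be re-summarized without re-simulating.
    A realization counts as extinct when it contains a record with
    ``N = 0``; otherwise its records with ``t >= window_start`` are
    time-averaged (NaN-aware: the final snapshot has no pot).
    """
    if df.empty:
        raise ValueError("cannot summarize an empty trajectory frame")
    if T is None:
        T = int(df["t"].max())
    start = _window_start(T, window_fraction)

    rows = []
    ext_gens = []
    n_real = df["realization"].nunique()
    for r, g in df.groupby("realization"):
        dead = g.loc[g["N"] == 0, "t"]
        if len(dead):
            ext_gens.append(int(dead.min()))
            continue
        w = g[g["t"] >= start]
        row = {"realization": r}
        for f in _WINDOW_FIELDS:
            vals = w[f].to_numpy(dtype=float) if f in w else np.array([])
            row[f] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
        rows.append(row)

    per = pd.DataFrame(rows, columns=["realization", *_WINDOW_FIELDS])
    n_surv = len(per)
    mean = {
        f: (float(per[f].mean()) if n_surv else float("nan")) for f in _WINDOW_FIELDS
    }
    return EquilibriumStats(
        T=T,
        window_fraction=window_fraction,
        window_start=start,
        n_realizations=n_real,
        n_surviving=n_surv,
        extinct_fraction=len(ext_gens) / n_real,
        mean_extinction_generation=(
            float(np.mean(ext_gens)) if ext_gens else float("nan")
        ),
        mean_population=mean["N"],
        frac_S=mean["frac_S"],
        frac_G=1.0 - mean["frac_S"] if n_surv else float("nan"),
        mean_phi=mean["mean_phi"],
        mean_gamma=mean["mean_gamma"],
        mean_omega=mean["mean_omega"],
        mean_phi_SS=mean["mean_phi_SS"],
        mean_phi_GG=mean["mean_phi_GG"],
        mean_pot=mean["pot"],
        mean_c_G=mean["c_G"],
        mean_contribution=mean["mean_contribution"],
        per_realization=per,
    )


def equilibrium_summary(
    ensemble: EnsembleResult, window_fraction: float = 0.10
) -> EquilibriumStats:
    """Equilibrium summary of an in-memory ensemble.

    Delegates to :func:`summarize_frame` on the ensemble's tidy frame, so
    an in-run summary and one recomputed from the stored trajectory CSV
    agree exactly.
    """
    return summarize_frame(
        ensemble.to_frame(), T=ensemble.config.T, window_fraction=window_fraction
    )


@dataclasses.dataclass
class SweepResult:
    """One ensemble summary per grid cell.

    ``frame`` has one row per cell: the axis values, every scalar field of
    :class:`EquilibriumStats`, and an ``all_extinct`` flag (the map of
    conditions under which populations cannot persist).
    """

    grid: dict[str, Sequence]
    n_realizations: int
    master_seed: int
    frame: pd.DataFrame
    stats: list[EquilibriumStats] = dataclasses.field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()


def _cell_config(base: ModelConfig, axes: Sequence[str], values: Sequence) -> ModelConfig:
    updates: dict[str, Any] = {}
    cfg = base
    for name, value in zip(axes, values):
        if name == "variant":
            cfg = apply_variant(cfg, value)
        else:
            updates[name] = value
    if updates:
        cfg = cfg.with_updates(**updates)
    return cfg


def sweep(
    base: ModelConfig,
    grid: Mapping[str, Sequence],
    n_realizations: int | None = None,
    master_seed: int = 0,
    window_fraction: float = 0.10,
) -> SweepResult:
    """Run an ensemble per cell of the cartesian grid and summarize each.

    ``grid`` maps config field names (or ``"variant"`` for a named flag
    preset) to value lists.  Cell ``k`` (row-major over the grid) uses the
    ``k``-th child of ``SeedSequence(master_seed)`` so cells are
    independent and the whole sweep is reproducible.
    """
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    axes = list(grid.keys())
    value_lists = [list(grid[a]) for a in axes]
    cells = list(itertools.product(*value_lists))
    seeds = np.random.SeedSequence(master_seed).spawn(len(cells))

    rows = []
    stats_list = []
    for cell, seed in zip(cells, seeds):
        cfg = _cell_config(base, axes, cell)
        n = cfg.I if n_realizations is None else n_realizations
        logger.info("sweep cell %s: running %d realizations", dict(zip(axes, cell)), n)
        ens = run_ensemble(cfg, n, seed)
        st = equilibrium_summary(ens, window_fraction)
        row = dict(zip(axes, cell))
        row.update(st.to_dict())
        row["all_extinct"] = st.all_extinct
        rows.append(row)
        stats_list.append(st)
    return SweepResult(
        grid={a: v for a, v in zip(axes, value_lists)},
        n_realizations=(base.I if n_realizations is None else n_realizations),
        master_seed=master_seed,
        frame=pd.DataFrame(rows),
        stats=stats_list,
    )
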