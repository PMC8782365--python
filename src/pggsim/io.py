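"""Result serialization: trajectory CSV, summary JSON, run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import json
import pathlib
from typing import Any

import pandas as pd

from . import __version__
from .config import ModelConfig
from .engine import EnsembleResult
from .summaries import EquilibriumStats, SweepResult


def _clean(obj: Any) -> Any:
    """Make numpy scalars and paths JSON-serializable."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, pathlib.Path):
        return str(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_trajectories(ensemble: EnsembleResult, path: str | pathlib.Path) -> pathlib.Path:
    """Write the tidy trajectory table (one row per generation per realization).

    Floats are serialized at full repr precision so the CSV preserves the
    byte-for-byte reproducibility contract.
    """
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ensemble.to_frame().to_csv(path, index=False)
    return path


def read_trajectories(path: str | pathlib.Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summary(stats: EquilibriumStats, path: str | pathlib.Path) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_clean(stats.to_dict()), indent=2, allow_nan=True) + "\n")
    return path


def write_sweep(result: SweepResult, csv_path: str | pathlib.Path) -> pathlib.Path:
    csv_path = pathlib.Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(csv_path, index=False)
    return csv_path


def write_manifest(
    path: str | pathlib.Path,
    config: ModelConfig,
    master_seed: int,
    n_realizations: int,
    outputs: dict[str, Any],
    extra: dict[str, Any] | None = None,
) -> pathlib.Path:
    """Write the run manifest: everything needed to reproduce the outputs.

    The manifest records the fully resolved configuration, the master
    seed, the package version and the output paths; with the same package
    version these determine every output byte-for-byte (the timestamp is
    informational only).
    """
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "pggsim",
        "version": __version__,
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "master_seed": master_seed,
        "n_realizations": n_realizations,
        "config": config.to_dict(),
        "outputs": outputs,
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(_clean(manifest), indent=2) + "\n")
    return path
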