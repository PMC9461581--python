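"""Configuration and dataset serialization.

Models and simulation settings round-trip through a flat YAML config
with per-agent subsections; departure datasets are tab-separated
tables (``trial, agent, decision_time, decision_rank, simultaneous``)
with a YAML sidecar recording the generating model, seed, config hash
and package version, so every output file carries its provenance.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml

from .model import AgentStrategy, GroupModel, PatchEnvironment, SimulationSettings

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "settings_to_dict",
    "settings_from_dict",
    "save_config",
    "load_config",
    "write_dataset",
    "read_dataset",
    "config_hash",
]

DATASET_COLUMNS = ["trial", "agent", "decision_time", "decision_rank", "simultaneous"]


def model_to_dict(model: GroupModel) -> dict:
    return {
        "mode": model.mode,
        "noise_scale": float(model.noise_scale),
        "environment": {
            "rho": float(model.env.rho),
            "tau": float(model.env.tau),
            "alpha": float(model.env.alpha),
            "travel_time": float(model.env.travel_time),
        },
        "agents": [
            {"theta": float(a.theta), "kappa": float(a.kappa)} for a in model.agents
        ],
    }


def model_from_dict(d: dict) -> GroupModel:
    missing = {"mode", "noise_scale", "environment", "agents"} - set(d)
    if missing:
        raise ValueError(f"config missing keys: {sorted(missing)}")
    env = PatchEnvironment(**d["environment"])
    agents = tuple(AgentStrategy(**a) for a in d["agents"])
    return GroupModel(mode=d["mode"], agents=agents, noise_scale=d["noise_scale"], env=env)


def settings_to_dict(settings: SimulationSettings) -> dict:
    return {
        "dt": float(settings.dt),
        "t_max": float(settings.t_max),
        "n_trials": int(settings.n_trials),
        "seed": int(settings.seed),
    }


def settings_from_dict(d: dict) -> SimulationSettings:
    return SimulationSettings(**d)


def config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_config(path, model: GroupModel, settings: SimulationSettings | None = None) -> None:
    config = {"model": model_to_dict(model)}
    if settings is not None:
        config["simulation"] = settings_to_dict(settings)
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_config(path) -> tuple[GroupModel, SimulationSettings | None]:
    config = yaml.safe_load(Path(path).read_text())
    if not isinstance(config, dict) or "model" not in config:
        raise ValueError(f"config {path} must contain a 'model' section")
    model = model_from_dict(config["model"])
    settings = (
        settings_from_dict(config["simulation"]) if "simulation" in config else None
    )
    return model, settings


def _package_version() -> str:
    from . import __version__

    return __version__


def write_dataset(
    df: pd.DataFrame,
    path,
    model: GroupModel | None = None,
    settings: SimulationSettings | None = None,
) -> None:
    """Write a departure dataset as TSV plus a ``.meta.yaml`` sidecar."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    meta: dict = {"package_version": _package_version(), "columns": DATASET_COLUMNS}
    if model is not None:
        config = {"model": model_to_dict(model)}
        if settings is not None:
            config["simulation"] = settings_to_dict(settings)
        meta["config"] = config
        meta["config_hash"] = config_hash(config)
    path.with_suffix(path.suffix + ".meta.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=True)
    )


def read_dataset(path) -> tuple[pd.DataFrame, dict | None]:
    """Read a dataset table and its sidecar metadata (None if absent)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset {path} missing columns: {sorted(missing)}")
    df["simultaneous"] = df["simultaneous"].astype(bool)
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else None
    return df, meta
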