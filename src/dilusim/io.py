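"""Config loading and CSV/JSON serialization for the command-line tools."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .batch_dynamics import BatchConfig, CommunityState, StrategyVector, equally_spaced_community

logger = logging.getLogger(__name__)


def load_config(path) -> dict:
    """Read a YAML or JSON key-value config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def batch_config_from_dict(cfg: dict) -> BatchConfig:
    kwargs = dict(
        c0=float(cfg["c0"]),
        nutrient_fractions=np.asarray(cfg["nutrient_fractions"], dtype=float),
        rho0=float(cfg.get("rho0", 1.0)),
        K=float(cfg.get("K", 1.0)),
    )
    for key in ("depletion_tol", "max_time"):
        if key in cfg:
            kwargs[key] = float(cfg[key])
    return BatchConfig(**kwargs)


def community_from_dict(cfg: dict) -> CommunityState:
    """Build the initial community from config keys m/p/strategies.

    ``strategies`` may be the string ``"equally_spaced"`` or an explicit
    list of strategy vectors; inocula are equal unless ``biomass`` given.
    """
    p = int(cfg.get("p", 2))
    choice = cfg.get("strategies", "equally_spaced")
    if isinstance(choice, str):
        if choice != "equally_spaced":
            raise ValueError(f"unknown strategies setting {choice!r}")
        strategies = equally_spaced_community(int(cfg["m"]), p)
    else:
        strategies = [StrategyVector(np.asarray(row, dtype=float)) for row in choice]
    m = len(strategies)
    rho0 = float(cfg.get("rho0", 1.0))
    biomass = np.asarray(cfg.get("biomass", np.full(m, rho0 / m)), dtype=float)
    return CommunityState.from_strategies(strategies, biomass)


def write_fractions_csv(table: pd.DataFrame, path) -> None:
    """Per-batch inoculum fractions in long form (batch, species, fraction)."""
    long = table.reset_index().melt(
        id_vars="batch", var_name="species", value_name="fraction"
    )
    long.sort_values(["batch", "species"]).to_csv(path, index=False)


def write_timecourse_csv(timecourse, labels, path) -> None:
    p = timecourse.nutrients.shape[1]
    cols = {"t": timecourse.times}
    for i in range(p):
        cols[f"c_{i + 1}"] = timecourse.nutrients[:, i]
    for k, label in enumerate(labels):
        cols[f"rho_{label}"] = timecourse.biomass[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_summary_json(summary: dict, config: dict, path) -> None:
    """JSON summary carrying the resolved config and package version."""
    payload = {"dilusim_version": __version__, "config": config, **summary}
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
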