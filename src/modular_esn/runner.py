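"""Experiment orchestration: config validation, dispatch, reproducible output.

A flat JSON-style dict selects one of the four experiments (``graph``,
``spreading``, ``mc``, ``recall``) and its parameters; ``run_experiment``
validates it, dispatches to the module sweeps and returns a
:class:`ResultTable` whose rows are reproducible bit-for-bit from the
master seed.  Seeds for every stochastic component derive from
``(master seed, cell index, sample index)`` via :func:`~modular_esn.seeding.derive_seed`,
so parallel and serial execution, and any evaluation order, give identical
tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .graphs import GraphSpec, WeightSpec, generate_graph, realized_mixing, weight_matrix
from .memory import MCConfig, mc_sweep
from .recall import RecallConfig, recall_sweep
from .seeding import derive_seed
from .spreading import SpreadingConfig, phase_diagram

__all__ = ["ConfigurationError", "ResultTable", "run_experiment", "write_result", "derive_seed"]

logger = logging.getLogger("modular_esn")


class ConfigurationError(ValueError):
    """An experiment config failed validation before any computation."""


@dataclass(frozen=True)
class ResultTable:
    """Long-format experiment results plus run metadata."""

    table: pd.DataFrame
    metadata: dict


_EXPERIMENTS = ("graph", "spreading", "mc", "recall")


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigurationError(message)


def _check_mu(mu, field: str = "mu") -> float:
    _require(isinstance(mu, (int, float)), f"{field} must be a number, got {mu!r}")
    _require(0.0 <= mu <= 0.5, f"{field} must lie in the allowed range [0, 0.5], got {mu}")
    return float(mu)


def _check_grid(grid, field: str, low: float, high: float) -> list[float]:
    _require(
        isinstance(grid, (list, tuple, np.ndarray)) and len(grid) > 0,
        f"{field} must be a nonempty list",
    )
    out = []
    for v in grid:
        _require(
            low <= float(v) <= high,
            f"{field} entries must lie in the allowed range [{low}, {high}], got {v}",
        )
        out.append(float(v))
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_experiment(config: dict) -> ResultTable:
    """Validate a config dict, run the named experiment, return its table.

    Required keys: ``experiment`` (one of graph | spreading | mc | recall)
    and ``seed``; the remaining keys parameterize the chosen experiment and
    fall back to the task defaults.  Schema violations raise
    :class:`ConfigurationError` before any computation starts.
    """
    _require(isinstance(config, dict), "config must be a dict")
    name = config.get("experiment")
    _require(name in _EXPERIMENTS, f"experiment must be one of {_EXPERIMENTS}, got {name!r}")
    seed = config.get("seed", 0)
    _require(isinstance(seed, int), f"seed must be an integer, got {seed!r}")

    started = datetime.now(timezone.utc).isoformat()
    if name == "graph":
        table = _run_graph(config, seed)
    elif name == "spreading":
        table = _run_spreading(config, seed)
    elif name == "mc":
        table = _run_mc(config, seed)
    else:
        table = _run_recall(config, seed)

    metadata = {
        "experiment": name,
        "config": config,
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
    }
    return ResultTable(table=table, metadata=metadata)


def _run_graph(config: dict, seed: int) -> pd.DataFrame:
    mu = _check_mu(config.get("mu", 0.2))
    n = int(config.get("n", 500))
    communities = int(config.get("communities", 50))
    _require(communities >= 1, "communities must be >= 1")
    _require(n % communities == 0, f"n = {n} must be divisible by communities = {communities}")
    spec = GraphSpec(
        n_nodes=n,
        n_communities=communities,
        community_size=n // communities,
        degree=int(config.get("degree", 6)),
        mu=mu,
        seed=derive_seed(seed, "graph", "topology"),
    )
    graph = generate_graph(spec)
    W = weight_matrix(
        graph,
        WeightSpec(
            w_low=float(config.get("w_low", -0.2)),
            w_high=float(config.get("w_high", 1.0)),
            w_scale=float(config.get("w_scale", 1.13)),
            seed=derive_seed(seed, "graph", "weights"),
        ),
    )
    logger.info("generated graph: N=%d, mu=%.3f, realized=%.4f", n, mu, realized_mixing(graph))
    coo = W.tocoo()
    return pd.DataFrame(
        {
            "source": coo.col,
            "target": coo.row,
            "weight": coo.data,
            "source_community": graph.membership[coo.col],
            "target_community": graph.membership[coo.row],
        }
    )


def _run_spreading(config: dict, seed: int) -> pd.DataFrame:
    layout = config.get("layout", "fifty")
    _require(layout in ("two", "fifty"), f"layout must be 'two' or 'fifty', got {layout!r}")
    mu_grid = _check_grid(config.get("mu_grid", [0.2]), "mu_grid", 0.0, 0.5)
    rsig_grid = _check_grid(config.get("rsig_grid", [0.25]), "rsig_grid", 0.0, 1.0)
    samples = int(config.get("samples", 48))
    _require(samples >= 1, "samples must be >= 1")
    sconf = SpreadingConfig(
        n_nodes=int(config.get("n", 500)),
        degree=int(config.get("degree", 6)),
        w_low=float(config.get("w_low", 0.2)),
        w_high=float(config.get("w_high", 0.65)),
        w_scale=float(config.get("w_scale", 1.0)),
    )
    logger.info("spreading sweep: %d x %d cells, %d samples", len(mu_grid), len(rsig_grid), samples)
    return phase_diagram(
        mu_grid,
        rsig_grid,
        n_samples=samples,
        seed=seed,
        config=sconf,
        layout=layout,
        include_communities=bool(config.get("include_communities", False)),
    )


def _run_mc(config: dict, seed: int) -> pd.DataFrame:
    mu_grid = _check_grid(config.get("mu_grid", [0.2]), "mu_grid", 0.0, 0.5)
    rsig_grid = _check_grid(config.get("rsig_grid", [0.3]), "rsig_grid", 0.0, 1.0)
    samples = int(config.get("samples", 64))
    _require(samples >= 1, "samples must be >= 1")
    mconf = MCConfig(
        max_lag=int(config.get("max_lag", 40)),
        T_washout=int(config.get("washout", 500)),
        T_train=int(config.get("train_steps", 1500)),
        T_val=int(config.get("val_steps", 1500)),
    )
    logger.info("mc sweep: %d x %d cells, %d samples", len(mu_grid), len(rsig_grid), samples)
    return mc_sweep(
        mu_grid,
        rsig_grid,
        n_samples=samples,
        config=mconf,
        seed=seed,
        n_jobs=int(config.get("n_workers", 1)),
    )


def _run_recall(config: dict, seed: int) -> pd.DataFrame:
    mu_grid = _check_grid(config.get("mu_grid", [0.1]), "mu_grid", 0.0, 0.5)
    samples = int(config.get("samples", 48))
    _require(samples >= 1, "samples must be >= 1")
    n_seq = int(config.get("n_seq", 200))
    _require(1 <= n_seq <= 1024, f"n_seq must lie in the allowed range [1, 1024], got {n_seq}")
    rconf = RecallConfig(
        delta_t=int(config.get("dt", 80)),
        n_sequences=n_seq,
        epsilon=float(config.get("epsilon", 0.1)),
    )
    logger.info("recall sweep: %d mu values, %d samples", len(mu_grid), samples)
    return recall_sweep(
        mu_grid,
        n_samples=samples,
        config=rconf,
        seed=seed,
        include_census=bool(config.get("include_census", False)),
    )


def write_result(result: ResultTable, csv_path) -> None:
    """Write the table as CSV with a JSON metadata sidecar (``.meta.json``)."""
    result.table.to_csv(csv_path, index=False)
    with open(str(csv_path) + ".meta.json", "w") as fh:
        json.dump(result.metadata, fh, indent=1, default=str)
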