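"""Short-term memory-capacity benchmark on modular reservoirs.

A Bernoulli stream of 0s and 1s is fed into the reservoir and, for every
lag ``k = 1..l``, a linear readout is trained to replay the input ``k``
steps back.  The lag-``k`` score is the squared Pearson correlation between
``u(t - k)`` and the readout output ``y_k(t)`` on a fresh validation
stream, and the memory capacity is the sum

    MC = sum_k  cov(u(t-k), y_k(t))^2 / (var(u) var(y_k)),

truncated at ``max_lag`` readouts (the tail is numerically dead for the
reservoir sizes used here).  All lags share one state history and one
least-squares solve — a multi-target regression that is mathematically
identical to training each lag independently.

MC is scored on the graded (identity) readout output; the step readout is
a task-output rule and is not applied when computing correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .esn import (
    ActivationParams,
    InputProjection,
    Reservoir,
    Trajectory,
    build_input_weights,
    run_reservoir,
    train_readout,
)
from .graphs import GraphSpec, WeightSpec, generate_graph, normalize_to, weight_matrix
from .seeding import derive_seed
from .streams import binomial_stream

__all__ = ["MCConfig", "MCResult", "lag_r2", "memory_capacity", "score_memory_capacity", "mc_sweep"]


@dataclass(frozen=True)
class MCConfig:
    """Reservoir and task settings for the memory-capacity benchmark.

    Defaults: N = 500 nodes in 50 communities of 10, in-degree 6, recurrent
    weights uniform[-0.2, 1] scaled by 1.13, input weights uniform[-0.2, 1]
    with gain 1.0 into a fraction ``r_sig`` of the neurons; 500 washout
    steps, 1,500 training steps, 1,500 validation steps, lags 1..40,
    Bernoulli(0.5) input.
    """

    mu: float = 0.2
    r_sig: float = 0.3
    n_nodes: int = 500
    n_communities: int = 50
    community_size: int = 10
    degree: int = 6
    w_low: float = -0.2
    w_high: float = 1.0
    w_scale: float = 1.13
    iw_low: float = -0.2
    iw_high: float = 1.0
    input_gain: float = 1.0
    T_washout: int = 500
    T_train: int = 1500
    T_val: int = 1500
    max_lag: int = 40
    p: float = 0.5
    activation: ActivationParams = field(default_factory=ActivationParams.threshold)
    spectral_radius_target: float | None = None

    def __post_init__(self) -> None:
        if self.T_train <= self.max_lag or self.T_val <= self.max_lag:
            raise ValueError("T_train and T_val must exceed max_lag")
        if self.T_washout < self.max_lag:
            raise ValueError("T_washout must be >= max_lag so every lagged target exists")


@dataclass(frozen=True)
class MCResult:
    """Per-lag squared correlations and their sum."""

    r2_by_lag: np.ndarray
    mc: float

    def __post_init__(self) -> None:
        if abs(self.mc - float(np.sum(self.r2_by_lag))) > 1e-12:
            raise ValueError("mc must equal the sum of r2_by_lag")


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either series is constant."""
    if x.shape[0] < 2:
        raise ValueError("need at least two points to correlate")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0  # zero-variance convention
    vx = float(np.var(x))
    vy = float(np.var(y))
    cov = float(np.mean((x - x.mean()) * (y - y.mean())))
    return cov * cov / (vx * vy)


def lag_r2(u, y, lag: int) -> float:
    """Squared correlation between ``u(t - lag)`` and ``y(t)``.

    ``u`` and ``y`` are aligned sequences of equal length; the overlap
    after shifting must contain at least two points.  Returns 0 by
    convention when either side has zero variance.
    """
    u = np.asarray(getattr(u, "values", u), dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if u.shape[0] != y.shape[0]:
        raise ValueError("u and y must have the same length")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if u.shape[0] - lag < 2:
        raise ValueError("overlap after lag trimming must contain at least 2 points")
    if lag == 0:
        return _r2(u, y)
    return _r2(u[:-lag], y[lag:])


def build_mc_reservoir(config: MCConfig, seed: int) -> Reservoir:
    """Build the graph, weights and input projection for one MC run."""
    gspec = GraphSpec(
        n_nodes=config.n_nodes,
        n_communities=config.n_communities,
        community_size=config.community_size,
        degree=config.degree,
        mu=config.mu,
        seed=derive_seed(seed, "topology"),
    )
    graph = generate_graph(gspec)
    W = weight_matrix(
        graph,
        WeightSpec(config.w_low, config.w_high, config.w_scale, seed=derive_seed(seed, "weights")),
    )
    if config.spectral_radius_target is not None:
        W = normalize_to(W, config.spectral_radius_target)
    proj = InputProjection(
        r_sig=config.r_sig,
        input_gain=config.input_gain,
        iw_low=config.iw_low,
        iw_high=config.iw_high,
        seed=derive_seed(seed, "input"),
    )
    W_in = build_input_weights(config.n_nodes, 1, proj)
    return Reservoir(W=W, W_in=W_in, activation=config.activation, membership=graph.membership)


def score_memory_capacity(
    res: Reservoir,
    T_washout: int,
    T_train: int,
    T_val: int,
    max_lag: int,
    p: float,
    seed: int,
) -> MCResult:
    """Train lag readouts on one stream and score them on a fresh one.

    The training design is the concatenated ``[x(t) : u(t)]`` history over
    the post-washout window; all ``max_lag`` readouts are solved in one
    pseudoinverse.  Validation uses an independently drawn stream with its
    own washout, and each lag is scored by :func:`lag_r2` on the graded
    readout output.
    """
    train = binomial_stream(T_washout + T_train, p, seed=derive_seed(seed, "train-stream"))
    traj = run_reservoir(None, train.values[np.newaxis, :], res)
    sl = slice(T_washout, T_washout + T_train)
    X = traj.X[:, sl]
    U = traj.U[:, sl]
    # lagged targets: row k-1 holds u(t - k) for t in the training window
    t_idx = np.arange(T_washout, T_washout + T_train)
    targets = np.stack([train.values[t_idx - k] for k in range(1, max_lag + 1)])
    readout = train_readout(Trajectory(X=X, U=U), targets)

    val = binomial_stream(T_washout + T_val, p, seed=derive_seed(seed, "val-stream"))
    vtraj = run_reservoir(None, val.values[np.newaxis, :], res)
    vsl = slice(T_washout, T_washout + T_val)
    D_val = np.vstack([vtraj.X[:, vsl], vtraj.U[:, vsl]])
    Y = readout.W_out @ D_val  # identity readout: MC is scored on the graded output
    v_idx = np.arange(T_washout, T_washout + T_val)
    r2 = np.array([_r2(val.values[v_idx - k], Y[k - 1]) for k in range(1, max_lag + 1)])
    return MCResult(r2_by_lag=r2, mc=float(np.sum(r2)))


def memory_capacity(config: MCConfig, seed: int = 0) -> MCResult:
    """Memory capacity of one reservoir realization.

    Builds the graph, weights, input projection and streams from seeds
    derived from ``seed``, so the whole run is reproducible from one
    integer.
    """
    res = build_mc_reservoir(config, seed)
    return score_memory_capacity(
        res, config.T_washout, config.T_train, config.T_val, config.max_lag, config.p, seed
    )


def _cell(config: MCConfig, mu: float, r_sig: float, i_mu: int, i_rsig: int,
          n_samples: int, seed: int) -> dict:
    from dataclasses import replace

    cell_config = replace(config, mu=float(mu), r_sig=float(r_sig))
    mcs = np.array(
        [
            memory_capacity(cell_config, derive_seed(seed, "mc", i_mu, i_rsig, s)).mc
            for s in range(n_samples)
        ]
    )
    sem = float(mcs.std(ddof=1) / np.sqrt(n_samples)) if n_samples > 1 else 0.0
    return {
        "mu": float(mu),
        "r_sig": float(r_sig),
        "mean_mc": float(mcs.mean()),
        "sem": sem,
        "n": n_samples,
    }


def mc_sweep(
    mu_grid,
    rsig_grid,
    n_samples: int,
    config: MCConfig | None = None,
    seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Mean memory capacity over a (mu, r_sig) grid.

    Every cell runs ``n_samples`` fully independent realizations (graph,
    weights, input mask, train and validation streams) whose seeds derive
    from ``(seed, cell index, sample index)``; results are therefore
    independent of evaluation order and worker count.
    """
    config = config or MCConfig()
    jobs = [
        (float(mu), float(r_sig), i_mu, i_rsig)
        for i_mu, mu in enumerate(mu_grid)
        for i_rsig, r_sig in enumerate(rsig_grid)
    ]
    if n_jobs == 1:
        records = [_cell(config, mu, r, i, j, n_samples, seed) for mu, r, i, j in jobs]
    else:
        records = Parallel(n_jobs=n_jobs)(
            delayed(_cell)(config, mu, r, i, j, n_samples, seed) for mu, r, i, j in jobs
        )
    return pd.DataFrame.from_records(records)
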