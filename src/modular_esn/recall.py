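"""Cued recall of one-hot sequences and the attractor census.

The recall task probes how many distinct patterns a reservoir can store in
its attractor landscape.  Each episode presents a one-hot 4x5 binary
sequence for 5 steps, holds the reservoir through an all-zero distractor
period of ``delta_t`` steps, raises a cue on a fifth input channel for one
step, and reads all 20 output bits once at the following decision step
through the step readout.  A recall is *perfect* only if all 20 bits match
the flattened original sequence; performance is the fraction of perfect
recalls over the trained set.

The attractor census counts how many epsilon-distinct states the reservoir
reaches at the cue time across the sequence set: two states belong to the
same attractor when connected by a chain of pairwise Euclidean distances
below ``epsilon`` (single-linkage grouping, the transitive completion of
the pairwise rule).  Collapsed attractors bound recall from above — two
sequences folded into the same state cannot be told apart by any readout.

Episodes are independent (the reservoir is reset to the zero state for
each one), so a whole sequence set is stepped as one state batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .esn import ActivationParams, Readout, Reservoir, step_state
from .graphs import GraphSpec, WeightSpec, generate_graph, weight_matrix
from .seeding import derive_seed
from .streams import SequenceSet, assemble_recall_episode, one_hot_sequence_set

__all__ = [
    "RecallConfig",
    "RecallResult",
    "AttractorCensus",
    "build_recall_reservoir",
    "train_and_evaluate_recall",
    "attractor_census",
    "group_states",
    "recall_sweep",
]

N_TARGET_BITS = 20  # flattened 4x5 sequence


@dataclass(frozen=True)
class RecallConfig:
    """Reservoir and task settings for the recall experiments.

    Defaults: N = 1,000 nodes in communities of 10, recurrent weights
    uniform[-0.1, 1.0] with scale 1.0, each of the 5 input channels (4 data
    + cue) injected into a fraction ``r_sig = 0.3`` of the neurons through
    constant weights 1.0 with input gain 2.0; 200 sequences, distractor
    delay 80, attractor tolerance epsilon = 0.1.

    The in-degree default is 4: the task's nominal connectivity of 7 read
    as the node's total (in + out) degree, i.e. a mean in-degree of 3.5,
    rounded up so communities stay bistable.  Sequence storage needs
    community-level bistability — the ON state must self-sustain,
    ``(1 - mu) * degree * mean_weight > 1`` — without the whole network
    saturating; at in-degree 7 with these weights every input ignites the
    entire reservoir into a single global attractor and nothing can be
    recalled, while at in-degree 3 the ON state is marginal and attractors
    dissolve during the distractor period.
    """

    mu: float = 0.1
    delta_t: int = 80
    n_sequences: int = 200
    n_nodes: int = 1000
    degree: int = 4
    community_size: int = 10
    w_low: float = -0.1
    w_high: float = 1.0
    w_scale: float = 1.0
    r_sig: float = 0.3
    input_gain: float = 2.0
    input_weight: float = 1.0
    epsilon: float = 0.1
    activation: ActivationParams = field(default_factory=ActivationParams.threshold)

    def __post_init__(self) -> None:
        if self.n_sequences > 1024:
            raise ValueError("at most 1024 distinct one-hot 4x5 sequences exist")
        if self.n_nodes % self.community_size:
            raise ValueError("n_nodes must be divisible by community_size")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def n_communities(self) -> int:
        return self.n_nodes // self.community_size


@dataclass(frozen=True)
class RecallResult:
    """Fraction of perfectly recalled sequences with per-sequence flags."""

    fraction_perfect: float
    success: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.fraction_perfect - float(np.mean(self.success))) > 1e-12:
            raise ValueError("fraction_perfect must be the mean of the success flags")


@dataclass(frozen=True)
class AttractorCensus:
    """Number of epsilon-distinct cue-time states and their grouping."""

    n_attractors: int
    labels: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        if not 1 <= self.n_attractors <= self.labels.shape[0]:
            raise ValueError("attractor count must lie in [1, n_sequences]")


def build_recall_reservoir(config: RecallConfig, seed: int) -> Reservoir:
    """Build the recall reservoir: graph, weights, and 5-channel projection.

    Every channel (the 4 data channels and the cue) connects to its own
    random subset of ``round(r_sig * N)`` neurons with constant weight
    ``input_weight * input_gain``.
    """
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
    rng = np.random.default_rng(derive_seed(seed, "input"))
    n_recv = int(round(config.r_sig * config.n_nodes))
    if n_recv < 1:
        raise ValueError("r_sig selects no neurons")
    W_in = np.zeros((config.n_nodes, 5))
    for ch in range(5):
        rows = rng.choice(config.n_nodes, size=n_recv, replace=False)
        W_in[rows, ch] = config.input_weight * config.input_gain
    return Reservoir(W=W, W_in=W_in, activation=config.activation, membership=graph.membership)


def _run_episodes(res: Reservoir, seqs: SequenceSet, delta_t: int, until: str) -> np.ndarray:
    """Run every episode from the zero state as one batch.

    ``until = "decision"`` returns the N x n_seq matrix of decision-step
    states; ``until = "cue"`` stops when the cue arrives (after the
    distractor, before the cue input is applied) — the snapshot the
    attractor census uses.
    """
    episodes = [assemble_recall_episode(seq, delta_t) for seq in seqs.sequences]
    n_steps = episodes[0].n_steps
    if until == "cue":
        n_steps = episodes[0].cue_step  # state reached when the cue arrives
    U = np.stack([ep.inputs for ep in episodes], axis=-1)  # (5, T, n_seq)
    x = np.zeros((res.n_nodes, len(episodes)))
    for t in range(n_steps):
        x = step_state(x, U[:, t, :], res)
    return x


def train_recall_readout(res: Reservoir, seqs: SequenceSet, delta_t: int) -> Readout:
    """Train the 20 step-readouts on the decision-step states of all episodes.

    One design column per episode — the concatenated ``[x : u]`` at the
    decision step (where the input is all-zero) — solved in a single
    pseudoinverse against the flattened sequences.
    """
    states = _run_episodes(res, seqs, delta_t, until="decision")
    D = np.vstack([states, np.zeros((5, states.shape[1]))])
    targets = seqs.sequences.reshape(len(seqs), N_TARGET_BITS).T
    sol, *_ = np.linalg.lstsq(D.T, targets.T, rcond=None)
    return Readout(W_out=sol.T, mode="step")


def evaluate_recall(res: Reservoir, seqs: SequenceSet, delta_t: int, readout: Readout) -> RecallResult:
    """Re-run every episode and mark the ones recalled perfectly.

    A sequence counts as recalled only if all 20 step-readout bits at the
    decision step equal the flattened original sequence.
    """
    states = _run_episodes(res, seqs, delta_t, until="decision")
    D = np.vstack([states, np.zeros((5, states.shape[1]))])
    z = readout.W_out @ D
    bits = (z > 0.5).astype(np.float64)
    targets = seqs.sequences.reshape(len(seqs), N_TARGET_BITS).T
    success = np.all(bits == targets, axis=0)
    return RecallResult(fraction_perfect=float(np.mean(success)), success=success)


def train_and_evaluate_recall(
    config: RecallConfig, seed: int = 0, sequences: SequenceSet | None = None
) -> RecallResult:
    """Full recall experiment on one reservoir realization.

    Builds the reservoir, draws ``n_sequences`` unique one-hot sequences
    (unless an explicit set is given), trains the readout on the whole set
    and evaluates the fraction of perfect recalls.  Deterministic given
    ``seed``.
    """
    res = build_recall_reservoir(config, seed)
    seqs = sequences or one_hot_sequence_set(config.n_sequences, seed=derive_seed(seed, "sequences"))
    readout = train_recall_readout(res, seqs, config.delta_t)
    return evaluate_recall(res, seqs, config.delta_t, readout)


def group_states(states: np.ndarray, epsilon: float) -> tuple[int, np.ndarray]:
    """Single-linkage grouping of state columns at distance threshold ``epsilon``.

    Two states share a group when connected by a chain of pairwise
    Euclidean distances strictly below ``epsilon`` — the transitive
    completion of the pairwise rule.  Returns ``(n_groups, labels)``.
    """
    n = states.shape[1]
    if n == 0:
        raise ValueError("no states to group")
    if n == 1:
        return 1, np.zeros(1, dtype=int)
    dist = squareform(pdist(states.T))
    adjacency = dist < epsilon
    n_groups, labels = connected_components(adjacency, directed=False)
    return int(n_groups), labels


def attractor_census(config: RecallConfig, seed: int = 0,
                     sequences: SequenceSet | None = None) -> AttractorCensus:
    """Count the epsilon-distinct states reached at the cue time.

    Every sequence's episode is run from the zero state up to the moment
    the cue arrives; the resulting states are grouped by single linkage at
    threshold ``config.epsilon``.  The group count proxies the number of
    attractors the readout could exploit to tell sequences apart.
    """
    res = build_recall_reservoir(config, seed)
    seqs = sequences or one_hot_sequence_set(config.n_sequences, seed=derive_seed(seed, "sequences"))
    states = _run_episodes(res, seqs, config.delta_t, until="cue")
    n_groups, labels = group_states(states, config.epsilon)
    return AttractorCensus(n_attractors=n_groups, labels=labels, epsilon=config.epsilon)


def recall_sweep(
    mu_grid,
    n_samples: int,
    config: RecallConfig | None = None,
    seed: int = 0,
    delta_t_grid=None,
    n_sequences_grid=None,
    include_census: bool = False,
) -> pd.DataFrame:
    """Mean recall performance over mu (optionally crossed with delta_t or
    the number of sequences).

    Each cell averages ``fraction_perfect`` over ``n_samples`` independent
    reservoir realizations; columns ``mu, delta_t, n_seq, mean_fraction,
    sem, n`` (plus ``mean_attractors`` when ``include_census`` is set).
    """
    config = config or RecallConfig()
    dts = list(delta_t_grid) if delta_t_grid is not None else [config.delta_t]
    nseqs = list(n_sequences_grid) if n_sequences_grid is not None else [config.n_sequences]
    records = []
    for i_mu, mu in enumerate(mu_grid):
        for i_dt, dt in enumerate(dts):
            for i_ns, ns in enumerate(nseqs):
                cell = replace(config, mu=float(mu), delta_t=int(dt), n_sequences=int(ns))
                fracs, censuses = [], []
                for s in range(n_samples):
                    run_seed = derive_seed(seed, "recall", i_mu, i_dt, i_ns, s)
                    fracs.append(train_and_evaluate_recall(cell, run_seed).fraction_perfect)
                    if include_census:
                        censuses.append(attractor_census(cell, run_seed).n_attractors)
                fracs = np.asarray(fracs)
                sem = float(fracs.std(ddof=1) / np.sqrt(n_samples)) if n_samples > 1 else 0.0
                rec = {
                    "mu": float(mu),
                    "delta_t": int(dt),
                    "n_seq": int(ns),
                    "mean_fraction": float(fracs.mean()),
                    "sem": sem,
                    "n": n_samples,
                }
                if include_census:
                    rec["mean_attractors"] = float(np.mean(censuses))
                records.append(rec)
    return pd.DataFrame.from_records(records)
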