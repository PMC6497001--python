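"""Directed, degree-regular modular graphs with a tunable bridge fraction.

The reservoirs studied here are random directed graphs with ``n_communities``
equal-size communities and a mixing parameter ``mu`` controlling the fraction
of *bridges* — edges whose endpoints lie in different communities.  The
generator is a planted-partition variant of the configuration model: every
node receives exactly ``degree`` incoming edges, of which a stochastically
rounded ``(1 - mu) * degree`` come from its own community and the rest from
the outside.  Degree sequence and total edge count are therefore invariant
as ``mu`` varies, which isolates the effect of community structure from
density effects.

Edges are stored in an ``N x N`` sparse adjacency where entry ``(i, j) = 1``
means a directed edge from presynaptic node ``j`` to postsynaptic node ``i``,
so that ``A @ x`` sums each node's presynaptic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse

__all__ = [
    "GraphSpec",
    "WeightSpec",
    "ModularGraph",
    "generate_graph",
    "realized_mixing",
    "weight_matrix",
    "spectral_radius",
    "normalize_to",
    "to_networkx",
    "write_edge_list",
    "write_membership",
    "write_graphml",
]


@dataclass(frozen=True)
class GraphSpec:
    """Parameters of a degree-regular modular graph.

    Attributes
    ----------
    n_nodes
        Total number of nodes ``N``.
    n_communities
        Number of equal-size communities.
    community_size
        Nodes per community; ``n_communities * community_size == n_nodes``.
    degree
        Incoming edges per node (constant across nodes and across ``mu``).
    mu
        Target fraction of inter-community edges, in ``[0, 0.5]``.
        ``mu = 0`` gives disconnected communities, ``mu ≈ 0.5`` erases
        community structure.
    seed
        Seed for the topology draw.
    """

    n_nodes: int
    n_communities: int
    community_size: int
    degree: int
    mu: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_communities * self.community_size != self.n_nodes:
            raise ValueError(
                f"n_communities * community_size must equal n_nodes: "
                f"{self.n_communities} * {self.community_size} != {self.n_nodes}"
            )
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")
        if not 0.0 <= self.mu <= 0.5:
            raise ValueError(f"mu must lie in [0, 0.5], got {self.mu}")
        internal = round((1.0 - self.mu) * self.degree)
        if internal > self.community_size - 1:
            raise ValueError(
                f"infeasible spec: {internal} internal stubs requested but a "
                f"community of size {self.community_size} offers at most "
                f"{self.community_size - 1} internal sources"
            )
        if self.degree > self.n_nodes - 1:
            raise ValueError("degree exceeds the number of available sources")


@dataclass(frozen=True)
class WeightSpec:
    """Uniform weight draw for the edges of a graph.

    Each edge weight is drawn i.i.d. from ``uniform[w_low, w_high]`` and then
    multiplied by the global weight scale ``w_scale`` (the knob that rescales
    every recurrent weight at once).  Setting ``w_low == w_high`` gives
    constant weights.
    """

    w_low: float = -0.2
    w_high: float = 1.0
    w_scale: float = 1.13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w_low > self.w_high:
            raise ValueError(f"w_low must be <= w_high, got {self.w_low} > {self.w_high}")
        if self.w_scale <= 0:
            raise ValueError(f"w_scale must be positive, got {self.w_scale}")


@dataclass(frozen=True)
class ModularGraph:
    """A realized directed modular graph.

    ``adjacency[i, j] == 1`` encodes a directed edge from ``j`` (presynaptic)
    to ``i`` (postsynaptic).  Communities are the contiguous index blocks of
    size ``spec.community_size``; ``membership[i]`` is the community index of
    node ``i``.
    """

    adjacency: sparse.csr_array
    membership: np.ndarray
    spec: GraphSpec

    @property
    def n_nodes(self) -> int:
        return self.spec.n_nodes

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)


def generate_graph(spec: GraphSpec) -> ModularGraph:
    """Generate a directed, in-degree-regular graph with planted communities.

    Every node draws ``n_int`` internal sources from its own community
    (excluding itself) and ``degree - n_int`` external sources from the rest
    of the network, all without replacement, where ``n_int`` is the unbiased
    stochastic rounding of ``(1 - mu) * degree``.  No self-loops or duplicate
    edges can arise, and the realized bridge fraction is an unbiased
    estimate of ``mu``.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, cs = spec.n_nodes, spec.community_size
    membership = np.repeat(np.arange(spec.n_communities), cs)

    v_internal = (1.0 - spec.mu) * spec.degree
    base = int(np.floor(v_internal))
    frac = v_internal - base
    # internal stubs can never exceed the community's capacity, external
    # stubs never the rest of the network
    lo = max(0, spec.degree - (n - cs))
    hi = min(spec.degree, cs - 1)

    rows = np.empty(n * spec.degree, dtype=np.int64)
    cols = np.empty(n * spec.degree, dtype=np.int64)
    pos = 0
    for i in range(n):
        n_int = base + (1 if rng.random() < frac else 0)
        n_int = min(max(n_int, lo), hi)
        n_ext = spec.degree - n_int
        c = membership[i]
        block_start = c * cs
        if n_int:
            # community members excluding self: draw from cs - 1 slots and
            # shift indices at or past self
            picks = rng.choice(cs - 1, size=n_int, replace=False) + block_start
            picks[picks >= i] += 1
            rows[pos : pos + n_int] = i
            cols[pos : pos + n_int] = picks
            pos += n_int
        if n_ext:
            # nodes outside the community: draw from n - cs slots and skip
            # the community's block
            picks = rng.choice(n - cs, size=n_ext, replace=False)
            picks[picks >= block_start] += cs
            rows[pos : pos + n_ext] = i
            cols[pos : pos + n_ext] = picks
            pos += n_ext

    data = np.ones(n * spec.degree, dtype=np.int8)
    adjacency = sparse.csr_array((data, (rows, cols)), shape=(n, n))
    return ModularGraph(adjacency=adjacency, membership=membership, spec=spec)


def realized_mixing(graph: ModularGraph) -> float:
    """Fraction of edges whose endpoints lie in different communities."""
    coo = graph.adjacency.tocoo()
    if coo.nnz == 0:
        raise ValueError("realized_mixing is undefined for a graph with no edges")
    cross = graph.membership[coo.row] != graph.membership[coo.col]
    return float(np.count_nonzero(cross)) / coo.nnz


def weight_matrix(graph: ModularGraph, wspec: WeightSpec) -> sparse.csr_array:
    """Draw edge weights onto the adjacency pattern of ``graph``.

    Nonzero exactly where the adjacency is nonzero; each weight is an
    independent ``uniform[w_low, w_high]`` draw multiplied by ``w_scale``.
    Deterministic given ``wspec.seed``; the weight stream is independent of
    the topology stream so topology can be held fixed while weights vary.
    """
    pattern = graph.adjacency.tocsr()
    pattern.sort_indices()
    nnz = pattern.nnz
    rng = np.random.default_rng(wspec.seed)
    if wspec.w_low == wspec.w_high:
        values = np.full(nnz, wspec.w_low, dtype=np.float64)
    else:
        values = rng.uniform(wspec.w_low, wspec.w_high, size=nnz)
    values *= wspec.w_scale
    return sparse.csr_array(
        (values, pattern.indices.copy(), pattern.indptr.copy()), shape=pattern.shape
    )


def spectral_radius(W) -> float:
    """Largest eigenvalue magnitude of a square matrix (sparse or dense)."""
    if sparse.issparse(W):
        W = W.toarray()
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {W.shape}")
    if W.shape[0] == 0 or not np.any(W):
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(W))))


def normalize_to(W, rho_target: float):
    """Rescale ``W`` so its spectral radius equals ``rho_target``."""
    rho = spectral_radius(W)
    if rho == 0.0:
        raise ValueError("cannot normalize a matrix with zero spectral radius")
    return W * (rho_target / rho)


def to_networkx(graph: ModularGraph, W: sparse.csr_array | None = None) -> nx.DiGraph:
    """Convert to a ``networkx.DiGraph`` (edge direction source -> target).

    Node attribute ``community`` carries the membership; edge attribute
    ``weight`` carries the weight (1.0 when ``W`` is not given).
    """
    g = nx.DiGraph()
    for i in range(graph.n_nodes):
        g.add_node(i, community=int(graph.membership[i]))
    coo = (W if W is not None else graph.adjacency).tocoo()
    for i, j, w in zip(coo.row, coo.col, coo.data):
        g.add_edge(int(j), int(i), weight=float(w))
    return g


def write_edge_list(path, graph: ModularGraph, W: sparse.csr_array | None = None) -> None:
    """Write a TSV edge list with columns source, target, weight."""
    coo = (W if W is not None else graph.adjacency).tocoo()
    order = np.lexsort((coo.row, coo.col))
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for k in order:
            fh.write(f"{coo.col[k]}\t{coo.row[k]}\t{coo.data[k]:.17g}\n")


def write_membership(path, graph: ModularGraph) -> None:
    """Write a TSV membership table with columns node, community."""
    with open(path, "w") as fh:
        fh.write("node\tcommunity\n")
        for i, c in enumerate(graph.membership):
            fh.write(f"{i}\t{int(c)}\n")


def write_graphml(path, graph: ModularGraph, W: sparse.csr_array | None = None) -> None:
    """Export to GraphML with ``community`` node and ``weight`` edge attributes."""
    nx.write_graphml(to_networkx(graph, W), path)
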