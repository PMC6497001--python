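"""Generate a modular reservoir graph and inspect its structure.

Builds a directed, in-degree-regular graph with 50 planted communities and
a target bridge fraction, draws the recurrent weights, and prints the
realized statistics.
"""

import numpy as np

from modular_esn import (
    GraphSpec,
    WeightSpec,
    generate_graph,
    realized_mixing,
    spectral_radius,
    weight_matrix,
)

spec = GraphSpec(n_nodes=500, n_communities=50, community_size=10, degree=6, mu=0.2, seed=7)
graph = generate_graph(spec)
W = weight_matrix(graph, WeightSpec(w_low=-0.2, w_high=1.0, w_scale=1.13, seed=7))

in_degree = np.asarray(graph.adjacency.sum(axis=1)).ravel()
print(f"nodes: {graph.n_nodes}, edges: {graph.n_edges}")
print(f"in-degree: min {in_degree.min()}, max {in_degree.max()} (regular by construction)")
print(f"target mu: {spec.mu}, realized bridge fraction: {realized_mixing(graph):.4f}")
print(f"weight range: [{W.data.min():.3f}, {W.data.max():.3f}], mean {W.data.mean():.3f}")
print(f"spectral radius: {spectral_radius(W):.3f}")
print()
print("The realized bridge fraction tracks mu to within sampling noise while")
print("every node keeps exactly 6 incoming edges, so sweeping mu changes only")
print("how the fixed connectivity budget is split between communities.")
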