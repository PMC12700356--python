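import numpy as np
import pytest

from dcglearn.graphs import WeightedDigraph, is_stable
from dcglearn.simulate import scenario_one_b0


@pytest.fixture
def four_var_graph() -> WeightedDigraph:
    """The four-outcome cyclic benchmark graph (two joint 3-cycles)."""
    return WeightedDigraph(scenario_one_b0())


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_cyclic_digraph(rng, n: int, p_edge: float = 0.45, require_cycle: bool = True):
    """Random stable weighted digraph, optionally guaranteed cyclic.

    Weights are drawn away from zero and the matrix is rescaled to spectral
    radius ~0.8 when needed.
    """
    for _ in range(200):
        mask = rng.uniform(size=(n, n)) < p_edge
        np.fill_diagonal(mask, False)
        w = np.where(mask, rng.uniform(0.3, 1.2, size=(n, n)) * rng.choice([-1, 1], size=(n, n)), 0.0)
        if require_cycle:
            import networkx as nx

            g = nx.from_numpy_array((np.abs(w.T) > 0).astype(int), create_using=nx.DiGraph)
            if nx.is_directed_acyclic_graph(g):
                continue
        rho = np.max(np.abs(np.linalg.eigvals(w)))
        if rho >= 0.9:
            w = w * (0.8 / rho)
        graph = WeightedDigraph(w)
        if is_stable(graph.weights):
            return graph
    raise RuntimeError("could not generate a suitable random graph")


def brute_force_cycles(graph: WeightedDigraph):
    """Oracle: enumerate simple cycles by exhaustive path search."""
    n = graph.n_vertices
    adj = {v: [q for p, q, _ in graph.edges() if p == v] for v in range(n)}
    found = set()

    def dfs(start, node, path):
        for nxt in adj[node]:
            if nxt == start and len(path) >= 2:
                k = path.index(min(path))
                found.add(tuple(path[k:] + path[:k]))
            elif nxt > start and nxt not in path:
                dfs(start, nxt, path + [nxt])

    for s in range(n):
        dfs(s, s, [s])
    return found
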