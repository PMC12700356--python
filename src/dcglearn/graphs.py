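"""Weighted directed-graph algebra for linear cyclic structural models.

Coefficient matrices follow the *target-row* convention throughout: entry
``(q, p)`` of a weight matrix is the coefficient of the edge ``p -> q``
(the effect of vertex ``p`` on vertex ``q``).  The unmixing matrix of a
graph with coefficient matrix ``B`` is ``W = I - B``; a graph is recovered
from any unmixing matrix by normalizing each row by its diagonal entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "ZERO_TOL",
    "STABILITY_TOL",
    "GraphError",
    "WeightedDigraph",
    "Cycle",
    "UnmixingMatrix",
    "find_cycles",
    "is_stable",
    "spectral_radius",
    "solve_equilibrium",
    "to_unmixing",
    "from_unmixing",
]

#: Default magnitude below which a coefficient is treated as zero (no edge).
ZERO_TOL = 1e-8

#: Default margin for the spectral-radius stability test.
STABILITY_TOL = 1e-9


class GraphError(ValueError):
    """Invalid graph, matrix, or cycle argument."""


def _as_square(matrix) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise GraphError(f"expected a square matrix, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class WeightedDigraph:
    """Directed graph with real edge weights and zero diagonal.

    Parameters
    ----------
    weights:
        Square matrix in target-row convention; ``weights[q, p]`` is the
        coefficient of the edge ``p -> q``.  The diagonal must be exactly
        zero (no self-loops).
    labels:
        Optional vertex names; defaults to ``Y1 .. Yn``.
    zero_tol:
        Magnitude threshold deciding edge existence.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = ()
    zero_tol: float = ZERO_TOL

    def __post_init__(self) -> None:
        w = _as_square(self.weights)
        if np.any(np.diagonal(w) != 0.0):
            raise GraphError("diagonal entries must be exactly zero (no self-loops)")
        object.__setattr__(self, "weights", w)
        labels = tuple(self.labels) or tuple(f"Y{i + 1}" for i in range(w.shape[0]))
        if len(labels) != w.shape[0]:
            raise GraphError(
                f"{len(labels)} labels for {w.shape[0]} vertices"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]

    def has_edge(self, p: int, q: int) -> bool:
        """True iff the edge ``p -> q`` is present."""
        return abs(self.weights[q, p]) > self.zero_tol

    def edges(self) -> list[tuple[int, int, float]]:
        """All edges as ``(source, target, weight)`` triples."""
        q_idx, p_idx = np.nonzero(np.abs(self.weights) > self.zero_tol)
        return [(int(p), int(q), float(self.weights[q, p])) for q, p in zip(q_idx, p_idx)]

    def support(self) -> frozenset[tuple[int, int]]:
        """Edge support ``{(source, target)}`` at the zero tolerance."""
        q_idx, p_idx = np.nonzero(np.abs(self.weights) > self.zero_tol)
        return frozenset((int(p), int(q)) for q, p in zip(q_idx, p_idx))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_vertices))
        for p, q, w in self.edges():
            g.add_edge(p, q, weight=w)
        return g

    # --- serialization ----------------------------------------------------

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for name in self.labels:
            lines.append(f'  "{name}";')
        for p, q, w in self.edges():
            lines.append(
                f'  "{self.labels[p]}" -> "{self.labels[q]}" [label="{w:.3g}", weight="{w:.12g}"];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for i, name in enumerate(self.labels):
            g.add_node(name)
        for p, q, w in self.edges():
            g.add_edge(self.labels[p], self.labels[q], weight=float(w))
        nx.write_graphml(g, path)

    def to_adjacency_csv(self) -> str:
        """Square adjacency matrix CSV with header labels (target rows)."""
        header = "," + ",".join(self.labels)
        rows = [header]
        for q in range(self.n_vertices):
            vals = ",".join(f"{self.weights[q, p]:.12g}" for p in range(self.n_vertices))
            rows.append(f"{self.labels[q]},{vals}")
        return "\n".join(rows) + "\n"


@dataclass(frozen=True)
class Cycle:
    """Simple directed cycle, stored in canonical rotation.

    ``vertices = (v1, ..., vM)`` denotes the cycle with edges
    ``v1 -> v2 -> ... -> vM -> v1``; the stored rotation starts at the
    smallest vertex index.  Self-loops (length 1) are excluded.
    """

    vertices: tuple[int, ...]

    def __post_init__(self) -> None:
        verts = tuple(int(v) for v in self.vertices)
        if len(verts) < 2:
            raise GraphError("a cycle needs at least 2 vertices")
        if len(set(verts)) != len(verts):
            raise GraphError("cycle vertices must be distinct")
        k = verts.index(min(verts))
        object.__setattr__(self, "vertices", verts[k:] + verts[:k])

    def __len__(self) -> int:
        return len(self.vertices)

    def edges(self) -> list[tuple[int, int]]:
        v = self.vertices
        return [(v[i], v[(i + 1) % len(v)]) for i in range(len(v))]

    def parent_in_cycle(self, vertex: int) -> int:
        """The unique in-cycle parent of ``vertex``."""
        v = self.vertices
        i = v.index(vertex)
        return v[i - 1]

    def reversed(self) -> "Cycle":
        return Cycle(tuple(reversed(self.vertices)))

    def is_disjoint(self, other: "Cycle") -> bool:
        return not set(self.vertices) & set(other.vertices)


@dataclass(frozen=True)
class UnmixingMatrix:
    """Unmixing matrix ``W``; normalized form is ``I - B`` for a graph ``B``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_square(self.values))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def diagonal(self) -> np.ndarray:
        return np.diagonal(self.values)

    def normalized(self, zero_tol: float = ZERO_TOL) -> "UnmixingMatrix":
        """Divide each row by its diagonal entry so the diagonal is all ones."""
        d = self.diagonal()
        if np.any(np.abs(d) <= zero_tol):
            raise GraphError("cannot normalize: zero diagonal entry")
        return UnmixingMatrix(self.values / d[:, None])


def find_cycles(graph: WeightedDigraph, chord_policy: str = "ignore") -> list[Cycle]:
    """Enumerate every simple directed cycle of length >= 2.

    Parameters
    ----------
    graph:
        Host graph (zero diagonal enforced by construction).
    chord_policy:
        ``"ignore"`` (default): a cycle is the vertex sequence together with
        exactly its loop edges; additional edges of the graph among the
        cycle's vertices (chords) do not suppress it.  ``"suppress"``: a
        vertex sequence only counts as a cycle when the graph contains no
        extra edge between two of its vertices.

    Returns
    -------
    Cycles in canonical rotation, sorted by length then lexicographically.
    """
    if chord_policy not in ("ignore", "suppress"):
        raise ValueError(f"unknown chord_policy {chord_policy!r}")
    g = graph.to_networkx()
    out = []
    for seq in nx.simple_cycles(g):
        if len(seq) < 2:
            continue
        cyc = Cycle(tuple(seq))
        if chord_policy == "suppress":
            verts = set(cyc.vertices)
            loop = set(cyc.edges())
            extra = any(
                (p, q) not in loop
                for p, q, _ in graph.edges()
                if p in verts and q in verts
            )
            if extra:
                continue
        out.append(cyc)
    return sorted(out, key=lambda c: (len(c), c.vertices))


def spectral_radius(B0) -> float:
    """Maximum modulus of the eigenvalues of ``B0``."""
    return float(np.max(np.abs(np.linalg.eigvals(_as_square(B0))))) if np.asarray(B0).size else 0.0


def is_stable(B0, tol: float = STABILITY_TOL) -> bool:
    """True iff the spectral radius of ``B0`` is strictly below ``1 - tol``."""
    return spectral_radius(B0) < 1.0 - tol


def solve_equilibrium(B0, c) -> np.ndarray:
    """Solve the fixed point ``y = B0 @ y + c`` of a stable linear system."""
    B0 = _as_square(B0)
    c = np.asarray(c, dtype=float)
    if not is_stable(B0):
        raise GraphError(
            f"unstable coefficient matrix (spectral radius {spectral_radius(B0):.6g})"
        )
    return np.linalg.solve(np.eye(B0.shape[0]) - B0, c)


def to_unmixing(graph: WeightedDigraph) -> UnmixingMatrix:
    """``W = I - B`` for the graph's coefficient matrix ``B``."""
    return UnmixingMatrix(np.eye(graph.n_vertices) - graph.weights)


def from_unmixing(
    W: UnmixingMatrix,
    zero_tol: float = ZERO_TOL,
    labels: tuple[str, ...] = (),
) -> WeightedDigraph:
    """Recover the graph ``B = I - W`` after row-normalizing ``W``.

    Each row is first divided by its diagonal entry; entries with magnitude
    at most ``zero_tol`` are snapped to exact zero so the diagonal of ``B``
    is exactly zero.
    """
    norm = W.normalized(zero_tol).values
    B = np.eye(W.n) - norm
    B[np.abs(B) <= zero_tol] = 0.0
    np.fill_diagonal(B, 0.0)
    return WeightedDigraph(B, labels=labels, zero_tol=zero_tol)
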