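"""ICA equivalence classes and instrument-based identification.

A linear cyclic structural model is only recoverable from the observed
distribution up to admissible row permutations and row scalings of its
unmixing matrix ``W = I - B``.  This module makes that equivalence class
executable:

- :func:`apply_permutation` / :func:`is_admissible` — the permutation
  calculus on unmixing matrices (row ``r`` moves to row ``phi(r)``);
- :func:`decompose` — split a row-permutation into irreducible (single
  orbit) components;
- :func:`reverse_cycle_surgery` — the graph-level counterpart of an
  admissible irreducible permutation: reverse a set of pairwise disjoint
  cycles and re-target the out-of-cycle parents of every cycle vertex;
- :func:`enumerate_class` — brute-force enumeration of the whole class by
  scanning all row permutations;
- :func:`certify_identifiability` — uniqueness certificate given declared
  instrumental variables (vertices outside the graph whose single child
  pins down the true member of the class).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from dcglearn.graphs import (
    ZERO_TOL,
    Cycle,
    GraphError,
    UnmixingMatrix,
    WeightedDigraph,
    find_cycles,
    from_unmixing,
    is_stable,
    to_unmixing,
)

__all__ = [
    "RowPermutation",
    "ClassMember",
    "EquivalenceClass",
    "InstrumentSpec",
    "IdentifiabilityCertificate",
    "apply_permutation",
    "is_admissible",
    "decompose",
    "permutation_for_reversal",
    "reverse_cycle_surgery",
    "surgery_support",
    "enumerate_class",
    "enumerate_class_by_surgery",
    "certify_identifiability",
]


@dataclass(frozen=True)
class RowPermutation:
    """Partial permutation of row indices with no fixed points.

    ``mapping`` is a bijection on its key set ``R`` (``|R| >= 2``) with
    ``mapping[r] != r`` for every ``r``.
    """

    mapping: dict[int, int]

    def __post_init__(self) -> None:
        m = {int(k): int(v) for k, v in self.mapping.items()}
        if len(m) < 2:
            raise ValueError("row-permutation domain needs at least 2 indices")
        if set(m.values()) != set(m.keys()):
            raise ValueError("mapping must be a bijection on its domain")
        if any(v == k for k, v in m.items()):
            raise ValueError("row-permutation may not have fixed points")
        object.__setattr__(self, "mapping", m)

    @property
    def domain(self) -> frozenset[int]:
        return frozenset(self.mapping)

    def __call__(self, r: int) -> int:
        return self.mapping[r]

    def inverse(self) -> "RowPermutation":
        return RowPermutation({v: k for k, v in self.mapping.items()})

    def is_irreducible(self) -> bool:
        """True iff the permutation is a single orbit on its domain."""
        return len(decompose(self)) == 1


def apply_permutation(W: UnmixingMatrix, phi: RowPermutation) -> UnmixingMatrix:
    """Move row ``r`` of ``W`` to row ``phi(r)``; other rows untouched.

    No normalization is performed.
    """
    n = W.n
    if any(r < 0 or r >= n for r in phi.domain):
        raise IndexError(f"permutation domain {sorted(phi.domain)} outside 0..{n - 1}")
    out = W.values.copy()
    for r in phi.domain:
        out[phi(r)] = W.values[r]
    return UnmixingMatrix(out)


def is_admissible(W: UnmixingMatrix, phi: RowPermutation, zero_tol: float = ZERO_TOL) -> bool:
    """True iff every diagonal of the permuted matrix exceeds ``zero_tol``."""
    permuted = apply_permutation(W, phi)
    return bool(np.all(np.abs(permuted.diagonal()) > zero_tol))


def decompose(phi: RowPermutation) -> list[RowPermutation]:
    """Split ``phi`` into its disjoint orbit (irreducible) components.

    The component domains partition the domain of ``phi`` and applying the
    components sequentially (in any order) equals applying ``phi``.
    """
    seen: set[int] = set()
    parts: list[RowPermutation] = []
    for start in sorted(phi.domain):
        if start in seen:
            continue
        orbit = [start]
        cur = phi(start)
        while cur != start:
            orbit.append(cur)
            cur = phi(cur)
        seen.update(orbit)
        parts.append(RowPermutation({r: phi(r) for r in orbit}))
    return parts


def permutation_for_reversal(cycles: list[Cycle]) -> RowPermutation:
    """Row-permutation whose action on ``W`` reverses the given disjoint cycles.

    Each cycle vertex's row is moved to the row of its in-cycle parent.
    """
    mapping: dict[int, int] = {}
    for cyc in cycles:
        for v in cyc.vertices:
            if v in mapping:
                raise GraphError("cycles are not vertex-disjoint")
            mapping[v] = cyc.parent_in_cycle(v)
    return RowPermutation(mapping)


def _check_cycles_in_graph(graph: WeightedDigraph, cycles: list[Cycle]) -> None:
    for cyc in cycles:
        for p, q in cyc.edges():
            if not graph.has_edge(p, q):
                raise GraphError(f"cycle edge {p}->{q} not present in graph")
    for a, b in itertools.combinations(cycles, 2):
        if not a.is_disjoint(b):
            raise GraphError(
                "cycles share vertices; no admissible row-permutation reverses both"
            )


def reverse_cycle_surgery(graph: WeightedDigraph, cycles: list[Cycle]) -> WeightedDigraph:
    """Reverse disjoint cycles of ``graph`` and re-target out-of-cycle parents.

    Implemented by applying the corresponding row-permutation to the
    unmixing matrix and row-normalizing, so the weights follow the
    unmixing-matrix construction: a reversed cycle edge carries the
    reciprocal of the original edge weight it replaces, and out-of-cycle
    parent edges are rescaled accordingly.
    """
    _check_cycles_in_graph(graph, cycles)
    phi = permutation_for_reversal(cycles)
    W = to_unmixing(graph)
    if not is_admissible(W, phi, graph.zero_tol):
        raise GraphError("cycle reversal is not admissible for this graph")
    permuted = apply_permutation(W, phi)
    return from_unmixing(permuted, zero_tol=graph.zero_tol, labels=graph.labels)


def surgery_support(
    graph: WeightedDigraph, cycles: list[Cycle]
) -> frozenset[tuple[int, int]]:
    """Edge support of the cycle-reversal surgery, computed combinatorially.

    Independent of the unmixing-matrix route in
    :func:`reverse_cycle_surgery`: (i) reverse each cycle's loop edges,
    (ii) move every out-of-cycle edge ``z -> v`` (``v`` a cycle vertex) to
    ``z -> pa(v)`` where ``pa(v)`` is ``v``'s in-cycle parent.
    """
    _check_cycles_in_graph(graph, cycles)
    in_cycle: dict[int, Cycle] = {}
    loop_edges: set[tuple[int, int]] = set()
    for cyc in cycles:
        for v in cyc.vertices:
            if v in in_cycle:
                raise GraphError("cycles are not vertex-disjoint")
            in_cycle[v] = cyc
        loop_edges.update(cyc.edges())
    out: set[tuple[int, int]] = set()
    for p, q, _w in graph.edges():
        if (p, q) in loop_edges:
            out.add((q, p))  # reversed cycle edge
        elif q in in_cycle:
            out.add((p, in_cycle[q].parent_in_cycle(q)))  # re-targeted parent
        else:
            out.add((p, q))
    return frozenset(out)


@dataclass(frozen=True)
class ClassMember:
    graph: WeightedDigraph
    stable: bool
    permutation: RowPermutation | None  # None for the base graph


@dataclass(frozen=True)
class EquivalenceClass:
    base: WeightedDigraph
    members: tuple[ClassMember, ...]

    def __len__(self) -> int:
        return len(self.members)

    def supports(self) -> set[frozenset[tuple[int, int]]]:
        return {m.graph.support() for m in self.members}

    def stable_members(self) -> tuple[ClassMember, ...]:
        return tuple(m for m in self.members if m.stable)


def enumerate_class(
    graph: WeightedDigraph,
    stable_only: bool = False,
    max_vertices: int = 9,
) -> EquivalenceClass:
    """Brute-force the ICA equivalence class of ``graph``.

    Scans all ``n!`` full row permutations of the unmixing matrix, keeps
    the admissible ones, normalizes, and dedupes by edge support.  The base
    graph is always a member (identity permutation).
    """
    n = graph.n_vertices
    if n > max_vertices:
        raise GraphError(f"{n} vertices exceeds enumeration cap {max_vertices}")
    W = to_unmixing(graph)
    Wv = W.values
    tol = graph.zero_tol
    members: list[ClassMember] = [
        ClassMember(graph, is_stable(graph.weights), None)
    ]
    seen = {graph.support()}
    for perm in itertools.permutations(range(n)):
        moved = {r: perm[r] for r in range(n) if perm[r] != r}
        if not moved:
            continue
        # admissibility: the diagonal of the permuted matrix picks entry
        # (r, phi(r)) of W for moved rows
        if any(abs(Wv[r, t]) <= tol for r, t in moved.items()):
            continue
        phi = RowPermutation(moved)
        candidate = from_unmixing(apply_permutation(W, phi), zero_tol=tol, labels=graph.labels)
        support = candidate.support()
        if support in seen:
            continue
        seen.add(support)
        members.append(ClassMember(candidate, is_stable(candidate.weights), phi))
    if stable_only:
        members = [m for m in members if m.stable]
    return EquivalenceClass(base=graph, members=tuple(members))


def enumerate_class_by_surgery(graph: WeightedDigraph) -> EquivalenceClass:
    """Generate the class by cycle-reversal surgery over disjoint-cycle subsets.

    Cross-check counterpart of :func:`enumerate_class`: every non-empty set
    of pairwise disjoint cycles yields one (possibly duplicate) member.
    """
    cycles = find_cycles(graph)
    members: list[ClassMember] = [ClassMember(graph, is_stable(graph.weights), None)]
    seen = {graph.support()}
    for k in range(1, len(cycles) + 1):
        for subset in itertools.combinations(cycles, k):
            if any(
                not a.is_disjoint(b) for a, b in itertools.combinations(subset, 2)
            ):
                continue
            phi = permutation_for_reversal(list(subset))
            W = to_unmixing(graph)
            if not is_admissible(W, phi, graph.zero_tol):
                continue
            candidate = from_unmixing(
                apply_permutation(W, phi), zero_tol=graph.zero_tol, labels=graph.labels
            )
            support = candidate.support()
            if support in seen:
                continue
            seen.add(support)
            members.append(
                ClassMember(candidate, is_stable(candidate.weights), phi)
            )
    return EquivalenceClass(base=graph, members=tuple(members))


@dataclass(frozen=True)
class InstrumentSpec:
    """Declared instruments: map outcome-vertex index -> instrument name.

    Each instrument has exactly one child among the graph's vertices (its
    designated target) and lives outside the instantaneous graph.
    """

    assignments: dict[int, str]

    def __post_init__(self) -> None:
        m = {int(k): str(v) for k, v in self.assignments.items()}
        names = list(m.values())
        if len(set(names)) != len(names):
            dup = sorted({x for x in names if names.count(x) > 1})
            raise GraphError(
                f"instrument(s) {dup} declared for more than one target "
                "(an instrument must have exactly one child in the graph)"
            )
        object.__setattr__(self, "assignments", m)

    @property
    def targets(self) -> frozenset[int]:
        return frozenset(self.assignments)


def augment_with_instruments(
    graph: WeightedDigraph,
    instruments: InstrumentSpec,
    instrument_weight: float = 0.5,
) -> tuple[WeightedDigraph, dict[int, int]]:
    """Append one vertex per instrument with a single edge to its target.

    Returns the augmented graph and a map target-index -> instrument-index
    (in the augmented vertex numbering).
    """
    n = graph.n_vertices
    targets = sorted(instruments.assignments)
    if any(t < 0 or t >= n for t in targets):
        raise GraphError("instrument target outside the graph's vertex range")
    m = n + len(targets)
    W = np.zeros((m, m))
    W[:n, :n] = graph.weights
    inst_index: dict[int, int] = {}
    labels = list(graph.labels)
    for k, t in enumerate(targets):
        idx = n + k
        W[t, idx] = instrument_weight
        inst_index[t] = idx
        labels.append(instruments.assignments[t])
    return WeightedDigraph(W, labels=tuple(labels), zero_tol=graph.zero_tol), inst_index


@dataclass(frozen=True)
class IdentifiabilityCertificate:
    unique: bool
    sufficient_condition: bool
    class_size: int
    surviving_size: int
    surviving_edges: tuple[tuple[tuple[str, str], ...], ...]
    surviving_permutations: tuple[dict[int, int] | None, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "unique": self.unique,
                "sufficient_condition": self.sufficient_condition,
                "class_size": self.class_size,
                "surviving_size": self.surviving_size,
                "surviving_edges": [
                    [list(e) for e in member] for member in self.surviving_edges
                ],
                "surviving_permutations": [
                    None if p is None else {str(k): v for k, v in p.items()}
                    for p in self.surviving_permutations
                ],
            },
            indent=2,
        )


def certify_identifiability(
    graph: WeightedDigraph,
    instruments: InstrumentSpec,
    declared: frozenset[int] | None = None,
    instrument_weight: float = 0.5,
    stable_only: bool = False,
    max_vertices: int = 9,
) -> IdentifiabilityCertificate:
    """Certify unique identifiability of ``graph`` in its equivalence class.

    The graph is augmented with every instrument in ``instruments``; the
    augmented class is enumerated exhaustively; a member survives when the
    only child of each *declared* instrument (default: all of them) is its
    designated target.  The graph is uniquely identified iff exactly one
    member survives.  The sufficient-condition check — every cycle contains
    a vertex with a declared instrument — is reported alongside.
    """
    if declared is None:
        declared = instruments.targets
    else:
        declared = frozenset(declared)
        if not declared <= instruments.targets:
            raise GraphError("declared targets must be a subset of the instrument spec")

    cycles = find_cycles(graph)
    sufficient = all(any(v in declared for v in cyc.vertices) for cyc in cycles)

    augmented, inst_index = augment_with_instruments(graph, instruments, instrument_weight)
    cls = enumerate_class(augmented, stable_only=stable_only, max_vertices=max_vertices)

    n = graph.n_vertices
    survivors: list[ClassMember] = []
    for member in cls.members:
        support = member.graph.support()
        ok = True
        for t in sorted(declared):
            idx = inst_index[t]
            children = {q for (p, q) in support if p == idx and q < n}
            if children != {t}:
                ok = False
                break
        if ok:
            survivors.append(member)

    labels = augmented.labels
    return IdentifiabilityCertificate(
        unique=len(survivors) == 1,
        sufficient_condition=sufficient,
        class_size=len(cls),
        surviving_size=len(survivors),
        surviving_edges=tuple(
            tuple(
                (labels[p], labels[q]) for p, q in sorted(m.graph.support())
            )
            for m in survivors
        ),
        surviving_permutations=tuple(
            None if m.permutation is None else dict(m.permutation.mapping)
            for m in survivors
        ),
    )
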