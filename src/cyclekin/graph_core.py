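"""Kinetic diagrams and their auxiliary diagram families.

A *kinetic diagram* is an undirected, connected, simple graph whose nodes
are discrete system states and whose edges are reversible transitions, each
carrying a forward and a reverse rate symbol.  Three families of auxiliary
diagrams are derived from it:

* **partial diagrams** -- spanning trees of the kinetic diagram;
* **directional diagrams** -- spanning trees with every edge oriented
  toward a single target state; each one encodes a rate product that is
  one additive term of the target state's unnormalized steady-state
  probability;
* **flux diagrams** -- a target cycle (kept bidirectional) plus directed
  feeder edges that drain every remaining state into the cycle; each one
  encodes one term of a net cycle flux numerator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "EdgeAnnotation",
    "KineticDiagram",
    "PartialDiagram",
    "DirectionalDiagram",
    "FluxDiagram",
    "DiagramError",
    "rate_name",
    "load_diagram",
    "kirchhoff_count",
    "enumerate_partial_diagrams",
    "enumerate_directional_diagrams",
    "enumerate_flux_diagrams",
]

PROCESSES = ("binding", "unbinding", "conformational", "leakage")
SIDES = ("int", "ext", "none")


class DiagramError(ValueError):
    """Raised for structurally invalid kinetic diagrams or queries."""


def rate_name(i: int, j: int) -> str:
    """Canonical rate symbol name for the directed transition i -> j."""
    return f"k_{i}_{j}"


@dataclass(frozen=True)
class EdgeAnnotation:
    """Metadata attached to one *directed* edge.

    ``order`` is the reaction order; order-2 edges are pseudo-first-order
    binding steps whose effective rate is an intrinsic on-rate times the
    concentration named by ``concentration``.
    """

    process: str = "conformational"
    ligand: str | None = None
    side: str = "none"
    order: int = 1
    concentration: str | None = None

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise DiagramError(f"unknown process {self.process!r}")
        if self.side not in SIDES:
            raise DiagramError(f"unknown side {self.side!r}")
        if self.order not in (1, 2):
            raise DiagramError(f"reaction order must be 1 or 2, got {self.order}")
        if self.order == 2 and self.concentration is None:
            raise DiagramError("order-2 edge requires a concentration symbol")


@dataclass(frozen=True)
class KineticDiagram:
    """Connected simple graph of states with paired reversible rates.

    ``states`` are 1-based external labels.  ``transitions`` hold each
    reversible pair once as a sorted tuple ``(i, j)`` with ``i < j``; the
    two directed rate symbols are ``rates[(i, j)]`` and ``rates[(j, i)]``.
    """

    states: tuple[int, ...]
    transitions: tuple[tuple[int, int], ...]
    rates: Mapping[tuple[int, int], str]
    annotations: Mapping[tuple[int, int], EdgeAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for i, j in self.transitions:
            if i == j:
                raise DiagramError(f"self-loop on state {i}")
            if not (i in self.states and j in self.states):
                raise DiagramError(f"transition ({i},{j}) references unknown state")
            if i > j:
                raise DiagramError(f"transition ({i},{j}) must be stored sorted")
            if (i, j) in seen:
                raise DiagramError(f"duplicate transition ({i},{j})")
            seen.add((i, j))
            if (i, j) not in self.rates or (j, i) not in self.rates:
                raise DiagramError(f"missing reverse rate for transition ({i},{j})")
        g = self.to_networkx()
        if len(self.states) > 1 and not nx.is_connected(g):
            raise DiagramError("kinetic diagram is disconnected")

    # -- convenience accessors -------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    def directed_edges(self) -> list[tuple[int, int]]:
        """All directed edges in deterministic order."""
        out = []
        for i, j in self.transitions:
            out.append((i, j))
            out.append((j, i))
        return out

    def neighbors(self, i: int) -> list[int]:
        return sorted(
            j for a, b in self.transitions for j in ((b,) if a == i else (a,) if b == i else ())
        )

    def has_transition(self, i: int, j: int) -> bool:
        return tuple(sorted((i, j))) in set(self.transitions)

    def annotation(self, i: int, j: int) -> EdgeAnnotation:
        return self.annotations.get((i, j), EdgeAnnotation())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.states)
        g.add_edges_from(self.transitions)
        return g


@dataclass(frozen=True)
class PartialDiagram:
    """A spanning tree of the parent kinetic diagram."""

    edges: tuple[tuple[int, int], ...]  # sorted unordered pairs

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class DirectionalDiagram:
    """A spanning tree oriented toward a single target state."""

    target: int
    edges: tuple[tuple[int, int], ...]  # directed (source, sink) pairs
    parent: PartialDiagram

    def rate_product(self) -> tuple[str, ...]:
        """The sorted multiset of rate symbols on the directed edges."""
        return tuple(sorted(rate_name(i, j) for i, j in self.edges))


@dataclass(frozen=True)
class FluxDiagram:
    """A bidirectional target cycle plus directed feeder edges."""

    target_cycle: tuple[int, ...]
    feeder_edges: tuple[tuple[int, int], ...]  # directed, disjoint from cycle

    def feeder_rate_product(self) -> tuple[str, ...]:
        return tuple(sorted(rate_name(i, j) for i, j in self.feeder_edges))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def load_diagram(
    model_description: Sequence[Sequence[object]] | Iterable[Mapping[str, object]],
    states: Sequence[int] | None = None,
    annotations: Mapping[tuple[int, int], EdgeAnnotation] | None = None,
) -> KineticDiagram:
    """Build a :class:`KineticDiagram` from a rate matrix or an edge list.

    Parameters
    ----------
    model_description:
        Either a square matrix (nested sequence / ndarray) whose nonzero
        (i, j) entries declare directed edges, or an iterable of edge
        records ``{"from": i, "to": j, ...}`` with optional annotation
        keys (``process``, ``ligand``, ``side``, ``order``,
        ``concentration``).
    states:
        Explicit state labels; defaults to ``1..N`` for matrix input.
    annotations:
        Extra per-directed-edge annotations (matrix input only).

    Every declared directed edge must have its reverse declared as well;
    an unpaired edge raises :class:`DiagramError`.
    """
    if _looks_like_matrix(model_description):
        return _from_matrix(np.asarray(model_description), states, annotations)
    return _from_edge_records(model_description, states)


def _looks_like_matrix(obj) -> bool:
    if isinstance(obj, np.ndarray):
        return True
    if isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], (list, tuple, np.ndarray)):
        return True
    return False


def _from_matrix(mat, states, annotations) -> KineticDiagram:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise DiagramError("rate matrix must be square")
    n = mat.shape[0]
    labels = tuple(states) if states is not None else tuple(range(1, n + 1))
    if len(labels) != n:
        raise DiagramError("state label count does not match matrix size")
    transitions = []
    for a in range(n):
        if mat[a, a]:
            raise DiagramError(f"self-loop on state {labels[a]}")
        for b in range(a + 1, n):
            fwd, rev = bool(mat[a, b]), bool(mat[b, a])
            if fwd != rev:
                i, j = (labels[a], labels[b]) if fwd else (labels[b], labels[a])
                raise DiagramError(f"missing reverse rate for declared edge {i}->{j}")
            if fwd:
                transitions.append((labels[a], labels[b]))
    rates = {}
    for i, j in transitions:
        rates[(i, j)] = rate_name(i, j)
        rates[(j, i)] = rate_name(j, i)
    return KineticDiagram(labels, tuple(transitions), rates, dict(annotations or {}))


def _from_edge_records(records, states) -> KineticDiagram:
    directed: dict[tuple[int, int], EdgeAnnotation] = {}
    for rec in records:
        i, j = int(rec["from"]), int(rec["to"])
        if i == j:
            raise DiagramError(f"self-loop on state {i}")
        if (i, j) in directed:
            raise DiagramError(f"duplicate edge declaration {i}->{j}")
        directed[(i, j)] = EdgeAnnotation(
            process=rec.get("process", "conformational"),
            ligand=rec.get("ligand"),
            side=rec.get("side", "none"),
            order=int(rec.get("order", 1)),
            concentration=rec.get("concentration"),
        )
    for i, j in directed:
        if (j, i) not in directed:
            raise DiagramError(f"missing reverse rate for declared edge {i}->{j}")
    labels = tuple(states) if states is not None else tuple(
        sorted({s for e in directed for s in e})
    )
    transitions = tuple(sorted({tuple(sorted(e)) for e in directed}))
    rates = {e: rate_name(*e) for e in directed}
    return KineticDiagram(labels, transitions, rates, directed)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def kirchhoff_count(diagram: KineticDiagram) -> int:
    """Number of spanning trees via the matrix-tree theorem.

    Computed as the determinant of a principal (N-1)x(N-1) minor of the
    undirected graph Laplacian; serves as the independent oracle for
    :func:`enumerate_partial_diagrams`.
    """
    g = diagram.to_networkx()
    if diagram.n_states > 1 and not nx.is_connected(g):
        raise DiagramError("kinetic diagram is disconnected")
    lap = nx.laplacian_matrix(g, nodelist=sorted(diagram.states)).toarray().astype(float)
    count = int(round(float(np.linalg.det(lap[1:, 1:]))))
    if count < 1:
        raise DiagramError("Kirchhoff count < 1; diagram is not connected")
    return count


def _spans(edges: Sequence[tuple[int, int]], states: Sequence[int]) -> bool:
    """True iff `edges` (|V|-1 of them) form a spanning tree: union-find."""
    parent = {s: s for s in states}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri == rj:  # would close a loop
            return False
        parent[ri] = rj
    return True


def enumerate_partial_diagrams(diagram: KineticDiagram) -> list[PartialDiagram]:
    """All spanning trees by test-and-select over edge combinations.

    Combinations of |V|-1 edges are drawn in lexicographic order over the
    sorted transition list, so output order is deterministic.
    """
    n = diagram.n_states
    out = []
    for combo in itertools.combinations(diagram.transitions, n - 1):
        if _spans(combo, diagram.states):
            out.append(PartialDiagram(tuple(combo)))
    if len(out) != kirchhoff_count(diagram):
        raise DiagramError("spanning-tree enumeration disagrees with matrix-tree count")
    return out


def _orient_to_target(tree_edges, states, target) -> tuple[tuple[int, int], ...]:
    """Orient a spanning tree's edges toward `target` (child -> parent)."""
    adj: dict[int, list[int]] = {s: [] for s in states}
    for i, j in tree_edges:
        adj[i].append(j)
        adj[j].append(i)
    parent = {target: None}
    stack = [target]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                stack.append(v)
    return tuple(sorted((v, p) for v, p in parent.items() if p is not None))


def enumerate_directional_diagrams(diagram: KineticDiagram) -> list[DirectionalDiagram]:
    """One directional diagram per (partial diagram, target state) pair."""
    partials = enumerate_partial_diagrams(diagram)
    out = []
    for part in partials:
        for target in diagram.states:
            edges = _orient_to_target(part.edges, diagram.states, target)
            out.append(DirectionalDiagram(target, edges, part))
    return out


def _is_cycle_of(diagram: KineticDiagram, cycle: Sequence[int]) -> bool:
    if len(cycle) < 3 or len(set(cycle)) != len(cycle):
        return False
    return all(
        diagram.has_transition(a, b) for a, b in zip(cycle, list(cycle[1:]) + [cycle[0]])
    )


def enumerate_flux_diagrams(
    diagram: KineticDiagram, target_cycle: Sequence[int]
) -> list[FluxDiagram]:
    """All flux diagrams for `target_cycle`.

    A flux diagram assigns exactly one outgoing directed non-cycle edge to
    every state outside the cycle such that repeatedly following those
    edges always reaches the cycle (no secondary loops).  Hamiltonian
    cycles (and cycles admitting no such assignment) yield an empty list,
    in which case the feeder sum is taken as 1 downstream.
    """
    cyc = tuple(target_cycle)
    if not _is_cycle_of(diagram, cyc):
        raise DiagramError(f"{cyc} is not a simple cycle of the diagram")
    cycle_nodes = set(cyc)
    cycle_transitions = {
        tuple(sorted((a, b))) for a, b in zip(cyc, cyc[1:] + cyc[:1])
    }
    outside = sorted(s for s in diagram.states if s not in cycle_nodes)
    if not outside:
        return []
    # candidate out-edges per outside state, excluding cycle transitions
    candidates = {
        u: [v for v in diagram.neighbors(u) if tuple(sorted((u, v))) not in cycle_transitions]
        for u in outside
    }
    out = []
    for choice in itertools.product(*(candidates[u] for u in outside)):
        succ = dict(zip(outside, choice))
        if _drains_to_cycle(succ, cycle_nodes):
            feeders = tuple(sorted(succ.items()))
            out.append(FluxDiagram(cyc, feeders))
    return out


def _drains_to_cycle(succ: Mapping[int, int], cycle_nodes: set[int]) -> bool:
    done: set[int] = set()
    for start in succ:
        seen = []
        u = start
        while u not in cycle_nodes and u not in done:
            if u in seen:
                return False  # loop among feeder states
            seen.append(u)
            u = succ[u]
        done.update(seen)
    return True
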