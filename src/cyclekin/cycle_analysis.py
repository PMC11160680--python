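"""Simple-cycle enumeration, orientation, and net ligand transport.

The positive direction of a cycle is declared by an ordered pair of
consecutive nodes rather than a figure-dependent "counter-clockwise"
convention, so it remains well defined for non-planar diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .graph_core import DiagramError, KineticDiagram

__all__ = [
    "Cycle",
    "TransportSignature",
    "enumerate_cycles",
    "classify_cycle_transport",
    "contributing_cycles",
]


@dataclass(frozen=True)
class Cycle:
    """A simple cycle with a declared positive traversal direction."""

    nodes: tuple[int, ...]
    positive_orientation: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.nodes) < 3 or len(set(self.nodes)) != len(self.nodes):
            raise DiagramError(f"not a simple cycle: {self.nodes}")
        a, b = self.positive_orientation
        pairs = set(zip(self.nodes, self.nodes[1:] + self.nodes[:1]))
        if (a, b) not in pairs and (b, a) not in pairs:
            raise DiagramError(
                f"orientation pair {self.positive_orientation} is not consecutive in {self.nodes}"
            )

    def positive_sequence(self) -> tuple[int, ...]:
        """Node sequence rotated/reflected so traversal order is positive."""
        seq = list(self.nodes)
        a, b = self.positive_orientation
        pairs = list(zip(seq, seq[1:] + seq[:1]))
        if (a, b) not in pairs:
            seq = seq[::-1]
        k = seq.index(a)
        rolled = tuple(seq[k:] + seq[:k])
        assert rolled[1] == b or len(rolled) == 2
        return rolled

    def directed_edges(self) -> tuple[tuple[int, int], ...]:
        seq = self.positive_sequence()
        return tuple(zip(seq, seq[1:] + seq[:1]))

    def reversed_(self) -> "Cycle":
        a, b = self.positive_orientation
        return Cycle(self.nodes, (b, a))


@dataclass(frozen=True)
class TransportSignature:
    """Net molecules of each ligand moved ext -> int per positive completion."""

    counts: Mapping[str, int]

    def __getitem__(self, ligand: str) -> int:
        return self.counts.get(ligand, 0)

    def is_zero(self) -> bool:
        return all(v == 0 for v in self.counts.values())


def canonical_cycle(nodes: Sequence[int]) -> Cycle:
    """Canonical form: lowest label first, lower-labelled neighbor second.

    The positive orientation is the canonical sequence order.
    """
    seq = list(nodes)
    k = seq.index(min(seq))
    seq = seq[k:] + seq[:k]
    if seq[-1] < seq[1]:
        seq = [seq[0]] + seq[1:][::-1]
    return Cycle(tuple(seq), (seq[0], seq[1]))


def enumerate_cycles(diagram: KineticDiagram) -> list[Cycle]:
    """All simple cycles, one per rotation/reflection class, sorted."""
    g = diagram.to_networkx()
    cycles = [canonical_cycle(c) for c in nx.simple_cycles(g)]
    cycles.sort(key=lambda c: (len(c.nodes), c.nodes))
    return cycles


def classify_cycle_transport(diagram: KineticDiagram, cycle: Cycle) -> TransportSignature:
    """Walk the cycle once in its positive direction and tally transport.

    Binding from the external side and unbinding to the internal side move
    a ligand ext -> int (+1 each, summed and halved); the reverse events
    count -1.  Binding/unbinding edges must carry ligand and side
    annotations.
    """
    tallies: dict[str, int] = {}
    for i, j in cycle.directed_edges():
        ann = diagram.annotation(i, j)
        if ann.process not in ("binding", "unbinding"):
            continue
        if ann.ligand is None or ann.side == "none":
            raise DiagramError(f"edge {i}->{j} lacks ligand/side annotation")
        if ann.process == "binding":
            delta = 1 if ann.side == "ext" else -1
        else:
            delta = -1 if ann.side == "ext" else 1
        tallies[ann.ligand] = tallies.get(ann.ligand, 0) + delta
    for lig, v in tallies.items():
        if v % 2:
            raise DiagramError(f"unbalanced binding/unbinding events for {lig!r}")
    return TransportSignature({lig: v // 2 for lig, v in tallies.items()})


def contributing_cycles(
    diagram: KineticDiagram,
    cycles: Sequence[Cycle],
    ligand: str,
    positive_direction: str = "ext_to_int",
) -> list[tuple[Cycle, int]]:
    """Cycles with net transport of `ligand`, with signed weights.

    The weight is the cycle's net ext->int count, sign-flipped when the
    declared positive transport direction is ``"int_to_ext"``.  Summing
    ``weight * J_K`` over the returned list yields the operational flux.
    """
    if positive_direction not in ("ext_to_int", "int_to_ext"):
        raise DiagramError(f"unknown direction {positive_direction!r}")
    known = {
        ann.ligand
        for ann in diagram.annotations.values()
        if ann.process in ("binding", "unbinding") and ann.ligand is not None
    }
    if ligand not in known:
        raise DiagramError(f"ligand {ligand!r} has no annotated binding edges")
    flip = -1 if positive_direction == "int_to_ext" else 1
    out = []
    for cyc in cycles:
        count = classify_cycle_transport(diagram, cyc)[ligand]
        if count:
            out.append((cyc, flip * count))
    return out
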