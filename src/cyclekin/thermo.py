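"""Thermodynamic constraints on kinetic diagrams.

Cycle closure (the Wegscheider condition) requires the intrinsic forward
and reverse rate products around every cycle to be equal; the chemical
driving force of a cycle is the log-ratio of its forward and reverse
concentration products.  kT = 1 throughout; driving forces are in kT
units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cycle_analysis import Cycle
from .graph_core import (
    DiagramError,
    EdgeAnnotation,
    KineticDiagram,
    rate_name,
)

__all__ = [
    "CycleThermo",
    "EquilibriumRateSet",
    "closure_residual",
    "driving_force",
    "cycle_thermo",
    "generate_equilibrium_diagram",
]


@dataclass(frozen=True)
class CycleThermo:
    """Closure residual and driving force of one cycle."""

    cycle: Cycle
    closure: float  # ln(forward/reverse intrinsic rate product)
    chi: float  # driving force, kT units

    @property
    def equilibrium_constant(self) -> float:
        return math.exp(self.chi)


@dataclass(frozen=True)
class EquilibriumRateSet:
    """Detailed-balanced rates from node potentials and edge barriers.

    ``k_ij = exp(u_i - b_ij)`` with symmetric barriers ``b_ij = b_ji``
    guarantees ``k_ij / k_ji = exp(u_i - u_j)`` and hence zero closure
    residual on every cycle; the stationary distribution is Boltzmann,
    proportional to ``exp(-u_i)``.
    """

    potentials: Mapping[int, float]
    barriers: Mapping[tuple[int, int], float]  # keyed by sorted pair
    seed: int

    def rates(self) -> dict[str, float]:
        out = {}
        for (i, j), b in self.barriers.items():
            out[rate_name(i, j)] = math.exp(self.potentials[i] - b)
            out[rate_name(j, i)] = math.exp(self.potentials[j] - b)
        return out

    def boltzmann_weights(self) -> dict[int, float]:
        z = sum(math.exp(-u) for u in self.potentials.values())
        return {s: math.exp(-u) / z for s, u in self.potentials.items()}


def _intrinsic(rates: Mapping[str, float], i: int, j: int) -> float:
    try:
        k = rates[rate_name(i, j)]
    except KeyError:
        raise DiagramError(f"no intrinsic rate supplied for {i}->{j}") from None
    if not k > 0:
        raise DiagramError(f"nonpositive intrinsic rate for {i}->{j}")
    return k


def closure_residual(
    diagram: KineticDiagram, intrinsic_rates: Mapping[str, float], cycle: Cycle
) -> float:
    """ln of forward/reverse intrinsic rate product around `cycle`.

    Zero (to numerical precision) iff the cycle satisfies kinetic cycle
    closure; `intrinsic_rates` must be concentration-stripped.
    """
    r = 0.0
    for i, j in cycle.directed_edges():
        r += math.log(_intrinsic(intrinsic_rates, i, j))
        r -= math.log(_intrinsic(intrinsic_rates, j, i))
    return r


def driving_force(
    diagram: KineticDiagram, cycle: Cycle, concentrations: Mapping[str, float]
) -> float:
    """Chemical driving force chi of `cycle` in kT units.

    chi = ln(X+ / X-) where X+ (X-) is the product of the concentrations
    on order-2 binding edges traversed in the positive (negative) cycle
    direction.  Antisymmetric under orientation reversal; zero when all
    paired concentrations are equal.
    """
    chi = 0.0
    for i, j in cycle.directed_edges():
        for a, b, sign in ((i, j, 1.0), (j, i, -1.0)):
            ann = diagram.annotation(a, b)
            if ann.order == 2:
                if ann.concentration not in concentrations:
                    raise DiagramError(
                        f"missing concentration {ann.concentration!r} for edge {a}->{b}"
                    )
                c = concentrations[ann.concentration]
                if not c > 0:
                    raise DiagramError(f"nonpositive concentration {ann.concentration!r}")
                chi += sign * math.log(c)
    return chi


def cycle_thermo(
    diagram: KineticDiagram,
    cycle: Cycle,
    intrinsic_rates: Mapping[str, float],
    concentrations: Mapping[str, float],
) -> CycleThermo:
    return CycleThermo(
        cycle,
        closure_residual(diagram, intrinsic_rates, cycle),
        driving_force(diagram, cycle, concentrations),
    )


def generate_equilibrium_diagram(
    n_states: int,
    edge_density: float = 0.5,
    seed: int = 0,
    max_resamples: int = 1000,
) -> tuple[KineticDiagram, EquilibriumRateSet]:
    """Random connected diagram with detailed-balanced rates.

    Erdos-Renyi topology at `edge_density`, resampled until connected.
    Potentials are uniform(-3, 3) and barriers uniform(0, 3), spanning
    about six decades of rates.  Deterministic in `seed`.
    """
    if n_states < 3:
        raise DiagramError("need at least 3 states")
    if not 0 < edge_density <= 1:
        raise DiagramError("edge density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    states = tuple(range(1, n_states + 1))
    all_pairs = [(i, j) for i in states for j in states if i < j]
    for _ in range(max_resamples):
        mask = rng.random(len(all_pairs)) < edge_density
        chosen = tuple(p for p, m in zip(all_pairs, mask) if m)
        if len(chosen) < n_states - 1:
            continue
        if _connected(states, chosen):
            break
    else:
        raise DiagramError("could not sample a connected graph at this density")
    potentials = {s: float(rng.uniform(-3, 3)) for s in states}
    barriers = {e: float(rng.uniform(0, 3)) for e in chosen}
    rates = {e: rate_name(*e) for pair in chosen for e in (pair, pair[::-1])}
    annotations = {
        e: EdgeAnnotation(process="conformational")
        for pair in chosen
        for e in (pair, pair[::-1])
    }
    diagram = KineticDiagram(states, chosen, rates, annotations)
    return diagram, EquilibriumRateSet(potentials, barriers, seed)


def _connected(states, edges) -> bool:
    parent = {s: s for s in states}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent[find(i)] = find(j)
    return len({find(s) for s in states}) == 1
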