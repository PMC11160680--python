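"""Exact symbolic steady-state expressions over rate symbols.

All expressions are kept as (numerator, normalization) pairs where the
shared normalization ``sigma`` is the sum of every directional-diagram
rate product.  Downstream ratios (e.g. stoichiometries) then cancel
``sigma`` exactly instead of blowing up under simplification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import sympy as sp

from .cycle_analysis import Cycle, contributing_cycles, enumerate_cycles
from .graph_core import (
    DiagramError,
    KineticDiagram,
    enumerate_directional_diagrams,
    enumerate_flux_diagrams,
    rate_name,
)

__all__ = [
    "RateExpressionSet",
    "CycleFluxExpression",
    "OperationalFluxExpression",
    "state_probability_expressions",
    "net_cycle_flux_expression",
    "net_transition_flux_expression",
    "operational_flux",
    "substitute",
    "symbolically_equal",
    "compile_numeric",
]


def rate_symbol(i: int, j: int) -> sp.Symbol:
    return sp.Symbol(rate_name(i, j), positive=True)


def _product(symbol_names: Sequence[str]) -> sp.Expr:
    return sp.Mul(*(sp.Symbol(s, positive=True) for s in sorted(symbol_names)))


@dataclass(frozen=True)
class RateExpressionSet:
    """Unnormalized state probabilities and their shared normalization."""

    diagram: KineticDiagram
    omega: Mapping[int, sp.Expr]  # state -> sum of directional rate products
    sigma: sp.Expr

    def probability(self, state: int) -> sp.Expr:
        return self.omega[state] / self.sigma

    def term_count(self, state: int) -> int:
        return len(sp.Add.make_args(self.omega[state]))


@dataclass(frozen=True)
class CycleFluxExpression:
    """Net cycle flux J_K = (pi_forward - pi_reverse) * feeder_sum / sigma."""

    cycle: Cycle
    pi_forward: sp.Expr
    pi_reverse: sp.Expr
    feeder_sum: sp.Expr
    sigma: sp.Expr

    @property
    def numerator(self) -> sp.Expr:
        return (self.pi_forward - self.pi_reverse) * self.feeder_sum

    @property
    def expression(self) -> sp.Expr:
        return self.numerator / self.sigma


@dataclass(frozen=True)
class OperationalFluxExpression:
    """Observable transport rate of one ligand, as numerator / sigma."""

    ligand: str
    route: str  # "cycles" | "transitions"
    components: tuple[tuple[str, int], ...]  # (description, signed weight)
    numerator: sp.Expr
    sigma: sp.Expr

    @property
    def expression(self) -> sp.Expr:
        return self.numerator / self.sigma


def state_probability_expressions(diagram: KineticDiagram) -> RateExpressionSet:
    """Assemble p_i = omega_i / sigma from the directional diagrams."""
    omega: dict[int, sp.Expr] = {s: sp.Integer(0) for s in diagram.states}
    terms: dict[int, list[sp.Expr]] = {s: [] for s in diagram.states}
    for dd in enumerate_directional_diagrams(diagram):
        terms[dd.target].append(_product(dd.rate_product()))
    for s in diagram.states:
        omega[s] = sp.Add(*terms[s])
    sigma = sp.Add(*[omega[s] for s in diagram.states])
    return RateExpressionSet(diagram, omega, sigma)


def _cycle_rate_products(cycle: Cycle) -> tuple[sp.Expr, sp.Expr]:
    fwd = _product([rate_name(i, j) for i, j in cycle.directed_edges()])
    rev = _product([rate_name(j, i) for i, j in cycle.directed_edges()])
    return fwd, rev


def net_cycle_flux_expression(
    diagram: KineticDiagram,
    cycle: Cycle,
    expressions: RateExpressionSet | None = None,
) -> CycleFluxExpression:
    """J_K for `cycle`, positive in the cycle's declared direction."""
    flux_diagrams = enumerate_flux_diagrams(diagram, cycle.nodes)
    if flux_diagrams:
        feeder_sum = sp.Add(*[_product(fd.feeder_rate_product()) for fd in flux_diagrams])
    else:
        feeder_sum = sp.Integer(1)
    if expressions is None:
        expressions = state_probability_expressions(diagram)
    fwd, rev = _cycle_rate_products(cycle)
    return CycleFluxExpression(cycle, fwd, rev, feeder_sum, expressions.sigma)


def net_transition_flux_expression(
    diagram: KineticDiagram,
    i: int,
    j: int,
    expressions: RateExpressionSet | None = None,
) -> sp.Expr:
    """Numerator of J_ij = k_ij p_i - k_ji p_j (divide by sigma for the flux)."""
    if not diagram.has_transition(i, j):
        raise DiagramError(f"({i},{j}) is not a transition of the diagram")
    if expressions is None:
        expressions = state_probability_expressions(diagram)
    return rate_symbol(i, j) * expressions.omega[i] - rate_symbol(j, i) * expressions.omega[j]


def _contributing_transitions(
    diagram: KineticDiagram, ligand: str, positive_direction: str
) -> list[tuple[int, int]]:
    """Directed edges on the *external* side that realize positive transport.

    With positive transport ext -> int the contributing transitions are
    the external binding edges; with positive int -> ext they are the
    external unbinding edges.  Summing their net transition fluxes gives
    the operational flux.
    """
    want = "binding" if positive_direction == "ext_to_int" else "unbinding"
    picked = []
    for i, j in diagram.directed_edges():
        ann = diagram.annotation(i, j)
        if ann.process == want and ann.ligand == ligand and ann.side == "ext":
            picked.append((i, j))
    if not picked:
        raise DiagramError(f"no external {want} transitions annotated for {ligand!r}")
    return picked


def operational_flux(
    diagram: KineticDiagram,
    ligand: str,
    route: str = "cycles",
    positive_direction: str = "ext_to_int",
    expressions: RateExpressionSet | None = None,
    cycles: Sequence[Cycle] | None = None,
) -> OperationalFluxExpression:
    """Operational flux of `ligand` via cycle fluxes or transition fluxes.

    Both routes produce symbolically equal expressions; the cycles route
    sums weighted net cycle fluxes of transport-contributing cycles, the
    transitions route sums net transition fluxes of the external
    binding/unbinding edges for the ligand.
    """
    if expressions is None:
        expressions = state_probability_expressions(diagram)
    if route == "cycles":
        if cycles is None:
            cycles = enumerate_cycles(diagram)
        signed = contributing_cycles(diagram, cycles, ligand, positive_direction)
        if not signed:
            raise DiagramError(f"no cycles transport {ligand!r}")
        numerator = sp.Integer(0)
        components = []
        for cyc, weight in signed:
            cf = net_cycle_flux_expression(diagram, cyc, expressions)
            numerator = numerator + weight * cf.numerator
            components.append(("-".join(map(str, cyc.nodes)), weight))
    elif route == "transitions":
        numerator = sp.Integer(0)
        components = []
        for i, j in _contributing_transitions(diagram, ligand, positive_direction):
            numerator = numerator + net_transition_flux_expression(diagram, i, j, expressions)
            components.append((f"{i}->{j}", 1))
    else:
        raise DiagramError(f"unknown route {route!r}")
    return OperationalFluxExpression(
        ligand, route, tuple(components), numerator, expressions.sigma
    )


def substitute(
    expression: sp.Expr,
    parameter_map: Mapping[str, sp.Expr | float],
    simplify: bool = True,
) -> sp.Expr:
    """Substitute rate symbols with model-parameter expressions.

    Unmapped symbols pass through.  With ``simplify`` the result is
    factored so common parameter products are pulled out.
    """
    subs = {sp.Symbol(k, positive=True): v for k, v in parameter_map.items()}
    result = expression.subs(subs, simultaneous=True)
    if simplify:
        result = sp.factor(sp.expand(result))
    return result


def symbolically_equal(
    expr_a: sp.Expr,
    expr_b: sp.Expr,
    n_numeric: int = 50,
    tolerance: float = 1e-9,
    seed: int = 0,
) -> tuple[bool, str]:
    """Decide whether two expressions are identically equal.

    Tries exact polynomial cancellation first (``expand(a - b) == 0``
    after clearing denominators with ``together``).  If the symbolic path
    fails to decide, falls back to evaluation at `n_numeric` random
    positive rate points and reports ``"numerically verified"`` instead
    of ``"proved"``.
    """
    diff = expr_a - expr_b
    try:
        num, _den = sp.fraction(sp.together(diff))
        if sp.expand(num) == 0:
            return True, "proved"
        if not num.free_symbols:
            return (num == 0), "proved"
    except Exception:  # pragma: no cover - sympy internals
        pass
    import random

    rng = random.Random(seed)
    symbols = sorted(diff.free_symbols, key=lambda s: s.name)
    fn = sp.lambdify(symbols, diff, modules="math")
    fa = sp.lambdify(symbols, expr_a, modules="math")
    for _ in range(n_numeric):
        vals = [10 ** rng.uniform(-2, 2) for _ in symbols]
        ref = max(abs(float(fa(*vals))), 1.0)
        if abs(fn(*vals)) > tolerance * ref:
            return False, "numerically refuted"
    return True, "numerically verified"


def compile_numeric(
    expression: sp.Expr, symbol_order: Sequence[str]
) -> Callable[..., float]:
    """Compile an expression to a fast positional numeric evaluator.

    Raises at compile time if `symbol_order` does not cover all free
    symbols of the expression.  Large polynomial sums (which exceed the
    Python compiler's nesting limit under ``lambdify``) are evaluated
    from an exponent-matrix representation instead.
    """
    symbols = [sp.Symbol(s, positive=True) for s in symbol_order]
    missing = expression.free_symbols - set(symbols)
    if missing:
        raise DiagramError(
            f"symbol order missing {sorted(s.name for s in missing)}"
        )
    n_terms = len(sp.Add.make_args(expression))
    if n_terms > 500 and expression.is_polynomial(*symbols):
        return _compile_polynomial(expression, symbols)
    return sp.lambdify(symbols, expression, modules="numpy")


def _compile_polynomial(expression: sp.Expr, symbols: Sequence[sp.Symbol]):
    import numpy as np

    poly = sp.Poly(expression, *symbols)
    exps = np.array([list(m) for m in poly.monoms()], dtype=np.int64)
    coeffs = np.array([float(c) for c in poly.coeffs()])
    # per-term evaluation via exponent masks; exponents are small integers
    def evaluator(*values: float) -> float:
        v = np.asarray(values, dtype=float)
        return float(coeffs @ np.prod(v[None, :] ** exps, axis=1))

    return evaluator
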