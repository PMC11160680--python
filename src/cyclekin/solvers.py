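"""Numerical steady-state solvers for cross-validating symbolic results."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .graph_core import DiagramError, KineticDiagram, rate_name

__all__ = ["SteadyState", "steady_state_matrix", "steady_state_ode", "rmsd"]


@dataclass(frozen=True)
class SteadyState:
    """Steady-state probability vector with solver diagnostics."""

    probabilities: np.ndarray  # aligned with sorted state labels
    states: tuple[int, ...]
    method: str  # "matrix" | "ode" | "symbolic"
    max_dpdt: float
    normalization_error: float

    def as_dict(self) -> dict[int, float]:
        return {s: float(p) for s, p in zip(self.states, self.probabilities)}


def _rate_matrix(diagram: KineticDiagram, rates: Mapping[str, float]) -> np.ndarray:
    """Generator matrix A with dp/dt = A p."""
    states = sorted(diagram.states)
    index = {s: k for k, s in enumerate(states)}
    n = len(states)
    a = np.zeros((n, n))
    for i, j in diagram.directed_edges():
        try:
            k = float(rates[rate_name(i, j)])
        except KeyError:
            raise DiagramError(f"missing numeric rate for {i}->{j}") from None
        if not (np.isfinite(k) and k > 0):
            raise DiagramError(f"rate for {i}->{j} must be positive and finite")
        a[index[j], index[i]] += k
        a[index[i], index[i]] -= k
    return a


def _diagnose(a: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    return float(np.max(np.abs(a @ p))), float(abs(p.sum() - 1.0))


def steady_state_matrix(
    diagram: KineticDiagram, rates: Mapping[str, float]
) -> SteadyState:
    """Solve A p = 0 with the dependent row replaced by normalization.

    The linearly dependent equation is identified from the left singular
    vector of the smallest singular value; singular values below
    1e-12 x the largest beyond rank N-1 indicate a disconnected system.
    """
    a = _rate_matrix(diagram, rates)
    n = a.shape[0]
    u, s, _vt = np.linalg.svd(a)
    if n > 1 and s[-2] <= 1e-12 * s[0]:
        raise DiagramError("rate matrix is rank deficient beyond one dimension")
    dependent = int(np.argmax(np.abs(u[:, -1])))
    m = a.copy()
    b = np.zeros(n)
    m[dependent, :] = 1.0
    b[dependent] = 1.0
    p = np.linalg.solve(m, b)
    max_dpdt, norm_err = _diagnose(a, p)
    return SteadyState(p, tuple(sorted(diagram.states)), "matrix", max_dpdt, norm_err)


def steady_state_ode(
    diagram: KineticDiagram,
    rates: Mapping[str, float],
    p0: Sequence[float] | None = None,
    horizon: float = 1e8,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    dpdt_tol: float = 1e-10,
) -> SteadyState:
    """Integrate the master equations with LSODA until dp/dt vanishes.

    Integration proceeds in expanding time chunks until
    ``max |dp_i/dt| < dpdt_tol * max_rate`` (the achievable residual
    scales with the largest rate in double precision) or `horizon` is
    exhausted (error).
    """
    a = _rate_matrix(diagram, rates)
    n = a.shape[0]
    if p0 is None:
        p = np.full(n, 1.0 / n)
    else:
        p = np.asarray(p0, dtype=float)
        if p.shape != (n,) or abs(p.sum() - 1.0) > 1e-8 or (p < -1e-12).any():
            raise DiagramError("p0 must lie on the probability simplex")
    t = 0.0
    scale = abs(a.diagonal()).max()
    chunk = 1.0 / max(scale, 1e-30)
    tol = dpdt_tol * max(scale, 1.0)
    while np.max(np.abs(a @ p)) >= tol:
        if t >= horizon:
            raise DiagramError(
                f"ODE solver did not converge within horizon; max|dp/dt|="
                f"{np.max(np.abs(a @ p)):.3e}"
            )
        sol = solve_ivp(
            lambda _t, y: a @ y,
            (0.0, chunk),
            p,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            jac=lambda _t, _y: a,
        )
        if not sol.success:
            raise DiagramError(f"ODE integration failed: {sol.message}")
        p = sol.y[:, -1]
        if abs(p.sum() - 1.0) > 1e-9:
            raise DiagramError("probability not conserved during integration")
        t += chunk
        chunk *= 10.0
    max_dpdt, norm_err = _diagnose(a, p)
    return SteadyState(p, tuple(sorted(diagram.states)), "ode", max_dpdt, norm_err)


def rmsd(pa: Sequence[float], pb: Sequence[float]) -> float:
    """Root-mean-square deviation between two probability vectors."""
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((pa - pb) ** 2)))
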