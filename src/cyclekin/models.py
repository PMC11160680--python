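"""Transporter model fixtures, derived-rate helpers, and parameter sweeps.

Three built-in models:

* a 4-state antiporter (driving ion R, substrate L, leak transition 2-4)
  with a fully symbolic parameter map;
* a 6-state Na+/H+ antiporter ring, optionally with a 1-4 leak transition;
* an 8-state drug/proton free-exchange transporter on a cube topology
  (four drug-binding, four proton-binding, four alternating-access
  transitions).

Sweeps vary a leak rate, the alternating-access bias ratio, or the
substrate off-rate bias ratio.  Paired rates vary reciprocally about
fixed geometric-mean anchors so that cycle closure holds at every grid
point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

from .cycle_analysis import (
    Cycle,
    classify_cycle_transport,
    contributing_cycles,
    enumerate_cycles,
)
from .graph_core import DiagramError, KineticDiagram, load_diagram, rate_name
from .symbolic_engine import (
    RateExpressionSet,
    compile_numeric,
    net_cycle_flux_expression,
    state_probability_expressions,
)

__all__ = [
    "ModelParameters",
    "SweepResult",
    "AVOGADRO",
    "build_four_state",
    "build_six_state",
    "build_emre",
    "disk_flux_on_rate",
    "off_rate",
    "pH_to_concentration",
    "sweep_leak",
    "sweep_raa",
    "sweep_roff",
    "dominant_drug_cycle",
]

AVOGADRO = 6.02214076e23
_LITERS_PER_CUBIC_ANGSTROM = 1e-27

# geometric-mean anchors for reciprocal sweep pairs
AA_ANCHOR = 10.0  # s^-1, alternating-access rates
DRUG_OFF_ANCHOR = 10.0  # s^-1
PROTON_OFF_ANCHOR = 1.0e3  # s^-1


def pH_to_concentration(pH: float) -> float:
    """[H+] in molar from pH."""
    return 10.0 ** (-pH)


def disk_flux_on_rate(radius_angstrom: float, diffusion_coeff: float) -> float:
    """Diffusion-limited on-rate 4*R*D*N_A from the flux through a disk.

    `radius_angstrom` in Angstrom, `diffusion_coeff` in Angstrom^2/s;
    result in 1/(M s) using 1 L = 1e27 Angstrom^3.
    """
    if not (radius_angstrom > 0 and diffusion_coeff > 0):
        raise ValueError("radius and diffusion coefficient must be positive")
    return 4.0 * radius_angstrom * diffusion_coeff * AVOGADRO * _LITERS_PER_CUBIC_ANGSTROM


def off_rate(kon: float, mode: str, value: float) -> float:
    """Off-rate from an on-rate and either a pKa or a dissociation constant.

    ``mode="pKa"`` gives ``kon * 10**(-value)``; ``mode="KD"`` gives
    ``kon * value`` (KD in molar).
    """
    if not kon > 0:
        raise ValueError("kon must be positive")
    if mode == "pKa":
        return kon * 10.0 ** (-value)
    if mode == "KD":
        if not value > 0:
            raise ValueError("KD must be positive")
        return kon * value
    raise ValueError(f"unknown mode {mode!r}; expected 'pKa' or 'KD'")


@dataclass(frozen=True)
class ModelParameters:
    """Numeric model parameters: intrinsic rates and concentrations.

    ``intrinsic`` maps directed rate names to concentration-stripped
    values (on-rates in 1/(M s), everything else 1/s);
    ``concentrations`` maps concentration symbols to molar values.
    """

    intrinsic: Mapping[str, float]
    concentrations: Mapping[str, float] = field(default_factory=dict)

    def numeric_rates(self, diagram: KineticDiagram) -> dict[str, float]:
        """Realized first/pseudo-first-order rates for every directed edge."""
        out = {}
        for i, j in diagram.directed_edges():
            name = rate_name(i, j)
            k = self.intrinsic[name]
            ann = diagram.annotation(i, j)
            if ann.order == 2:
                k = k * self.concentrations[ann.concentration]
            out[name] = k
        return out

    def with_rates(self, **updates: float) -> "ModelParameters":
        new = dict(self.intrinsic)
        new.update(updates)
        return replace(self, intrinsic=new)


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-point operational fluxes and stoichiometry."""

    parameter: str
    grid: np.ndarray
    fluxes: Mapping[str, np.ndarray]  # ligand -> flux (1/s), sign-carrying
    stoichiometry: np.ndarray
    cycle_fluxes: Mapping[tuple[int, ...], np.ndarray]  # cycle nodes -> J_K


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def build_four_state() -> tuple[KineticDiagram, dict[str, sp.Expr]]:
    """4-state antiporter with leak transition 2-4.

    States: 1 ion-bound, 2 inward-open empty, 3 substrate-bound,
    4 outward-open empty.  Returns the diagram and the symbolic parameter
    map implementing symmetric binding, unbinding, and leakage rates:
    on/off symbols ``L_on, L_off, R_on, R_off``, concentrations
    ``L_int, L_ext, R_int, R_ext``, and ``k_leak``.
    """
    edges = [
        # R released inside (1->2), bound inside reverse
        {"from": 1, "to": 2, "process": "unbinding", "ligand": "R", "side": "int"},
        {"from": 2, "to": 1, "process": "binding", "ligand": "R", "side": "int",
         "order": 2, "concentration": "R_int"},
        {"from": 2, "to": 3, "process": "binding", "ligand": "L", "side": "int",
         "order": 2, "concentration": "L_int"},
        {"from": 3, "to": 2, "process": "unbinding", "ligand": "L", "side": "int"},
        {"from": 3, "to": 4, "process": "unbinding", "ligand": "L", "side": "ext"},
        {"from": 4, "to": 3, "process": "binding", "ligand": "L", "side": "ext",
         "order": 2, "concentration": "L_ext"},
        {"from": 4, "to": 1, "process": "binding", "ligand": "R", "side": "ext",
         "order": 2, "concentration": "R_ext"},
        {"from": 1, "to": 4, "process": "unbinding", "ligand": "R", "side": "ext"},
        {"from": 2, "to": 4, "process": "leakage"},
        {"from": 4, "to": 2, "process": "leakage"},
    ]
    diagram = load_diagram(edges)
    s = {n: sp.Symbol(n, positive=True) for n in
         ("L_on", "L_off", "R_on", "R_off", "L_int", "L_ext", "R_int", "R_ext", "k_leak")}
    parameter_map = {
        rate_name(1, 2): s["R_off"],
        rate_name(2, 1): s["R_on"] * s["R_int"],
        rate_name(2, 3): s["L_on"] * s["L_int"],
        rate_name(3, 2): s["L_off"],
        rate_name(3, 4): s["L_off"],
        rate_name(4, 3): s["L_on"] * s["L_ext"],
        rate_name(4, 1): s["R_on"] * s["R_ext"],
        rate_name(1, 4): s["R_off"],
        rate_name(2, 4): s["k_leak"],
        rate_name(4, 2): s["k_leak"],
    }
    return diagram, parameter_map


# Na+/H+ antiporter ring parameters
_KON_H = disk_flux_on_rate(5.0, 9.3e11)  # 1.120e10 / (M s)
_KON_NA = disk_flux_on_rate(5.0, 2.5e11)  # 3.011e9 / (M s)
_KOFF_H = off_rate(_KON_H, "pKa", 6.8)  # 1.775e3 / s
_KOFF_NA = off_rate(_KON_NA, "KD", 0.030)  # 9.033e7 / s


def build_six_state(
    with_leak: bool = False, k_leak: float = 1.0
) -> tuple[KineticDiagram, ModelParameters]:
    """6-state Na+/H+ antiporter ring 1-2-3-4-5-6-1, optional 1-4 leak.

    Proton binds outside (1->2), crosses (2<->3), releases inside (3->4);
    sodium binds inside (4->5), crosses (5<->6), releases outside (6->1).
    The positive coupled-cycle direction moves one proton ext -> int and
    one sodium int -> ext.
    """
    edges = [
        {"from": 1, "to": 2, "process": "binding", "ligand": "H", "side": "ext",
         "order": 2, "concentration": "c_H_ext"},
        {"from": 2, "to": 1, "process": "unbinding", "ligand": "H", "side": "ext"},
        {"from": 2, "to": 3, "process": "conformational"},
        {"from": 3, "to": 2, "process": "conformational"},
        {"from": 3, "to": 4, "process": "unbinding", "ligand": "H", "side": "int"},
        {"from": 4, "to": 3, "process": "binding", "ligand": "H", "side": "int",
         "order": 2, "concentration": "c_H_int"},
        {"from": 4, "to": 5, "process": "binding", "ligand": "Na", "side": "int",
         "order": 2, "concentration": "c_Na_int"},
        {"from": 5, "to": 4, "process": "unbinding", "ligand": "Na", "side": "int"},
        {"from": 5, "to": 6, "process": "conformational"},
        {"from": 6, "to": 5, "process": "conformational"},
        {"from": 6, "to": 1, "process": "unbinding", "ligand": "Na", "side": "ext"},
        {"from": 1, "to": 6, "process": "binding", "ligand": "Na", "side": "ext",
         "order": 2, "concentration": "c_Na_ext"},
    ]
    if with_leak:
        edges += [
            {"from": 1, "to": 4, "process": "leakage"},
            {"from": 4, "to": 1, "process": "leakage"},
        ]
    diagram = load_diagram(edges)
    intrinsic = {
        rate_name(1, 2): _KON_H,
        rate_name(2, 1): _KOFF_H,
        rate_name(2, 3): 69.0,
        rate_name(3, 2): 69.0,
        rate_name(3, 4): _KOFF_H,
        rate_name(4, 3): _KON_H,
        rate_name(4, 5): _KON_NA,
        rate_name(5, 4): _KOFF_NA,
        rate_name(5, 6): 350.0,
        rate_name(6, 5): 350.0,
        rate_name(6, 1): _KOFF_NA,
        rate_name(1, 6): _KON_NA,
    }
    if with_leak:
        if not k_leak > 0:
            raise ValueError("k_leak must be positive")
        intrinsic[rate_name(1, 4)] = k_leak
        intrinsic[rate_name(4, 1)] = k_leak
    concentrations = {
        "c_H_ext": pH_to_concentration(5.5),
        "c_H_int": pH_to_concentration(8.5),
        "c_Na_ext": 0.150,
        "c_Na_int": 0.010,
    }
    return diagram, ModelParameters(intrinsic, concentrations)


def build_emre(
    kAA_EH: float = 10.0,
    kAA_ED: float = 10.0,
    kAA_E: float = 10.0,
    kAA_EHD: float = 10.0,
    koff_H_EH: float = 1.0e3,
    koff_H_EHD: float = 1.0e3,
    koff_D_ED: float = 1.0,
    koff_D_EHD: float = 1.0,
) -> tuple[KineticDiagram, ModelParameters]:
    """8-state drug/proton free-exchange transporter (cube topology).

    Outward-facing states: 3 empty, 1 proton-bound, 4 drug-bound,
    2 doubly bound; inward-facing counterparts: 5, 7, 6, 8.  Four
    proton-binding, four drug-binding, and four alternating-access
    transitions give every state exactly three neighbors.

    The default rates are the fixed-parameter column of the model's rate
    table (proton off 1e3/s, drug off 1/s); alternating-access and
    off-rates are overridable for sweeps.
    """
    kon_H, kon_D = 1.0e10, 1.0e7

    def bind(i, j, lig, side, conc):
        return [
            {"from": i, "to": j, "process": "binding", "ligand": lig, "side": side,
             "order": 2, "concentration": conc},
            {"from": j, "to": i, "process": "unbinding", "ligand": lig, "side": side},
        ]

    def conf(i, j):
        return [
            {"from": i, "to": j, "process": "conformational"},
            {"from": j, "to": i, "process": "conformational"},
        ]

    edges = (
        bind(3, 1, "H", "ext", "c_H_ext")
        + bind(5, 7, "H", "int", "c_H_int")
        + bind(4, 2, "H", "ext", "c_H_ext")
        + bind(6, 8, "H", "int", "c_H_int")
        + bind(3, 4, "D", "ext", "c_D_ext")
        + bind(5, 6, "D", "int", "c_D_int")
        + bind(1, 2, "D", "ext", "c_D_ext")
        + bind(7, 8, "D", "int", "c_D_int")
        + conf(1, 7)  # EH
        + conf(4, 6)  # ED
        + conf(3, 5)  # E
        + conf(2, 8)  # EHD
    )
    diagram = load_diagram(edges)
    intrinsic = {
        rate_name(3, 1): kon_H, rate_name(1, 3): koff_H_EH,
        rate_name(5, 7): kon_H, rate_name(7, 5): koff_H_EH,
        rate_name(4, 2): kon_H, rate_name(2, 4): koff_H_EHD,
        rate_name(6, 8): kon_H, rate_name(8, 6): koff_H_EHD,
        rate_name(3, 4): kon_D, rate_name(4, 3): koff_D_ED,
        rate_name(5, 6): kon_D, rate_name(6, 5): koff_D_ED,
        rate_name(1, 2): kon_D, rate_name(2, 1): koff_D_EHD,
        rate_name(7, 8): kon_D, rate_name(8, 7): koff_D_EHD,
        rate_name(1, 7): kAA_EH, rate_name(7, 1): kAA_EH,
        rate_name(4, 6): kAA_ED, rate_name(6, 4): kAA_ED,
        rate_name(3, 5): kAA_E, rate_name(5, 3): kAA_E,
        rate_name(2, 8): kAA_EHD, rate_name(8, 2): kAA_EHD,
    }
    concentrations = {
        "c_H_ext": pH_to_concentration(7.5),
        "c_H_int": pH_to_concentration(6.5),
        "c_D_ext": 25e-9,
        "c_D_int": 25e-9,
    }
    return diagram, ModelParameters(intrinsic, concentrations)


# ---------------------------------------------------------------------------
# numeric flux machinery shared by the sweeps
# ---------------------------------------------------------------------------

class _FluxEvaluator:
    """Compiled cycle-route operational fluxes for one diagram.

    Expressions (state probabilities, cycle flux numerators) are built
    once; each grid point is then a cheap numeric evaluation.
    """

    def __init__(
        self,
        diagram: KineticDiagram,
        ligand_directions: Mapping[str, str],
        expressions: RateExpressionSet | None = None,
    ):
        self.diagram = diagram
        self.symbol_order = tuple(sorted(rate_name(i, j) for i, j in diagram.directed_edges()))
        self.expressions = expressions or state_probability_expressions(diagram)
        self.cycles = enumerate_cycles(diagram)
        self._sigma_fn = compile_numeric(self.expressions.sigma, self.symbol_order)
        self._cycle_fns = {
            cyc.nodes: compile_numeric(
                net_cycle_flux_expression(diagram, cyc, self.expressions).numerator,
                self.symbol_order,
            )
            for cyc in self.cycles
        }
        self._weights: dict[str, list[tuple[tuple[int, ...], int]]] = {}
        for ligand, direction in ligand_directions.items():
            signed = contributing_cycles(diagram, self.cycles, ligand, direction)
            self._weights[ligand] = [(cyc.nodes, w) for cyc, w in signed]

    def _vector(self, rates: Mapping[str, float]) -> list[float]:
        return [rates[name] for name in self.symbol_order]

    def cycle_fluxes(self, rates: Mapping[str, float]) -> dict[tuple[int, ...], float]:
        v = self._vector(rates)
        sigma = float(self._sigma_fn(*v))
        return {nodes: float(fn(*v)) / sigma for nodes, fn in self._cycle_fns.items()}

    def operational_fluxes(self, rates: Mapping[str, float]) -> dict[str, float]:
        jk = self.cycle_fluxes(rates)
        return {
            ligand: sum(w * jk[nodes] for nodes, w in signed)
            for ligand, signed in self._weights.items()
        }


def _stoichiometry(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full_like(num, np.nan)
    nonzero = den != 0
    out[nonzero] = num[nonzero] / den[nonzero]
    return out


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def sweep_leak(k_leak_grid: Sequence[float], control: bool = False) -> SweepResult:
    """6-state antiporter fluxes vs. leak rate.

    With ``control`` the leak-free single-cycle model is evaluated at
    every grid point (fluxes are then independent of the leak rate and
    stoichiometry is identically 1).  Fluxes: H positive ext -> int,
    Na positive int -> ext; stoichiometry is J_Na / J_H.
    """
    grid = np.asarray(list(k_leak_grid), dtype=float)
    if (grid <= 0).any():
        raise ValueError("k_leak grid must be positive")
    diagram, params = build_six_state(with_leak=not control)
    ev = _FluxEvaluator(diagram, {"H": "ext_to_int", "Na": "int_to_ext"})
    jh = np.empty(len(grid))
    jna = np.empty(len(grid))
    per_cycle: dict[tuple[int, ...], list[float]] = {c.nodes: [] for c in ev.cycles}
    for k, k_leak in enumerate(grid):
        p = params
        if not control:
            p = params.with_rates(**{rate_name(1, 4): k_leak, rate_name(4, 1): k_leak})
        rates = p.numeric_rates(diagram)
        jk = ev.cycle_fluxes(rates)
        for nodes, vals in per_cycle.items():
            vals.append(jk[nodes])
        fluxes = ev.operational_fluxes(rates)
        jh[k], jna[k] = fluxes["H"], fluxes["Na"]
    return SweepResult(
        "k_leak", grid, {"H": jh, "Na": jna}, _stoichiometry(jna, jh),
        {n: np.asarray(v) for n, v in per_cycle.items()},
    )


def _emre_sweep(
    grid: np.ndarray, intrinsic_for: "callable"
) -> SweepResult:
    diagram, base = build_emre()
    ev = _FluxEvaluator(diagram, {"H": "int_to_ext", "D": "int_to_ext"})
    jh = np.empty(len(grid))
    jd = np.empty(len(grid))
    per_cycle: dict[tuple[int, ...], list[float]] = {c.nodes: [] for c in ev.cycles}
    for k, r in enumerate(grid):
        params = base.with_rates(**intrinsic_for(r))
        rates = params.numeric_rates(diagram)
        jk = ev.cycle_fluxes(rates)
        for nodes, vals in per_cycle.items():
            vals.append(jk[nodes])
        fluxes = ev.operational_fluxes(rates)
        jh[k], jd[k] = fluxes["H"], fluxes["D"]
    return SweepResult(
        "ratio", grid, {"H": jh, "D": jd}, _stoichiometry(jd, jh),
        {n: np.asarray(v) for n, v in per_cycle.items()},
    )


def sweep_raa(raa_grid: Sequence[float]) -> SweepResult:
    """8-state model fluxes vs. the alternating-access bias ratio.

    Antiport-type rates (ED, EH conformers) are ``anchor * sqrt(R)``,
    symport-type rates (E, EHD) ``anchor / sqrt(R)``; the anchor is
    10/s.  Both ligand fluxes are positive int -> ext; stoichiometry is
    J_D / J_H.
    """
    grid = np.asarray(list(raa_grid), dtype=float)
    if (grid < 1e-8 - 1e-15).any() or (grid > 1e8 + 1e-7).any():
        raise ValueError("R_AA grid must lie within [1e-8, 1e8]")

    def intrinsic_for(r: float) -> dict[str, float]:
        anti = AA_ANCHOR * math.sqrt(r)
        sym = AA_ANCHOR / math.sqrt(r)
        return {
            rate_name(1, 7): anti, rate_name(7, 1): anti,  # EH
            rate_name(4, 6): anti, rate_name(6, 4): anti,  # ED
            rate_name(3, 5): sym, rate_name(5, 3): sym,  # E
            rate_name(2, 8): sym, rate_name(8, 2): sym,  # EHD
        }

    result = _emre_sweep(grid, intrinsic_for)
    return replace(result, parameter="R_AA")


def sweep_roff(roff_grid: Sequence[float], kAA: float = 100.0) -> SweepResult:
    """8-state model fluxes vs. the substrate off-rate bias ratio.

    All four alternating-access rates equal `kAA` (1, 10, 100, or
    1000/s).  Drug off-rates vary reciprocally about 10/s and proton
    off-rates about 1e3/s so that the ratio of the two off-rates in each
    pair equals R_off at every point.
    """
    if kAA not in (1.0, 10.0, 100.0, 1000.0):
        raise ValueError("kAA must be one of 1, 10, 100, 1000 /s")
    grid = np.asarray(list(roff_grid), dtype=float)
    if (grid < 1e-10 * (1 - 1e-9)).any() or (grid > 1e10 * (1 + 1e-9)).any():
        raise ValueError("R_off grid must lie within [1e-10, 1e10]")

    def intrinsic_for(r: float) -> dict[str, float]:
        sqrt_r = math.sqrt(r)
        koff_d_ed = DRUG_OFF_ANCHOR * sqrt_r
        koff_d_ehd = DRUG_OFF_ANCHOR / sqrt_r
        koff_h_eh = PROTON_OFF_ANCHOR * sqrt_r
        koff_h_ehd = PROTON_OFF_ANCHOR / sqrt_r
        return {
            rate_name(4, 3): koff_d_ed, rate_name(6, 5): koff_d_ed,
            rate_name(2, 1): koff_d_ehd, rate_name(8, 7): koff_d_ehd,
            rate_name(1, 3): koff_h_eh, rate_name(7, 5): koff_h_eh,
            rate_name(2, 4): koff_h_ehd, rate_name(8, 6): koff_h_ehd,
            rate_name(1, 7): kAA, rate_name(7, 1): kAA,
            rate_name(4, 6): kAA, rate_name(6, 4): kAA,
            rate_name(3, 5): kAA, rate_name(5, 3): kAA,
            rate_name(2, 8): kAA, rate_name(8, 2): kAA,
        }

    result = _emre_sweep(grid, intrinsic_for)
    return replace(result, parameter="R_off")


def dominant_drug_cycle(
    diagram: KineticDiagram, result: SweepResult, point: int
) -> tuple[tuple[int, ...], float]:
    """Drug-transporting cycle with the largest |net cycle flux| at a sweep point."""
    cycles = {c.nodes: c for c in enumerate_cycles(diagram)}
    best_nodes, best = None, -1.0
    for nodes, jk in result.cycle_fluxes.items():
        sig = classify_cycle_transport(diagram, cycles[nodes])
        if sig["D"] == 0:
            continue
        if abs(jk[point]) > best:
            best_nodes, best = nodes, abs(jk[point])
    if best_nodes is None:
        raise DiagramError("no drug-transporting cycles")
    return best_nodes, best
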