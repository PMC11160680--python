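import numpy as np
import pytest
import sympy as sp

from cyclekin import (
    DiagramError,
    compile_numeric,
    load_diagram,
    net_cycle_flux_expression,
    net_transition_flux_expression,
    operational_flux,
    rate_name,
    state_probability_expressions,
    substitute,
    symbolically_equal,
)
from cyclekin.cycle_analysis import Cycle, canonical_cycle, enumerate_cycles
from cyclekin.symbolic_engine import rate_symbol


def k(i, j):
    return rate_symbol(i, j)


class TestStateProbabilities:
    def test_four_state_omega1_reference_sum(self, four_state_expressions):
        expected = (
            k(2, 1) * k(3, 2) * k(4, 1) + k(2, 1) * k(3, 2) * k(4, 2)
            + k(2, 1) * k(3, 2) * k(4, 3) + k(2, 1) * k(3, 4) * k(4, 1)
            + k(2, 1) * k(3, 4) * k(4, 2) + k(2, 3) * k(3, 4) * k(4, 1)
            + k(2, 4) * k(3, 2) * k(4, 1) + k(2, 4) * k(3, 4) * k(4, 1)
        )
        assert sp.expand(four_state_expressions.omega[1] - expected) == 0

    def test_four_state_term_counts(self, four_state_expressions):
        ex = four_state_expressions
        assert all(ex.term_count(s) == 8 for s in (1, 2, 3, 4))
        assert len(sp.Add.make_args(ex.sigma)) == 32

    def test_triangle_omega1_hand_enumeration(self, triangle):
        ex = state_probability_expressions(triangle)
        expected = k(2, 1) * k(3, 1) + k(3, 2) * k(2, 1) + k(2, 3) * k(3, 1)
        assert sp.expand(ex.omega[1] - expected) == 0

    def test_probabilities_sum_to_one_symbolically(self, four_state_expressions):
        ex = four_state_expressions
        total = sum(ex.probability(s) for s in (1, 2, 3, 4))
        assert sp.simplify(total - 1) == 0

    def test_no_term_mixes_reverse_rates(self, six_state_leak_expressions):
        ex = six_state_leak_expressions
        for s, omega in ex.omega.items():
            for term in sp.Add.make_args(omega):
                names = {sym.name for sym in term.free_symbols}
                for name in names:
                    _, i, j = name.split("_")
                    assert rate_name(int(j), int(i)) not in names

    def test_term_multiset_matches_directional_diagrams(self, four_state):
        from cyclekin import enumerate_directional_diagrams

        diagram = four_state[0]
        ex = state_probability_expressions(diagram)
        for s in diagram.states:
            products = sorted(
                dd.rate_product()
                for dd in enumerate_directional_diagrams(diagram)
                if dd.target == s
            )
            terms = sorted(
                tuple(sorted(sym.name for sym in t.free_symbols))
                for t in sp.Add.make_args(ex.omega[s])
            )
            assert products == terms


class TestCycleFlux:
    def test_cycle_a_expression(self, four_state, four_state_expressions):
        cf = net_cycle_flux_expression(
            four_state[0], Cycle((1, 2, 3, 4), (1, 2)), four_state_expressions)
        expected = k(1, 2) * k(2, 3) * k(3, 4) * k(4, 1) - k(1, 4) * k(4, 3) * k(3, 2) * k(2, 1)
        assert sp.expand(cf.numerator - expected) == 0
        assert cf.feeder_sum == 1

    def test_cycle_b_expression(self, four_state, four_state_expressions):
        cf = net_cycle_flux_expression(
            four_state[0], Cycle((1, 2, 4), (1, 2)), four_state_expressions)
        expected = (k(1, 2) * k(2, 4) * k(4, 1) - k(1, 4) * k(4, 2) * k(2, 1)) * (
            k(3, 2) + k(3, 4))
        assert sp.expand(cf.numerator - expected) == 0

    def test_detailed_balance_zeroes_flux(self, four_state, four_state_expressions):
        # symmetric rates satisfy detailed balance trivially
        diagram = four_state[0]
        cf = net_cycle_flux_expression(
            diagram, Cycle((1, 2, 3, 4), (1, 2)), four_state_expressions)
        names = sorted(rate_name(i, j) for i, j in diagram.directed_edges())
        fn = compile_numeric(cf.numerator, names)
        assert fn(*([2.5] * len(names))) == pytest.approx(0.0, abs=1e-12)


class TestTransitionFlux:
    def test_antisymmetry(self, four_state, four_state_expressions):
        diagram = four_state[0]
        j24 = net_transition_flux_expression(diagram, 2, 4, four_state_expressions)
        j42 = net_transition_flux_expression(diagram, 4, 2, four_state_expressions)
        assert sp.expand(j24 + j42) == 0

    def test_j24_equals_jb_minus_jc(self, four_state, four_state_expressions):
        diagram = four_state[0]
        ex = four_state_expressions
        j24 = net_transition_flux_expression(diagram, 2, 4, ex)
        jb = net_cycle_flux_expression(diagram, Cycle((1, 2, 4), (1, 2)), ex)
        jc = net_cycle_flux_expression(diagram, Cycle((2, 3, 4), (2, 3)), ex)
        assert sp.expand(j24 - (jb.numerator - jc.numerator)) == 0

    def test_j12_equals_ja_plus_jb(self, four_state, four_state_expressions):
        diagram = four_state[0]
        ex = four_state_expressions
        j12 = net_transition_flux_expression(diagram, 1, 2, ex)
        ja = net_cycle_flux_expression(diagram, Cycle((1, 2, 3, 4), (1, 2)), ex)
        jb = net_cycle_flux_expression(diagram, Cycle((1, 2, 4), (1, 2)), ex)
        assert sp.expand(j12 - (ja.numerator + jb.numerator)) == 0

    def test_not_a_transition(self, four_state):
        with pytest.raises(DiagramError, match="not a transition"):
            net_transition_flux_expression(four_state[0], 1, 3)


class TestOperationalFlux:
    def test_four_state_routes_equal(self, four_state, four_state_expressions):
        diagram = four_state[0]
        for ligand, direction in (("L", "int_to_ext"), ("R", "ext_to_int")):
            a = operational_flux(diagram, ligand, "cycles", direction,
                                 four_state_expressions)
            b = operational_flux(diagram, ligand, "transitions", direction,
                                 four_state_expressions)
            ok, how = symbolically_equal(a.numerator, b.numerator)
            assert ok and how == "proved"

    def test_four_state_single_transition_identities(self, four_state,
                                                     four_state_expressions):
        # J_R = J_4,1 = J_1,2 and J_L = J_2,3 = J_3,4
        diagram = four_state[0]
        ex = four_state_expressions
        jr = operational_flux(diagram, "R", "cycles", "ext_to_int", ex)
        for i, j in ((4, 1), (1, 2)):
            jij = net_transition_flux_expression(diagram, i, j, ex)
            assert sp.expand(jr.numerator - jij) == 0
        jl = operational_flux(diagram, "L", "cycles", "int_to_ext", ex)
        for i, j in ((2, 3), (3, 4)):
            jij = net_transition_flux_expression(diagram, i, j, ex)
            assert sp.expand(jl.numerator - jij) == 0

    def test_six_state_leak_routes_equal(self, six_state_leak,
                                         six_state_leak_expressions):
        diagram = six_state_leak[0]
        ex = six_state_leak_expressions
        for ligand, direction in (("H", "ext_to_int"), ("Na", "int_to_ext")):
            a = operational_flux(diagram, ligand, "cycles", direction, ex)
            b = operational_flux(diagram, ligand, "transitions", direction, ex)
            ok, how = symbolically_equal(a.numerator, b.numerator)
            assert ok and how == "proved"

    def test_six_state_sodium_transition_chain(self, six_state_leak,
                                               six_state_leak_expressions):
        # J_Na = J_6,1 = J_5,6 = J_4,5
        diagram = six_state_leak[0]
        ex = six_state_leak_expressions
        jna = operational_flux(diagram, "Na", "cycles", "int_to_ext", ex)
        for i, j in ((6, 1), (5, 6), (4, 5)):
            jij = net_transition_flux_expression(diagram, i, j, ex)
            assert sp.expand(jna.numerator - jij) == 0

    def test_emre_transitions_components(self, emre, emre_expressions):
        diagram = emre[0]
        jh = operational_flux(diagram, "H", "transitions", "int_to_ext",
                              emre_expressions)
        assert set(jh.components) == {("1->3", 1), ("2->4", 1)}
        jd = operational_flux(diagram, "D", "transitions", "int_to_ext",
                              emre_expressions)
        assert set(jd.components) == {("2->1", 1), ("4->3", 1)}

    def test_emre_cycle_route_16_terms(self, emre, emre_expressions):
        diagram = emre[0]
        for ligand in ("H", "D"):
            flux = operational_flux(diagram, ligand, "cycles", "int_to_ext",
                                    emre_expressions)
            assert len(flux.components) == 16

    def test_unannotated_ligand_errors(self, four_state):
        with pytest.raises(DiagramError):
            operational_flux(four_state[0], "Q", "transitions")


class TestSubstitute:
    def test_four_state_p1(self, four_state, four_state_expressions):
        _, pmap = four_state
        sub = substitute(four_state_expressions.omega[1], pmap)
        names = ("L_on", "L_off", "R_on", "R_off", "L_int", "L_ext",
                 "R_int", "R_ext", "k_leak")
        Ln, Lo, Rn, Ro, Li, Le, Ri, Re, kl = (
            sp.Symbol(n, positive=True) for n in names)
        expected = Lo * Rn * (Le * Ln * Ri + Li * Ln * Re + 2 * Re * Ri * Rn
                              + 2 * Re * kl + 2 * Ri * kl)
        assert sp.simplify(sub - expected) == 0

    def test_cycle_a_numerator(self, four_state, four_state_expressions):
        diagram, pmap = four_state
        cf = net_cycle_flux_expression(diagram, Cycle((1, 2, 3, 4), (1, 2)),
                                       four_state_expressions)
        sub = substitute(cf.numerator, pmap)
        names = ("L_on", "L_off", "R_on", "R_off", "L_int", "L_ext",
                 "R_int", "R_ext")
        Ln, Lo, Rn, Ro, Li, Le, Ri, Re = (sp.Symbol(n, positive=True) for n in names)
        expected = Lo * Ln * Ro * Rn * (Li * Re - Le * Ri)
        assert sp.simplify(sub - expected) == 0

    def test_identity_map(self, four_state_expressions):
        expr = four_state_expressions.omega[1]
        assert sp.expand(substitute(expr, {}) - expr) == 0

    def test_partial_map_passthrough(self):
        a, b = sp.symbols("a b", positive=True)
        expr = sp.Symbol("k_1_2", positive=True) * b
        out = substitute(expr, {"k_1_2": a}, simplify=False)
        assert out == a * b


class TestSymbolicallyEqual:
    def test_cycle_a_vs_cycle_b_differ(self, four_state, four_state_expressions):
        diagram = four_state[0]
        ex = four_state_expressions
        ja = net_cycle_flux_expression(diagram, Cycle((1, 2, 3, 4), (1, 2)), ex)
        jb = net_cycle_flux_expression(diagram, Cycle((1, 2, 4), (1, 2)), ex)
        ok, _ = symbolically_equal(ja.numerator, jb.numerator)
        assert not ok

    def test_rational_expressions(self):
        x, y = sp.symbols("x y", positive=True)
        ok, how = symbolically_equal((x ** 2 - y ** 2) / (x - y), x + y)
        assert ok


class TestCompileNumeric:
    def test_triangle_uniform_rates(self, triangle):
        ex = state_probability_expressions(triangle)
        names = sorted(rate_name(i, j) for i, j in triangle.directed_edges())
        for s in (1, 2, 3):
            fn = compile_numeric(ex.omega[s] / ex.sigma, names)
            assert fn(*([1.0] * 6)) == pytest.approx(1 / 3, rel=1e-12)

    def test_normalization_random_rates(self, four_state, four_state_expressions):
        diagram = four_state[0]
        ex = four_state_expressions
        names = sorted(rate_name(i, j) for i, j in diagram.directed_edges())
        rng = np.random.default_rng(3)
        vals = list(10 ** rng.uniform(-2, 2, len(names)))
        total = sum(
            compile_numeric(ex.omega[s] / ex.sigma, names)(*vals)
            for s in diagram.states
        )
        assert total == pytest.approx(1.0, rel=1e-12)

    def test_agrees_with_substitution(self, four_state_expressions):
        ex = four_state_expressions
        names = sorted(s.name for s in ex.omega[2].free_symbols)
        rng = np.random.default_rng(11)
        vals = list(10 ** rng.uniform(-1, 1, len(names)))
        fn = compile_numeric(ex.omega[2], names)
        direct = float(ex.omega[2].subs(
            {sp.Symbol(n, positive=True): v for n, v in zip(names, vals)}))
        assert fn(*vals) == pytest.approx(direct, rel=1e-12)

    def test_large_polynomial_path(self, emre, emre_expressions):
        diagram = emre[0]
        names = sorted(rate_name(i, j) for i, j in diagram.directed_edges())
        fn = compile_numeric(emre_expressions.sigma, names)
        vals = [1.0] * len(names)
        # all rates 1: sigma = number of directional diagrams
        assert fn(*vals) == pytest.approx(8 * 384, rel=1e-12)

    def test_missing_symbol_errors_at_compile(self, four_state_expressions):
        with pytest.raises(DiagramError, match="missing"):
            compile_numeric(four_state_expressions.omega[1], ["k_1_2"])


class TestTransitionCycleConsistency:
    @pytest.mark.parametrize("fixture", ["four_state", "six_state_leak"])
    def test_jij_is_signed_sum_of_cycle_fluxes(self, fixture, request):
        diagram = request.getfixturevalue(fixture)[0]
        ex = request.getfixturevalue(f"{fixture}_expressions")
        cycles = enumerate_cycles(diagram)
        for i, j in diagram.transitions:
            jij = net_transition_flux_expression(diagram, i, j, ex)
            acc = sp.Integer(0)
            for cyc in cycles:
                edges = cyc.directed_edges()
                if (i, j) in edges:
                    sign = 1
                elif (j, i) in edges:
                    sign = -1
                else:
                    continue
                acc += sign * net_cycle_flux_expression(diagram, cyc, ex).numerator
            assert sp.expand(jij - acc) == 0
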