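"""Kinetic scheme validation, mass-action ODE compilation and equilibria."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clampkin.schemes import (
    KineticScheme,
    SchemeError,
    Step,
    compile_rhs,
    derived_constants,
    integrate,
    one_step_binding_scheme,
    two_step_binding_scheme,
)


class TestValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(SchemeError):
            two_step_binding_scheme(-1.0, 1.0, 1.0, 1.0)

    def test_unknown_species_rejected(self):
        with pytest.raises(SchemeError):
            KineticScheme(("E", "S"), (Step(("E", "X"), ("S",), "k"),), {"k": 1.0})

    def test_termolecular_rejected(self):
        with pytest.raises(SchemeError):
            KineticScheme(("A",), (Step(("A", "A", "A"), ("A",), "k"),), {"k": 1.0})

    def test_duplicate_species_rejected(self):
        with pytest.raises(SchemeError):
            KineticScheme(("E", "E"), (), {})

    def test_missing_rate_rejected(self):
        with pytest.raises(SchemeError):
            KineticScheme(("E", "S", "ES"), (Step(("E", "S"), ("ES",), "k1", "k_1"),), {"k1": 1.0})


class TestDerivedConstants:
    def test_two_step_algebra(self):
        # K1 = 5e6/50 = 1e5, K2 = 15/10 = 1.5, Ka = K1(1+K2) = 2.5e5 /M
        d = derived_constants(two_step_binding_scheme(5e6, 50.0, 15.0, 10.0))
        assert d.K1 == pytest.approx(1e5)
        assert d.K2 == pytest.approx(1.5)
        assert d.Ka == pytest.approx(2.5e5)

    def test_single_step_limit(self):
        d = derived_constants(two_step_binding_scheme(5e6, 50.0, 0.0, 10.0))
        assert d.Ka == d.K1

    def test_ka_linear_in_k1(self):
        a = derived_constants(two_step_binding_scheme(5e6, 50.0, 15.0, 10.0))
        b = derived_constants(two_step_binding_scheme(1e7, 50.0, 15.0, 10.0))
        assert b.Ka == pytest.approx(2 * a.Ka)

    def test_zero_reverse_rate_is_error(self):
        with pytest.raises(SchemeError, match="equilibrium undefined"):
            derived_constants(two_step_binding_scheme(5e6, 0.0, 15.0, 10.0))


class TestCompiledRhs:
    def test_bimolecular_rate_at_unit_micromolar(self):
        scheme = KineticScheme(("E", "S", "ES"),
                               (Step(("E", "S"), ("ES",), "k1"),), {"k1": 1e6})
        rhs = compile_rhs(scheme)
        c = rhs.state_to_array({"E": 1e-6, "S": 1e-6})
        dc = rhs.rhs(0.0, c)
        assert dc[rhs.index["ES"]] == pytest.approx(1e-6)

    def test_zero_concentrations_give_zero_bimolecular_flux(self, two_step_scheme):
        rhs = compile_rhs(two_step_scheme)
        dc = rhs.rhs(0.0, rhs.state_to_array({"ES": 1e-6}))
        # only the unimolecular terms involving ES may fire
        assert dc[rhs.index["E"]] == pytest.approx(50.0 * 1e-6)
        assert dc[rhs.index["S"]] == pytest.approx(50.0 * 1e-6)

    def test_rhs_conserves_totals_pointwise(self, two_step_scheme):
        rhs = compile_rhs(two_step_scheme)
        rng = np.random.default_rng(0)
        for _ in range(25):
            c = rng.uniform(0, 1e-5, size=4)
            dc = rhs.rhs(0.0, c)
            i = rhs.index
            assert dc[i["E"]] + dc[i["ES"]] + dc[i["ES*"]] == pytest.approx(0.0, abs=1e-18)
            assert dc[i["S"]] + dc[i["ES"]] + dc[i["ES*"]] == pytest.approx(0.0, abs=1e-18)

    def test_jacobian_matches_finite_differences(self, two_step_scheme):
        rhs = compile_rhs(two_step_scheme)
        c = np.array([1e-6, 2e-6, 5e-7, 1e-7])
        J = rhs.jac(0.0, c)
        for j in range(4):
            h = 1e-12
            cp = c.copy(); cp[j] += h
            col = (rhs.rhs(0.0, cp) - rhs.rhs(0.0, c)) / h
            np.testing.assert_allclose(J[:, j], col, rtol=1e-3, atol=1e-9)


class TestIntegration:
    def test_all_rates_zero_is_constant(self):
        scheme = two_step_binding_scheme(0.0, 0.0, 0.0, 0.0)
        traj = integrate(scheme, {"E": 1e-6, "S": 2e-6}, np.linspace(0.001, 1, 50))
        np.testing.assert_array_equal(traj["E"], np.full(50, 1e-6))
        np.testing.assert_array_equal(traj["ES*"], np.zeros(50))

    def test_times_must_increase(self, two_step_scheme):
        with pytest.raises(ValueError):
            integrate(two_step_scheme, {"E": 1e-6, "S": 1e-6}, [0.1, 0.1, 0.2])

    def test_negative_initial_concentration_rejected(self, two_step_scheme):
        with pytest.raises(SchemeError):
            integrate(two_step_scheme, {"E": -1e-9, "S": 1e-6}, [0.1, 0.2])

    def test_pseudo_first_order_relaxation(self):
        # E0 = 50 * S0: [ES](t) ~ A(1 - exp(-kobs t)) with kobs = k1 E0 + k_1 = 12/s
        scheme = one_step_binding_scheme(1e6, 10.0)
        e0, s0 = 2e-6, 4e-8
        times = np.linspace(1e-4, 1.0, 400)
        traj = integrate(scheme, {"E": e0, "S": s0}, times)
        es = traj["ES"]
        kobs_true = 1e6 * e0 + 10.0
        plateau = es[-1]
        # log-linear fit of the approach to equilibrium
        mask = es < 0.99 * plateau
        slope = np.polyfit(times[mask], np.log(plateau - es[mask]), 1)[0]
        assert -slope == pytest.approx(kobs_true, rel=0.01)

    def test_conservation_along_trajectory(self, two_step_scheme):
        times = np.geomspace(1e-5, 10.0, 200)
        traj = integrate(two_step_scheme, {"E": 3e-6, "S": 1e-6}, times)
        e_tot = traj["E"] + traj["ES"] + traj["ES*"]
        s_tot = traj["S"] + traj["ES"] + traj["ES*"]
        np.testing.assert_allclose(e_tot, 3e-6, rtol=1e-9)
        np.testing.assert_allclose(s_tot, 1e-6, rtol=1e-9)


@st.composite
def rate_sets(draw):
    k1 = draw(st.floats(1e4, 1e7))
    k_1 = draw(st.floats(1e-2, 1e3))
    k2 = draw(st.floats(1e-2, 1e3))
    k_2 = draw(st.floats(1e-2, 1e3))
    return k1, k_1, k2, k_2


class TestEquilibriumOracle:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(rate_sets())
    def test_long_time_equilibrium_matches_derived_constants(self, rates):
        """Integrating to steady state reproduces K1, K2 and Ka to 0.1%."""
        scheme = two_step_binding_scheme(*rates)
        d = derived_constants(scheme)
        # the slow eigenmode can relax far more slowly than the smallest
        # rate constant (drain through a sparsely populated intermediate)
        slowest = min(rates[1], rates[2], rates[3])
        t_end = min(5e3 / slowest, 1e6)
        traj = integrate(scheme, {"E": 2e-6, "S": 1e-6},
                         [t_end * 0.5, t_end], rtol=1e-10, atol=1e-16)
        E, S, ES, ES2 = (traj[s][-1] for s in ("E", "S", "ES", "ES*"))
        assert ES / (E * S) == pytest.approx(d.K1, rel=1e-3)
        assert ES2 / ES == pytest.approx(d.K2, rel=1e-3)
        assert (ES + ES2) / (E * S) == pytest.approx(d.Ka, rel=1e-3)

    def test_reversed_step_labels_leave_equilibrium_unchanged(self):
        fwd = two_step_binding_scheme(5e6, 50.0, 15.0, 10.0)
        rev = KineticScheme(
            fwd.species,
            (fwd.steps[0], fwd.steps[1].reversed()),
            {"k1": 5e6, "k_1": 50.0, "k2": 15.0, "k_2": 10.0},
        )
        times = [100.0, 400.0]
        a = integrate(fwd, {"E": 2e-6, "S": 1e-6}, times)
        b = integrate(rev, {"E": 2e-6, "S": 1e-6}, times)
        for sp in fwd.species:
            np.testing.assert_allclose(a[sp][-1], b[sp][-1], rtol=1e-6)


class TestSerialization:
    def test_round_trip(self, two_step_scheme):
        text = two_step_scheme.to_text()
        back = KineticScheme.from_text(text)
        assert back.species == two_step_scheme.species
        assert back.steps == two_step_scheme.steps
        assert back.rate_constants == dict(two_step_scheme.rate_constants)

    def test_parse_handwritten_scheme(self):
        scheme = KineticScheme.from_text(
            "E + S <-> ES ; k1, k_1\n\n[rates]\nk1 = 2.5e6\nk_1 = 12\n")
        assert scheme.species == ("E", "S", "ES")
        assert scheme.rate_constants["k_1"] == 12.0
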