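"""Kinetic rate laws: examples, analytic oracles and property tests.

The extended Michaelis–Menten law is checked against brute-force
integration of the explicit mass-action binding scheme E+S <-> C -> E+P;
the competitive transcription law against the promoter-occupancy
enumeration it condenses.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from uprkit.rate_laws import (
    EnzymeRateParams,
    HillParams,
    ReceptorKineticParams,
    RegulatorTerm,
    hill_response,
    receptor_fluxes,
    regulation_rate,
    tqssa_rate,
)

finite_pos = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def mass_action_qss_rate(kc, Km, St, Et, kon=100.0):
    """Product-formation rate of E+S <-> C -> E+P at quasi-steady complex.

    The reduced law assumes fast binding equilibration: with association
    rate ``kon`` and (koff + kcat)/kon = Km, kcat = kc, the scheme is
    integrated with product formation recycling substrate (so totals stay
    fixed) until the complex settles; the rate is kcat * C.
    """
    kcat = kc
    koff = Km * kon - kcat
    assert koff >= 0, "oracle requires Km * kon >= kc"

    def f(t, y):
        c = y[0]
        e, s = Et - c, St - c
        return [kon * e * s - (koff + kcat) * c]

    # binding equilibrates on the 1/(kon*(St+Et+Km)) scale; run a couple of
    # decades past it with a stiff-capable solver
    t_eq = 50.0 / (kon * (St + Et + Km))
    sol = solve_ivp(f, (0.0, max(t_eq, 1e-3)), [0.0], method="LSODA",
                    rtol=1e-10, atol=1e-12)
    c = sol.y[0, -1]
    return kcat * c


class TestTqssa:
    def test_no_substrate_gives_zero(self):
        assert tqssa_rate(EnzymeRateParams(1.0, 1.0), 0.0, 5.0) == 0.0

    def test_zero_km_saturates_at_limiting_pool(self):
        # discriminant (2)^2 - 4 = 0: full saturation, rate = kc * min(S, E)
        assert tqssa_rate(EnzymeRateParams(1.0, 0.0), 1.0, 1.0) == pytest.approx(1.0)

    def test_classical_michaelis_menten_limit(self):
        # scarce enzyme: reduces to kc*Et*St/(Km+St)
        p = EnzymeRateParams(1.0, 1.0)
        rate = tqssa_rate(p, 100.0, 1.0)
        assert rate == pytest.approx(100.0 / 101.0, rel=1e-2)
        assert rate == pytest.approx(0.990, abs=5e-3)

    def test_matches_mass_action_oracle(self):
        p = EnzymeRateParams(1.0, 1.0)
        assert tqssa_rate(p, 100.0, 1.0) == pytest.approx(
            mass_action_qss_rate(1.0, 1.0, 100.0, 1.0), rel=0.01
        )

    def test_mass_action_oracle_over_random_parameters(self):
        # validity regime: binding equilibration fast relative to catalysis
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(120):
            kc = rng.uniform(0.1, 2.0)
            Km = rng.uniform(0.2, 20.0)
            St = rng.uniform(0.1, 50.0)
            Et = rng.uniform(0.1, 50.0)
            ref = mass_action_qss_rate(kc, Km, St, Et, kon=200.0)
            got = tqssa_rate(EnzymeRateParams(kc, Km), St, Et)
            if ref > 1e-12:
                worst = max(worst, abs(got - ref) / ref)
        assert worst < 0.05

    @given(kc=finite_pos, Km=finite_pos, St=finite_pos, Et=finite_pos)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_symmetry_and_bounds(self, kc, Km, St, Et):
        p = EnzymeRateParams(kc, Km)
        r = tqssa_rate(p, St, Et)
        assert r == tqssa_rate(p, Et, St)  # exact symmetry
        assert 0.0 <= r <= kc * min(St, Et) * (1 + 1e-12)

    @given(kc=finite_pos, Km=finite_pos, St=finite_pos, Et=finite_pos,
           bump=st.floats(min_value=1e-3, max_value=10.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_in_both_pools(self, kc, Km, St, Et, bump):
        p = EnzymeRateParams(kc, Km)
        base = tqssa_rate(p, St, Et)
        assert tqssa_rate(p, St + bump, Et) >= base - 1e-12
        assert tqssa_rate(p, St, Et + bump) >= base - 1e-12

    def test_scarce_enzyme_reduces_to_classical_within_1pct(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            Km = rng.uniform(0.5, 20.0)
            St = rng.uniform(1.0, 100.0)
            Et = 0.01 * (St + Km) * rng.uniform(0.1, 1.0)
            got = tqssa_rate(EnzymeRateParams(1.0, Km), St, Et)
            classical = Et * St / (Km + St)
            assert got == pytest.approx(classical, rel=0.01)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            tqssa_rate(EnzymeRateParams(1.0, 1.0), -1.0, 1.0)
        with pytest.raises(ValueError):
            EnzymeRateParams(-1.0, 1.0)


def occupancy_rate(regulators):
    """Brute-force promoter-occupancy rate: state weights 1 (free) and
    [TF]_i/Km_i (bound by regulator i); activators transcribe at kc_i."""
    weights = [1.0] + [r.concentration / r.Km for r in regulators]
    rates = [0.0] + [r.kc for r in regulators]
    return sum(w * r for w, r in zip(weights, rates)) / sum(weights)


class TestRegulation:
    def test_empty_set_is_silent(self):
        assert regulation_rate([]) == 0.0

    def test_half_saturation(self):
        act = RegulatorTerm(concentration=3.0, kc=2.0, Km=3.0)
        assert regulation_rate([act]) == pytest.approx(1.0)

    def test_activator_with_repressor_matches_occupancy_enumeration(self):
        act = RegulatorTerm(concentration=1.0, kc=2.0, Km=1.0)
        rep = RegulatorTerm(concentration=1.0, kc=0.0, Km=1.0)
        # occupancy weights 1 : 1 : 1 for free/activator-bound/repressor-bound
        assert regulation_rate([act, rep]) == pytest.approx(2.0 / 3.0)
        assert regulation_rate([act, rep]) == pytest.approx(occupancy_rate([act, rep]))

    @given(st.lists(
        st.tuples(finite_pos, st.floats(min_value=0, max_value=10), finite_pos),
        min_size=1, max_size=6))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_bounded_by_strongest_activator_and_matches_enumeration(self, raw):
        regs = [RegulatorTerm(c, kc, Km) for c, kc, Km in raw]
        rate = regulation_rate(regs)
        assert rate <= max(r.kc for r in regs) + 1e-12
        assert rate == pytest.approx(occupancy_rate(regs), rel=1e-9, abs=1e-12)

    @given(conc=finite_pos, kc=finite_pos, Km=finite_pos,
           rep_conc=finite_pos, extra=finite_pos)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_repressor_never_increases_rate(self, conc, kc, Km, rep_conc, extra):
        act = RegulatorTerm(conc, kc, Km)
        rep = RegulatorTerm(rep_conc, 0.0, 1.0)
        rep_more = RegulatorTerm(rep_conc + extra, 0.0, 1.0)
        assert regulation_rate([act, rep]) <= regulation_rate([act]) + 1e-12
        assert regulation_rate([act, rep_more]) <= regulation_rate([act, rep]) + 1e-12

    def test_lone_activator_saturates_at_its_kc(self):
        rates = [regulation_rate([RegulatorTerm(c, 2.0, 1.0)]) for c in (1e2, 1e5, 1e8)]
        assert rates[-1] == pytest.approx(2.0, rel=1e-6)
        assert all(np.diff(rates) > 0)

    def test_zero_km_rejected(self):
        with pytest.raises(ValueError):
            RegulatorTerm(1.0, 1.0, 0.0)


class TestHill:
    def test_midpoint_is_half(self):
        for h in (1.0, 2.5, 8.0):
            assert hill_response(3.0, HillParams(3.0, h)) == pytest.approx(0.5)

    def test_zero_input_activating(self):
        assert hill_response(0.0, HillParams(2.0, 4.0)) == 0.0

    def test_repressing_at_twice_midpoint(self):
        p = HillParams(5.0, 4.0, "repressing")
        assert hill_response(10.0, p) == pytest.approx(1.0 / 17.0)
        # complementary to the activating branch
        pa = HillParams(5.0, 4.0, "activating")
        assert hill_response(10.0, p) + hill_response(10.0, pa) == pytest.approx(1.0)

    @given(x=st.floats(min_value=0, max_value=1e3), K=finite_pos, h=finite_pos)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_bounded_and_monotone(self, x, K, h):
        p = HillParams(K, h)
        v = hill_response(x, p)
        assert 0.0 <= v <= 1.0
        assert hill_response(x + 1.0, p) >= v - 1e-12

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hill_response(-0.1, HillParams(1.0, 1.0))


class TestReceptorFluxes:
    def test_standard_substitution(self):
        p = ReceptorKineticParams(kf=1.0, kr=1.0, n=2)
        assert receptor_fluxes(p, R=1.0, Ract=0.5) == (1.0, 0.5)

    def test_stabilised_with_zero_strength_equals_standard(self):
        std = ReceptorKineticParams(kf=1.0, kr=1.0, n=2)
        stab = ReceptorKineticParams(kf=1.0, kr=1.0, n=2, ext_stab=0.0,
                                     variant="ufp_stabilised")
        assert receptor_fluxes(stab, 1.0, 0.5, UFP=7.0) == receptor_fluxes(std, 1.0, 0.5)

    def test_direct_variant_needs_ufp(self):
        p = ReceptorKineticParams(kf=5.0, kr=2.0, n=4, variant="direct_ufp")
        assert receptor_fluxes(p, R=3.0, Ract=1.0, UFP=0.0) == (0.0, 2.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ReceptorKineticParams(kf=1.0, kr=1.0, n=2, variant="telepathic")

    def test_conserved_subsystem_steady_state_matches_polynomial_root(self):
        """One receptor with conservation R + n*Ract = T: the steady state
        solves kf*R^n = kr*(T-R)/n; simulation must land on that root."""
        kf, kr, n, total = 2.0, 1.0, 3, 4.0

        def ode(t, y):
            r = y[0]
            ract = (total - r) / n
            vact, vdeact = receptor_fluxes(
                ReceptorKineticParams(kf, kr, n), r, ract)
            return [-n * vact + n * vdeact]

        sol = solve_ivp(ode, (0, 200.0), [total], rtol=1e-12, atol=1e-14)
        r_sim = sol.y[0, -1]
        roots = np.roots([kf * n] + [0.0] * (n - 2) + [kr, -kr * total])
        r_alg = min(r for r in roots.real[np.abs(roots.imag) < 1e-12]
                    if 0 <= r <= total)
        assert r_sim == pytest.approx(r_alg, abs=1e-8)
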