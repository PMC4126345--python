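"""Equilibrium core: binding polynomials, mass balance, polymer statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctpspoly import (
    Conditions,
    ThermoParams,
    binding_polynomials,
    filament_length_distribution,
    mean_filament_length,
    solve_equilibrium,
)
from conftest import truncated_sums


class TestBindingPolynomials:
    def test_empty_ligands_identity(self, simple_params):
        P_f, P_p = binding_polynomials(simple_params, Conditions())
        assert (P_f, P_p) == (1.0, 1.0)

    def test_competitive_unit_occupancy(self, simple_params):
        cond = Conditions(U=simple_params.K_uf, C=simple_params.K_cf)
        P_f, _ = binding_polynomials(simple_params, cond)
        assert P_f == pytest.approx(3.0, rel=1e-15)

    def test_noncompetitive_factorizes(self, simple_params):
        p = simple_params.replace(mechanism="noncompetitive")
        cond = Conditions(U=p.K_uf, C=p.K_cf)
        P_f, _ = binding_polynomials(p, cond)
        assert P_f == pytest.approx(4.0, rel=1e-15)

    def test_polymer_polynomial_only_sees_ctp(self, simple_params):
        _, P_p = binding_polynomials(simple_params, Conditions(U=1e4, C=simple_params.K_cp))
        assert P_p == pytest.approx(2.0, rel=1e-15)


class TestSolveEquilibrium:
    def test_empty_system(self, simple_params):
        st_ = solve_equilibrium(simple_params, Conditions(E_tot=0.0))
        assert st_.b == 0.0 and st_.M_poly == 0.0 and st_.a == 0.0

    def test_saturating_substrate_nonpolymerizing(self, simple_params):
        p = simple_params.replace(polymerizing=False)
        st_ = solve_equilibrium(p, Conditions(U=1000 * p.K_uf, C=0.0, E_tot=1.0))
        assert st_.a >= 0.999
        assert st_.kcat_obs == pytest.approx(p.k_max, rel=2e-3)

    def test_bare_ladder_root_matches_truncated_sum_oracle(self):
        # K_e = 1, E_nuc = 0, no ligands: b solves b + b^2(2-b)/(1-b)^2 = 0.5,
        # verified against direct summation of n*z^n up to n = 1e6 (= 2 - sqrt(3))
        p = ThermoParams(K_uf=1.0, K_cf=1.0, K_cp=0.5, K_e=1.0, E_nuc=0.0, k_max=0.0)
        st_ = solve_equilibrium(p, Conditions(U=0.0, C=0.0, E_tot=0.5))
        assert st_.b == pytest.approx(0.2679491924311227, rel=1e-8)
        m_sum, _ = truncated_sums(st_.z, p.K_e, p.sigma)
        assert st_.M_poly == pytest.approx(m_sum, rel=1e-8)

    @pytest.mark.filterwarnings("ignore::ctpspoly.params.LinkageDirectionWarning")
    def test_mass_balance_and_bounds_random_draws(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(100):
            p = ThermoParams(
                K_uf=10 ** rng.uniform(0, 3), K_cf=10 ** rng.uniform(0, 3),
                K_cp=10 ** rng.uniform(-1, 3), K_e=10 ** rng.uniform(-2, 2),
                E_nuc=rng.uniform(0, 12), k_max=10.0,
            )
            cond = Conditions(U=10 ** rng.uniform(-1, 4), C=10 ** rng.uniform(-1, 4),
                              E_tot=10 ** rng.uniform(-2, 2))
            st_ = solve_equilibrium(p, cond)
            assert abs(st_.f + st_.M_poly - cond.E_tot) <= 1e-9 * max(cond.E_tot, 1.0)
            assert 0.0 <= st_.z < 1.0
            assert 0.0 <= st_.a <= 1.0
            assert st_.M_poly >= 0.0 and st_.N_fil >= 0.0
            if st_.z < 0.99 and st_.M_poly > 0:
                m_sum, n_sum = truncated_sums(st_.z, p.K_e, p.sigma)
                assert st_.M_poly == pytest.approx(m_sum, rel=1e-8)
                assert st_.N_fil == pytest.approx(n_sum, rel=1e-8)
                n_checked += 1
        assert n_checked >= 20  # the draw ranges must actually exercise polymer

    def test_nonpolymerizing_closed_forms_both_mechanisms(self):
        # a huge nucleation barrier reproduces the no-polymer active
        # fractions below the critical concentration (E_tot/P_f < K_e/P_p)
        for mech in ("competitive", "noncompetitive"):
            p = ThermoParams(K_uf=100.0, K_cf=50.0, K_cp=10.0, K_e=1.0,
                             E_nuc=500.0, k_max=1.0, mechanism=mech)
            cond = Conditions(U=250.0, C=75.0, E_tot=0.4)
            st_ = solve_equilibrium(p, cond)
            u, c = cond.U / p.K_uf, cond.C / p.K_cf
            if mech == "competitive":
                expected = u / (1 + u + c)
            else:
                expected = u / (1 + u) / (1 + c)
            assert abs(st_.a - expected) < 1e-10

    def test_huge_barrier_above_critical_pins_free_pool(self):
        # above the critical concentration the sigma -> 0 limit pins the
        # reference species at K_e/P_p; all excess enzyme sits in filaments
        p = ThermoParams(K_uf=100.0, K_cf=50.0, K_cp=10.0, K_e=1.0,
                         E_nuc=500.0, k_max=1.0)
        cond = Conditions(U=250.0, C=75.0, E_tot=5.0)
        _, P_p = binding_polynomials(p, cond)
        st_ = solve_equilibrium(p, cond)
        assert st_.b == pytest.approx(p.K_e / P_p, rel=1e-9)
        assert abs(st_.f + st_.M_poly - cond.E_tot) <= 1e-9 * cond.E_tot
        assert st_.M_poly > 1.0 and st_.mean_len > 1e6 and st_.z < 1.0

    def test_polymerizing_false_keeps_everything_free(self, simple_params):
        p = simple_params.replace(polymerizing=False)
        st_ = solve_equilibrium(p, Conditions(U=50.0, C=20.0, E_tot=7.0))
        assert st_.M_poly == 0.0 and st_.f == 7.0

    @settings(max_examples=30, deadline=None)
    @given(C=st.floats(0.0, 1000.0), E_tot=st.floats(0.01, 50.0))
    def test_mass_balance_property(self, C, E_tot):
        p = ThermoParams(K_uf=100.0, K_cf=50.0, K_cp=10.0, K_e=1.0,
                         E_nuc=2.0, k_max=5.0)
        st_ = solve_equilibrium(p, Conditions(U=100.0, C=C, E_tot=E_tot))
        assert abs(st_.f + st_.M_poly - E_tot) <= 1e-9 * max(E_tot, 1.0)


class TestLinkageMonotonicity:
    def test_polymer_fraction_nondecreasing_in_ctp(self, simple_params):
        fracs = [solve_equilibrium(simple_params, Conditions(U=100.0, C=C, E_tot=5.0)).frac_poly
                 for C in np.linspace(0, 500, 30)]
        assert np.all(np.diff(fracs) >= -1e-12)

    def test_polymer_fraction_nondecreasing_in_enzyme(self, simple_params):
        fracs = [solve_equilibrium(simple_params, Conditions(U=100.0, C=50.0, E_tot=E)).frac_poly
                 for E in np.linspace(0.01, 30, 30)]
        assert np.all(np.diff(fracs) >= -1e-12)

    def test_substrate_antagonizes_assembly(self, simple_params):
        # filaments disassemble as UTP is added at fixed CTP
        fracs = [solve_equilibrium(simple_params, Conditions(U=U, C=100.0, E_tot=10.0)).frac_poly
                 for U in np.linspace(0, 2000, 25)]
        assert fracs[0] > 0.1
        assert np.all(np.diff(fracs) <= 1e-12)


class TestLengthDistribution:
    def test_requires_two_tetramers(self, simple_params):
        st_ = solve_equilibrium(simple_params, Conditions(U=0, C=100, E_tot=10))
        with pytest.raises(ValueError):
            filament_length_distribution(st_, simple_params, n_max=1)

    def test_nonpolymerizing_state_is_empty(self, simple_params):
        p = simple_params.replace(polymerizing=False)
        st_ = solve_equilibrium(p, Conditions(U=0, C=100, E_tot=10))
        assert len(filament_length_distribution(st_, p, n_max=100)) == 0

    def test_geometric_ratio_is_z(self, simple_params):
        st_ = solve_equilibrium(simple_params, Conditions(U=0, C=100, E_tot=10))
        dist = filament_length_distribution(st_, simple_params, n_max=50)
        ratios = dist[1:, 1] / dist[:-1, 1]
        np.testing.assert_allclose(ratios, st_.z, rtol=1e-13)

    def test_partial_sum_approaches_mass_within_tail_bound(self, simple_params):
        st_ = solve_equilibrium(simple_params, Conditions(U=0, C=100, E_tot=10))
        n_max = 2000
        dist = filament_length_distribution(st_, simple_params, n_max=n_max)
        partial = float(np.sum(dist[:, 0] * dist[:, 1]))
        z, K_e, sigma = st_.z, simple_params.K_e, simple_params.sigma
        # tail of sum n z^n beyond n_max in closed form
        tail = K_e * sigma * (z ** (n_max + 1)) * (
            (n_max + 1) / (1 - z) + z / (1 - z) ** 2)
        assert st_.M_poly - partial <= tail * (1 + 1e-9) + 1e-300
        assert st_.M_poly >= partial


class TestMeanLength:
    def test_undefined_without_polymer(self, simple_params):
        st_ = solve_equilibrium(simple_params.replace(polymerizing=False),
                                Conditions(U=0, C=100, E_tot=10))
        with pytest.raises(ValueError):
            mean_filament_length(st_)

    def test_matches_moment_ratio_oracle(self, simple_params):
        st_ = solve_equilibrium(simple_params, Conditions(U=0, C=100, E_tot=10))
        m_sum, n_sum = truncated_sums(st_.z, simple_params.K_e, simple_params.sigma)
        assert mean_filament_length(st_) == pytest.approx(m_sum / n_sum, rel=1e-8)

    def test_closed_form_limits(self):
        # z -> 0+ gives the minimal filament of 2; z = 0.5 gives 3 exactly
        from ctpspoly.equilibrium import EquilibriumState
        mk = lambda z: EquilibriumState(b=0, f=0, z=z, M_poly=1.0, N_fil=1.0,
                                        mean_len=0, frac_poly=0, a=0, kcat_obs=0)
        assert mean_filament_length(mk(1e-12)) == pytest.approx(2.0, abs=1e-9)
        assert mean_filament_length(mk(0.5)) == pytest.approx(3.0, rel=1e-12)

    def test_solver_reports_mean_len_consistent_with_ratio(self, simple_params):
        st_ = solve_equilibrium(simple_params, Conditions(U=0, C=100, E_tot=10))
        assert st_.mean_len == pytest.approx(st_.M_poly / st_.N_fil, rel=1e-12)
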