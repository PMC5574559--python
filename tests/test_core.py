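import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laternula_deb import (Forcing, OrganismState, compute_fluxes, integrate,
                           observables, reserve_density_dynamics, respiration,
                           temp_correction)


def _closed_form_correction(T, arr):
    # independent scalar evaluation of the boundary-corrected Arrhenius ratio
    def s(Tv):
        return math.exp(-arr.T_A / Tv) / (1.0 + math.exp(arr.T_AL / Tv - arr.T_AL / arr.T_L))
    return s(T) / s(arr.T_ref)


class TestTempCorrection:
    def test_identity_at_reference(self, params):
        assert temp_correction(273.15, params.arr) == pytest.approx(1.0, abs=1e-12)

    def test_one_degree_above_reference(self, params):
        expected = _closed_form_correction(274.15, params.arr)
        assert expected == pytest.approx(1.164, abs=2e-3)
        assert temp_correction(274.15, params.arr) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_up_to_warm_side(self, params):
        T = np.linspace(params.arr.T_L, params.arr.T_ref + 25.0, 400)
        c = temp_correction(T, params.arr)
        assert np.all(np.diff(c) > 0)
        assert temp_correction(params.arr.T_L + 1e-6, params.arr) < 1.0

    def test_non_positive_temperature_rejected(self, params):
        with pytest.raises(ValueError):
            temp_correction(0.0, params.arr)


@st.composite
def adult_states(draw):
    L = draw(st.floats(0.2, 8.0))
    e = draw(st.floats(0.05, 1.0))
    return L, e


class TestFluxes:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(state=adult_states(), f=st.floats(0.0, 1.0), dT=st.floats(-2.0, 5.0))
    def test_kappa_rule_conservation(self, params, state, f, dT):
        """The kappa-rule split is exactly conservative whenever maintenance is covered."""
        L, e = state
        V = L**3
        st_ = OrganismState(t=0.0, V=V, E=e * params.compound.E_m * V, E_H=params.E_Hp)
        fx = compute_fluxes(st_, f, params.arr.T_ref + dT, params)
        if fx.p_deficit == 0.0 and fx.p_G > 0.0:
            assert fx.p_M_flux + fx.p_G == pytest.approx(params.kappa * fx.p_C, rel=1e-9)
            assert fx.p_J + fx.p_R == pytest.approx((1 - params.kappa) * fx.p_C, rel=1e-9)
        assert fx.p_G >= 0.0 and fx.p_R >= 0.0 and fx.p_deficit >= 0.0

    def test_growth_stops_at_ultimate_size(self, params):
        f = 0.5
        L = f * params.compound.L_m
        V = L**3
        st_ = OrganismState(t=0.0, V=V, E=f * params.compound.E_m * V, E_H=params.E_Hp)
        fx = compute_fluxes(st_, f, params.arr.T_ref, params)
        assert fx.p_G == pytest.approx(0.0, abs=1e-8 * fx.p_C)

    def test_pre_birth_state_does_not_assimilate(self, params):
        st_ = OrganismState(t=0.0, V=1e-3, E=1.0, E_H=params.E_Hb / 2)
        fx = compute_fluxes(st_, 1.0, params.arr.T_ref, params)
        assert fx.p_A == 0.0


class TestReserveDynamics:
    def test_equilibrium_is_zero(self, params):
        assert reserve_density_dynamics(0.5, 0.5, 3.0, 274.0, params) == 0.0

    def test_rate_equals_energy_conductance_at_unit_length(self, params):
        # empty reserve, full food, L = 1 cm at T_ref: de/dt = v = 0.023 d^-1
        assert reserve_density_dynamics(0.0, 1.0, 1.0, params.arr.T_ref, params) \
            == pytest.approx(0.023)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(e=st.floats(0.0, 1.5), f=st.floats(0.0, 1.0), L=st.floats(0.05, 8.0))
    def test_relaxation_sign(self, params, e, f, L):
        rate = reserve_density_dynamics(e, f, L, 273.0, params)
        assert np.sign(rate) == np.sign(f - e)

    def test_non_positive_length_rejected(self, params):
        with pytest.raises(ValueError):
            reserve_density_dynamics(0.5, 0.5, 0.0, 273.0, params)


def _adult_at(params, f, frac_of_ult=0.5):
    L = frac_of_ult * f * params.compound.L_m
    V = L**3
    return OrganismState(t=0.0, V=V, E=f * params.compound.E_m * V, E_H=params.E_Hp)


class TestIntegrate:
    def test_growth_approaches_ultimate_length_monotonically(self, params):
        f, T = 0.6, 274.15
        state0 = _adult_at(params, f, frac_of_ult=0.2)
        forcing = Forcing.constant(f, T, 25000.0)
        traj = integrate(state0, forcing, params,
                         t_eval=np.linspace(0, 25000, 400))
        L = traj["V"] ** (1 / 3)
        assert np.all(np.diff(L) > -1e-9)
        assert L[-1] == pytest.approx(f * params.compound.L_m, rel=0.01)

    def test_reproduction_buffer_linear_at_stable_size(self, params):
        f, T = 0.4, 273.15
        state0 = _adult_at(params, f, frac_of_ult=1.0)
        forcing = Forcing.constant(f, T, 400.0)
        t_eval = np.linspace(0, 400, 81)
        traj = integrate(state0, forcing, params, t_eval=t_eval)
        rates = np.diff(traj["E_R"]) / np.diff(traj["t"])
        assert np.ptp(rates) / np.mean(rates) < 1e-4

    def test_starvation_preserves_structure_and_drains_reserve(self, params):
        # fed individual at the size its reserve supports; food then vanishes
        state0 = _adult_at(params, 0.8, frac_of_ult=1.0)
        forcing = Forcing.constant(0.0, 273.15, 400.0)
        traj = integrate(state0, forcing, params, t_eval=np.linspace(0, 400, 50))
        assert np.all(np.diff(traj["E"]) < 0)
        assert traj["V"][-1] == pytest.approx(state0.V, rel=1e-6)  # no growth, no shrinkage

    def test_reserve_density_matches_relaxation_equation(self, params):
        # at (nearly) fixed structural length, finite differences of the
        # simulated e reproduce de/dt = (f - e) v_T / L
        f, T = 0.9, 273.15
        state0 = _adult_at(params, 0.3, frac_of_ult=1.0)
        state0 = OrganismState(t=0.0, V=state0.V, E=0.3 * params.compound.E_m * state0.V,
                               E_H=params.E_Hp)
        t_eval = np.linspace(0.0, 10.0, 101)
        traj = integrate(state0, Forcing.constant(f, T, 10.0), params, t_eval=t_eval)
        e = traj["E"] / (params.compound.E_m * traj["V"])
        L = traj["V"] ** (1 / 3)
        dedt_fd = np.gradient(e, t_eval)
        dedt_eq = reserve_density_dynamics(e, f, L, T, params)
        assert np.max(np.abs(dedt_fd - dedt_eq)) < 5e-4  # O(dt) agreement

    def test_forcing_gap_raises(self, params):
        state0 = _adult_at(params, 0.5)
        forcing = Forcing.constant(0.5, 273.15, 10.0)
        with pytest.raises(ValueError):
            integrate(state0, forcing, params, t_eval=np.array([0.0, 50.0]))


class TestObservables:
    def test_empty_reserve_leaves_structural_mass(self, params):
        st_ = OrganismState(t=0.0, V=8.0, E=0.0, E_H=params.E_Hp)
        obs = observables(st_, params)
        assert obs["gonadfree_afdw"] == pytest.approx(params.d_V * 8.0)

    def test_reserve_share_at_full_density(self, params):
        comp = params.compound
        share = params.rho_E * comp.E_m / (params.d_V + params.rho_E * comp.E_m)
        assert share == pytest.approx(0.65, abs=0.02)
        V = 8.0
        st_ = OrganismState(t=0.0, V=V, E=comp.E_m * V, E_H=params.E_Hp)
        obs = observables(st_, params)
        assert params.rho_E * st_.E / obs["gonadfree_afdw"] == pytest.approx(share)

    def test_larval_shape_coefficient_used_before_metamorphosis(self, params):
        st_ = OrganismState(t=0.0, V=0.14**3, E=1.0, E_H=params.E_Hb)
        obs = observables(st_, params, pre_metamorphic=True)
        assert obs["shell_length"] == pytest.approx(0.14 / params.delta_M_lrv)


class TestRespiration:
    def test_starved_individual_ignores_assimilation_flag(self, params):
        st_ = _adult_at(params, 0.5)
        fx = compute_fluxes(st_, 0.0, 273.15, params)
        off = respiration(fx, include_assimilation=False)
        on = respiration(fx, include_assimilation=True)
        assert off == on

    def test_increases_with_temperature(self, params):
        st_ = _adult_at(params, 0.5)
        powers = [respiration(compute_fluxes(st_, 0.5, T, params))["power"]
                  for T in np.linspace(271.0, 276.0, 11)]
        assert np.all(np.diff(powers) > 0)

    def test_size_scaling_between_surface_and_volume(self, params):
        e, T = 0.5, 273.15
        comp = params.compound
        small = OrganismState(t=0, V=1.0, E=e * comp.E_m, E_H=params.E_Hp)
        big = OrganismState(t=0, V=8.0, E=e * comp.E_m * 8.0, E_H=params.E_Hp)
        r_small = respiration(compute_fluxes(small, e, T, params))["power"]
        r_big = respiration(compute_fluxes(big, e, T, params))["power"]
        assert 4.0 < r_big / r_small < 8.0

    def test_proportional_in_fluxes(self, params):
        st_ = _adult_at(params, 0.5)
        fx = compute_fluxes(st_, 0.5, 273.15, params)
        import dataclasses
        doubled = dataclasses.replace(fx, **{k: 2 * getattr(fx, k) for k in
                                             ("p_A", "p_C", "p_M_flux", "p_J", "p_G", "p_R")})
        assert respiration(doubled, True)["power"] == \
            pytest.approx(2 * respiration(fx, True)["power"])
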