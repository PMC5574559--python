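"""Life-stage event solvers and zero-variate predictors.

Covers the embryo (maternal-provisioned, non-feeding), the birth and
puberty maturity thresholds, ultimate size under constant food, and the
table of zero-variate predictions (ages, lengths, weights, gonadosomatic
index) that summarise the parameter set against single observed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import Fluxes, OrganismState, compute_fluxes, temp_correction
from .params import DEBParams

__all__ = [
    "ZeroVariatePrediction",
    "initial_reserve",
    "age_length_at_birth",
    "age_length_at_puberty",
    "ultimate_size",
    "gsi",
    "zero_variate_table",
]

_V0 = 1e-12  # embryo start volume (cm^3); early growth is linear in L so the
             # choice only shifts the birth age by O(V0^(1/3))


@dataclass(frozen=True)
class ZeroVariatePrediction:
    """One row of the zero-variate comparison table."""

    name: str
    observed: float
    predicted: float
    units: str
    temperature: float | None
    f_used: float | None

    @property
    def mre(self) -> float:
        return abs(self.predicted - self.observed) / abs(self.observed)


def _embryo_rhs(t, y, params: DEBParams, c_T: float):
    V, E, E_H = y
    V = max(V, _V0)
    E = max(E, 0.0)
    L = V ** (1.0 / 3.0)
    E_density = E / V
    v = params.v * c_T
    p_M = params.p_M * c_T
    k_J = params.k_J * c_T
    p_C = E_density * (params.E_G * v * L**2 + p_M * V) / (params.E_G + params.kappa * E_density)
    dV = max(params.kappa * p_C - p_M * V, 0.0) / params.E_G
    dE_H = (1.0 - params.kappa) * p_C - k_J * E_H
    return [dV, -p_C, dE_H]


def _integrate_embryo(E_0: float, T: float, params: DEBParams):
    """Run the embryo to the birth threshold; return (a_b, V_b, E_b) or None."""
    c_T = temp_correction(T, params.arr)

    def birth(t, y, *args):
        return y[2] - params.E_Hb
    birth.terminal = True
    birth.direction = 1.0

    sol = solve_ivp(_embryo_rhs, (0.0, 20000.0), [_V0, E_0, 0.0],
                    args=(params, c_T), method="LSODA", rtol=1e-8, atol=1e-12,
                    events=birth)
    if not sol.success:
        raise RuntimeError(f"embryo integration failed: {sol.message}")
    if len(sol.t_events[0]) == 0:
        return None
    a_b = float(sol.t_events[0][0])
    V_b, E_b, _ = sol.y_events[0][0]
    return a_b, float(V_b), float(E_b)


def initial_reserve(f_mother: float, params: DEBParams, T: float | None = None) -> float:
    """Initial egg reserve E_0 (J) such that reserve density at birth equals f_mother.

    The maternal-effect rule: the mother provisions the egg so that the
    scaled reserve density of the hatchling matches the food level she
    experienced.  Solved by root bracketing on the embryo integration.
    """
    if not 0 < f_mother <= 1:
        raise ValueError("f_mother must lie in (0, 1]")
    if T is None:
        T = params.arr.T_ref
    E_m = params.compound.E_m

    def e_birth_gap(E_0: float) -> float:
        result = _integrate_embryo(E_0, T, params)
        if result is None:  # reserve ran out before birth
            return -f_mother
        _, V_b, E_b = result
        return E_b / (E_m * V_b) - f_mother

    lo, hi = 1e-3, 1.0
    while e_birth_gap(hi) < 0:
        hi *= 4.0
        if hi > 1e9:
            raise RuntimeError("initial-reserve search failed to bracket")
    while e_birth_gap(lo) > 0:
        lo /= 4.0
        if lo < 1e-12:
            raise RuntimeError("initial-reserve search failed to bracket")
    return float(brentq(e_birth_gap, lo, hi, rtol=1e-6))


def age_length_at_birth(f_mother: float, T: float, params: DEBParams):
    """Age at birth (d), structural length at birth (cm) and physical D-larva length (cm).

    Birth is the onset of feeding: the first crossing of the maturity
    threshold E_Hb.  The egg is provisioned by ``initial_reserve``; the
    physical larval length converts structural length with the D-larva
    shape coefficient.
    """
    E_0 = initial_reserve(f_mother, params, T)
    result = _integrate_embryo(E_0, T, params)
    if result is None:
        raise RuntimeError("embryo failed to reach birth at the solved E_0")
    a_b, V_b, _ = result
    L_b = V_b ** (1.0 / 3.0)
    return a_b, L_b, L_b / params.delta_M_lrv


def age_length_at_puberty(f: float, T: float, params: DEBParams):
    """Age (d, from birth) and structural length (cm) at the puberty threshold.

    Integrates the post-birth system at constant (f, T) from a hatchling in
    reserve equilibrium (e = f).  Raises if maturation stalls below E_Hp,
    which happens when maturity maintenance consumes the entire
    maturation flux at the asymptotic size for this f.
    """
    if not 0 < f <= 1:
        raise ValueError("f must lie in (0, 1]")
    c_T = temp_correction(T, params.arr)
    comp = params.compound
    _, L_b, _ = age_length_at_birth(f, T, params)
    V_b = L_b**3

    def rhs(t, y):
        V, E, E_H = y
        state = OrganismState(t=t, V=V, E=max(E, 0.0), E_H=min(E_H, params.E_Hp))
        fx = compute_fluxes(state, f, T, params, validate=False)
        return [fx.p_G / params.E_G, fx.p_A - fx.p_C, fx.p_R]

    def puberty(t, y):
        return y[2] - params.E_Hp
    puberty.terminal = True
    puberty.direction = 1.0

    # generous horizon: several maintenance time scales at this temperature
    horizon = 50.0 / (comp.k_M * c_T)
    sol = solve_ivp(rhs, (0.0, horizon), [V_b, f * comp.E_m * V_b, params.E_Hb],
                    method="LSODA", rtol=1e-8, atol=1e-10, events=puberty)
    if not sol.success:
        raise RuntimeError(f"juvenile integration failed: {sol.message}")
    if len(sol.t_events[0]) == 0:
        raise RuntimeError(f"puberty unreachable at f = {f}: maturation stalled below E_Hp")
    a_p = float(sol.t_events[0][0])
    V_p = float(sol.y_events[0][0][0])
    return a_p, V_p ** (1.0 / 3.0)


def ultimate_size(f: float, params: DEBParams):
    """Asymptotic structural length f*L_m and physical shell length (cm)."""
    if not 0 <= f <= 1:
        raise ValueError("f must lie in [0, 1]")
    L_inf = f * params.compound.L_m
    return L_inf, L_inf / params.delta_M


def gsi(params: DEBParams, f: float, T: float, accumulation_days: float,
        *, wet_over_dry_body: float = 6.0, wet_over_dry_gonad: float = 4.79) -> float:
    """Gonadosomatic index: gonad wet weight over total wet weight.

    An individual at ultimate size for the given food level accumulates
    the reproduction flux for ``accumulation_days``; dry masses are
    converted to wet with configurable wet:dry factors (the model itself
    carries no water, so GSI magnitudes are indicative only).
    """
    if accumulation_days < 0:
        raise ValueError("accumulation_days must be non-negative")
    L_inf, _ = ultimate_size(f, params)
    V = L_inf**3
    comp = params.compound
    state = OrganismState(t=0.0, V=V, E=f * comp.E_m * V, E_H=params.E_Hp)
    fx = compute_fluxes(state, f, T, params)
    if fx.p_R <= 0:
        import warnings
        warnings.warn("reproduction flux non-positive at these inputs; GSI = 0")
        return 0.0
    E_R = params.kappa_R * fx.p_R * accumulation_days
    gonad_wet = params.rho_E * E_R * wet_over_dry_gonad
    body_wet = (params.d_V * V + params.rho_E * state.E) * wet_over_dry_body
    return gonad_wet / (gonad_wet + body_wet)


# Observed zero-variate values with units, assay temperatures and source site.
_ZERO_VARIATE_OBS = {
    "a_b": (23.0, "d", 274.15, "R"),
    "a_p": (730.0, "d", 274.15, "MC"),
    "L_b": (0.02, "cm", 274.15, "R"),
    "L_p": (2.87, "cm", None, "MC"),
    "L_i": (8.7, "cm", None, "MC"),
    "dW_p": (0.18, "g", None, "MC"),
    "dW_i": (3.21, "g", None, "MC"),
    "GSI": (0.22, "-", 272.7, "MC"),
}


def zero_variate_table(params: DEBParams, f_map: dict[str, float],
                       T_map: dict[str, float] | None = None) -> list[ZeroVariatePrediction]:
    """Predict all eight zero-variate quantities and their relative errors.

    ``f_map`` supplies per-site scaled functional responses keyed "MC",
    "PC", "R" (developmental rows use the Rothera level, size- and
    weight-linked rows the Marian Cove level).  ``T_map`` may override the
    default assay temperatures per row name.
    """
    T_map = T_map or {}
    rows: list[ZeroVariatePrediction] = []

    def site_f(site: str, row: str) -> float:
        if site not in f_map:
            raise ValueError(f"missing scaled functional response for site {site!r} "
                             f"needed by row {row!r}")
        return f_map[site]

    for name, (obs, units, T_default, site) in _ZERO_VARIATE_OBS.items():
        f = site_f(site, name)
        T = T_map.get(name, T_default)
        if name == "a_b":
            pred, _, _ = age_length_at_birth(f, T, params)
        elif name == "L_b":
            _, _, pred = age_length_at_birth(f, T, params)
        elif name == "a_p":
            pred, _ = age_length_at_puberty(f, T, params)
        elif name == "L_p":
            _, L_p = age_length_at_puberty(f, T_map.get("a_p", 274.15), params)
            pred = L_p / params.delta_M
        elif name == "L_i":
            _, pred = ultimate_size(f, params)
        elif name in ("dW_p", "dW_i"):
            if name == "dW_p":
                _, L = age_length_at_puberty(f, T_map.get("a_p", 274.15), params)
            else:
                L, _ = ultimate_size(f, params)
            V = L**3
            state = OrganismState(t=0.0, V=V, E=f * params.compound.E_m * V,
                                  E_H=params.E_Hp)
            from .core import observables
            pred = observables(state, params)["gonadfree_afdw"]
        elif name == "GSI":
            pred = gsi(params, f, T, 365.0)
        rows.append(ZeroVariatePrediction(name=name, observed=obs, predicted=pred,
                                          units=units, temperature=T, f_used=f))
    return rows
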