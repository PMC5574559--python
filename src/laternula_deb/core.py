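"""Standard-DEB state equations for an isomorphic individual.

State variables follow the standard Dynamic Energy Budget model: reserve
energy ``E`` (J), structural volume ``V`` (cm^3), maturity ``E_H`` (J) and,
after puberty, the reproduction buffer ``E_R`` (J).  Assimilation scales
with structural surface area and the scaled functional response ``f`` in
[0, 1]; mobilised energy is split by the kappa-rule between the soma
(somatic maintenance + growth) and the maturity/reproduction branch.

All physiological rates are stated at the reference temperature and scaled
by a boundary-corrected Arrhenius factor; the response has no upper branch
because the species never experiences warm water.

Starvation is handled conservatively: when the somatic share of the
mobilisation flux cannot cover somatic maintenance, the deficit is paid
first from the maturity/reproduction flux and then from the reproduction
buffer; structure never shrinks and gonad accretion halts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import ArrheniusParams, DEBParams

__all__ = [
    "OrganismState",
    "Fluxes",
    "Forcing",
    "temp_correction",
    "compute_fluxes",
    "reserve_density_dynamics",
    "integrate",
    "observables",
    "respiration",
]


@dataclass(frozen=True)
class OrganismState:
    """Instantaneous DEB state: age t (d), V (cm^3), E (J), E_H (J), E_R (J)."""

    t: float
    V: float
    E: float
    E_H: float
    E_R: float = 0.0

    def validate(self, params: DEBParams, *, post_birth: bool = True) -> None:
        if post_birth and self.V <= 0:
            raise ValueError("structural volume V must be > 0 after birth")
        if self.V < 0 or self.E < 0:
            raise ValueError("V and E must be non-negative")
        if not 0 <= self.E_H <= params.E_Hp * (1 + 1e-12):
            raise ValueError("maturity E_H must lie in [0, E_Hp]")
        if self.E_R < 0:
            raise ValueError("reproduction buffer E_R must be non-negative")
        if self.E_H < params.E_Hp and self.E_R > 0:
            raise ValueError("E_R must be zero before puberty")

    @property
    def L(self) -> float:
        """Structural length V^(1/3) (cm)."""
        return self.V ** (1.0 / 3.0)


@dataclass(frozen=True)
class Fluxes:
    """Instantaneous powers (J d^-1).

    ``p_deficit`` is the residual somatic-maintenance shortfall (after the
    reproduction flux has been redirected) that the integrator pays from
    the reproduction buffer; it is zero for a well-fed individual.
    """

    p_A: float
    p_C: float
    p_M_flux: float
    p_J: float
    p_G: float
    p_R: float
    p_deficit: float = 0.0


@dataclass(frozen=True)
class Forcing:
    """Daily environmental forcing: temperature (K) and scaled functional response.

    ``times`` are days (strictly increasing); temperature is interpolated
    linearly, ``f`` is held piecewise-constant over each day.
    """

    times: np.ndarray
    T: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        T = np.asarray(self.T, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "f", f)
        if not (len(times) == len(T) == len(f)):
            raise ValueError("times, T and f must have equal length")
        if len(times) < 1:
            raise ValueError("forcing must contain at least one sample")
        if np.any(np.diff(times) <= 0):
            raise ValueError("forcing times must be strictly increasing")
        if np.any(T <= 0):
            raise ValueError("temperatures must be positive (kelvin)")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("scaled functional response must lie in [0, 1]")

    def T_at(self, t: float | np.ndarray) -> float | np.ndarray:
        return np.interp(t, self.times, self.T)

    def f_at(self, t: float | np.ndarray) -> float | np.ndarray:
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, len(self.times) - 1)
        return self.f[idx]

    @classmethod
    def constant(cls, f: float, T: float, t_end: float, t_start: float = 0.0) -> "Forcing":
        times = np.arange(np.floor(t_start), np.ceil(t_end) + 1.0)
        return cls(times=times, T=np.full_like(times, T), f=np.full_like(times, f))


def temp_correction(T, arr: ArrheniusParams):
    """Dimensionless Arrhenius rate multiplier s(T)/s(T_ref).

    Uses the three-parameter form with a lower boundary only:
    ``s(T) = exp(-T_A/T) / (1 + exp(T_AL/T - T_AL/T_L))``.
    Equals 1 at the reference temperature and increases with T.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    def s(Tv):
        return np.exp(-arr.T_A / Tv) / (1.0 + np.exp(arr.T_AL / Tv - arr.T_AL / arr.T_L))
    out = s(T) / s(arr.T_ref)
    return float(out) if out.ndim == 0 else out


def compute_fluxes(state: OrganismState, f: float, T: float, params: DEBParams,
                   *, validate: bool = True) -> Fluxes:
    """Evaluate all DEB powers at a state under forcing (f, T).

    Assimilation ``p_A = {p_Am} L^2 f`` is on only after birth
    (``E_H >= E_Hb``).  Mobilisation uses the standard isomorph closed form
    ``p_C = (E/V) (E_G v L^2 + p_M V) / (E_G + kappa E/V)`` with
    temperature-corrected rates.  Under starvation the kappa-rule split is
    overridden: growth stops, the somatic deficit is taken from the
    maturity/reproduction flux and any remainder is reported as
    ``p_deficit`` for the reproduction buffer to pay.
    """
    if validate:
        state.validate(params, post_birth=False)
    if not 0 <= f <= 1:
        raise ValueError("scaled functional response f must lie in [0, 1]")
    c_T = temp_correction(T, params.arr)
    p_Am = params.p_Am * c_T
    v = params.v * c_T
    p_M = params.p_M * c_T
    k_J = params.k_J * c_T

    V = state.V
    L = state.L
    E_density = state.E / V if V > 0 else 0.0

    p_A = p_Am * L**2 * f if state.E_H >= params.E_Hb else 0.0
    p_C = E_density * (params.E_G * v * L**2 + p_M * V) / (params.E_G + params.kappa * E_density)
    p_M_flux = p_M * V
    p_J = k_J * min(state.E_H, params.E_Hp)

    p_G = params.kappa * p_C - p_M_flux
    p_R = (1.0 - params.kappa) * p_C - p_J
    deficit = 0.0
    if p_G < 0.0:
        # somatic maintenance shortfall: halt growth, divert p_R, then E_R
        deficit = -p_G
        p_G = 0.0
        take = min(max(p_R, 0.0), deficit)
        p_R = max(p_R, 0.0) - take
        deficit -= take
    elif p_R < 0.0:
        # maturity maintenance shortfall: halt reproduction, pay from E_R
        deficit = -p_R
        p_R = 0.0
    return Fluxes(p_A=p_A, p_C=p_C, p_M_flux=p_M_flux, p_J=p_J,
                  p_G=p_G, p_R=p_R, p_deficit=deficit)


def reserve_density_dynamics(e, f, L, T, params: DEBParams):
    """Rate of change of the scaled reserve density: de/dt = (f - e) v_T / L.

    The scaled reserve ``e = E / (E_m V)`` relaxes towards the scaled
    functional response with time constant ``L / v_T``; it is the relation
    inverted by the seasonal food reconstruction.
    """
    e = np.asarray(e, dtype=float)
    f = np.asarray(f, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("structural length L must be positive")
    if np.any(e < 0):
        raise ValueError("scaled reserve e must be non-negative")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("scaled functional response f must lie in [0, 1]")
    out = (f - e) * params.v * temp_correction(T, params.arr) / L
    return float(out) if out.ndim == 0 else out


def _rhs(t: float, y: np.ndarray, forcing: Forcing, params: DEBParams) -> list[float]:
    V, E, E_H, E_R = y
    state = OrganismState(t=t, V=max(V, 1e-30), E=max(E, 0.0),
                          E_H=min(max(E_H, 0.0), params.E_Hp), E_R=max(E_R, 0.0))
    fx = compute_fluxes(state, float(forcing.f_at(t)), float(forcing.T_at(t)),
                        params, validate=False)
    dV = fx.p_G / params.E_G
    dE = fx.p_A - fx.p_C
    if E_H < params.E_Hp:
        dE_H = fx.p_R
        dE_R = 0.0
    else:
        dE_H = 0.0
        # drain ramps down over the last joule of buffer so the RHS stays
        # continuous at E_R = 0 (avoids solver chattering at the boundary)
        drain = fx.p_deficit * min(1.0, max(E_R, 0.0))
        dE_R = params.kappa_R * fx.p_R - drain
    return [dV, dE, dE_H, dE_R]


def integrate(state0: OrganismState, forcing: Forcing, params: DEBParams,
              t_eval: np.ndarray | None = None, rtol: float = 1e-8):
    """Integrate the DEB state equations under a forcing series.

    Returns a record array-like dict of trajectories evaluated at ``t_eval``
    (default: the forcing times covered by the integration window).
    Maturity thresholds (birth, puberty) are located by the solver's event
    root-finding, and the integration is restarted there so the switch in
    the equations stays sharp.
    """
    state0.validate(params, post_birth=state0.E_H >= params.E_Hb)
    if t_eval is None:
        t_eval = forcing.times
    t_eval = np.asarray(t_eval, dtype=float)
    t0, t1 = float(t_eval[0]), float(t_eval[-1])
    if t0 < forcing.times[0] - 1e-9 or t1 > forcing.times[-1] + 1e-9:
        raise ValueError("requested interval extends beyond the forcing span")

    events = []

    def birth(t, y, *args):
        return y[2] - params.E_Hb
    birth.terminal = True
    birth.direction = 1.0

    def puberty(t, y, *args):
        return y[2] - params.E_Hp
    puberty.terminal = True
    puberty.direction = 1.0

    y = np.array([state0.V, state0.E, state0.E_H, state0.E_R], dtype=float)
    t = t0
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    while t < t1 - 1e-12:
        if y[2] < params.E_Hb:
            events = [birth]
        elif y[2] < params.E_Hp:
            events = [puberty]
        else:
            events = []
        seg_eval = t_eval[(t_eval >= t) & (t_eval <= t1)]
        sol = solve_ivp(_rhs, (t, t1), y, args=(forcing, params), method="LSODA",
                        rtol=rtol, atol=1e-10, t_eval=seg_eval if len(seg_eval) else None,
                        events=events, dense_output=True)
        if not sol.success:
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        if sol.t_events and any(len(te) for te in sol.t_events):
            t_stop = float(sol.t_events[0][0])
            keep = sol.t < t_stop - 1e-12 if len(sol.t) else np.array([], bool)
            ts.append(sol.t[keep])
            ys.append(sol.y[:, keep])
            y = sol.sol(t_stop)
            y[2] = params.E_Hb if events[0] is birth else params.E_Hp
            t = t_stop
        else:
            ts.append(sol.t)
            ys.append(sol.y)
            t = t1
            y = sol.y[:, -1] if sol.y.shape[1] else y
    if ts:
        t_all = np.concatenate(ts)
        y_all = np.concatenate(ys, axis=1)
    else:  # degenerate zero-length window
        t_all = np.array([t0])
        y_all = y[:, None]
    y_all = np.clip(y_all, 0.0, None)
    traj = {
        "t": t_all,
        "V": y_all[0],
        "E": y_all[1],
        "E_H": np.minimum(y_all[2], params.E_Hp),
        "E_R": y_all[3],
    }
    return traj


def observables(state: OrganismState, params: DEBParams,
                *, pre_metamorphic: bool = False) -> dict[str, float]:
    """Map a DEB state to measurable quantities.

    Shell length uses the post-metamorphic shape coefficient (or the
    D-larva coefficient when ``pre_metamorphic``); masses are g AFDW with
    structure at density ``d_V`` and reserve/gonad converted by ``rho_E``.
    """
    state.validate(params, post_birth=False)
    delta = params.delta_M_lrv if pre_metamorphic else params.delta_M
    L = state.L
    gonadfree = params.d_V * state.V + params.rho_E * state.E
    gonad = params.rho_E * state.E_R
    return {
        "shell_length": L / delta,
        "gonadfree_afdw": gonadfree,
        "gonad_afdw": gonad,
        "total_afdw": gonadfree + gonad,
    }


def respiration(fluxes: Fluxes, include_assimilation: bool = False,
                *, kappa_G: float = 0.8, eta_A: float = 0.1,
                joules_per_mg_o2: float = 16.4) -> dict[str, float]:
    """Dissipation-based respiration proxy.

    Sums somatic and maturity maintenance plus the overhead of growth
    (fraction ``1 - kappa_G`` of the growth flux) and, if
    ``include_assimilation``, a fraction ``eta_A`` of the assimilation flux.
    The oxygen-equivalent rate divides by a configurable oxycalorific
    coefficient (J per mg O2; default from the reserve chemical potential
    with a standard stoichiometry).  Output is proportional to the fluxes.
    """
    power = fluxes.p_M_flux + fluxes.p_J + (1.0 - kappa_G) * fluxes.p_G
    if include_assimilation:
        power += eta_A * fluxes.p_A
    return {"power": power, "mg_O2_per_d": power / joules_per_mg_o2}
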