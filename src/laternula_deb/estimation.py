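"""Parameter estimation: Arrhenius fit, shape fit, and the covariation method.

The covariation method fits many DEB parameters at once to a heterogeneous
collection of observations — zero-variate data (single observed quantities
such as ultimate length) and uni-variate data (paired series such as
length–weight or respiration–temperature) — by minimising a weighted
relative least-squares criterion with a Nelder–Mead simplex.  Weakly
identified parameters can be stabilised by pseudo-data: soft quadratic
pulls toward prior values.  Goodness of fit is summarised by the mean
absolute relative error (MRE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, minimize

from .core import OrganismState, compute_fluxes, respiration, temp_correction
from .params import ArrheniusParams, DEBParams

__all__ = [
    "UniVariateData",
    "ZeroVariateData",
    "PseudoData",
    "CalibrationDataset",
    "FitResult",
    "mre",
    "fit_arrhenius",
    "fit_shape",
    "predict_dataset",
    "covariation_fit",
]

_UNI_KINDS = ("length_weight", "size_at_age", "respiration_size", "respiration_temperature")


@dataclass
class UniVariateData:
    """A paired (x, y) calibration series.

    kind: one of length_weight (shell length cm -> gonad-free AFDW g),
    size_at_age (age d from birth -> shell length cm), respiration_size
    (shell length cm -> metabolic power J/d) or respiration_temperature
    (temperature K -> metabolic power J/d at a fixed shell length).
    """

    kind: str
    x: np.ndarray
    y: np.ndarray
    temperature: float | None = None
    f: float = 1.0
    population: str = ""
    weight: float = 1.0
    shell_length: float | None = None     # respiration_temperature only
    include_assimilation: bool = False    # respiration kinds
    L_0: float | None = None              # size_at_age: structural length at age 0

    def __post_init__(self) -> None:
        if self.kind not in _UNI_KINDS:
            raise ValueError(f"unsupported uni-variate kind: {self.kind!r}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")
        if self.weight < 0:
            raise ValueError("weights must be non-negative")


@dataclass
class ZeroVariateData:
    """A single observed quantity (name as in the zero-variate table)."""

    name: str
    observed: float
    units: str = ""
    temperature: float | None = None
    f: float = 1.0
    weight: float = 1.0


@dataclass
class PseudoData:
    """Soft prior pull on a parameter used by the covariation loss."""

    name: str
    value: float
    weight: float = 0.1


@dataclass
class CalibrationDataset:
    zero_variates: list[ZeroVariateData] = field(default_factory=list)
    uni_variates: list[UniVariateData] = field(default_factory=list)
    pseudo_data: list[PseudoData] = field(default_factory=list)


@dataclass
class FitResult:
    params: DEBParams
    loss: float
    mre_total: float
    mre_by_dataset: dict[str, float]
    n_iter: int
    converged: bool


def mre(pred, obs) -> float:
    """Mean absolute relative error mean(|pred - obs| / |obs|)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have the same shape")
    if np.any(obs == 0):
        raise ValueError("observations must be non-zero for a relative error")
    return float(np.mean(np.abs(pred - obs) / np.abs(obs)))


def fit_arrhenius(T, scaled_rate, T_ref: float = 273.15,
                  *, start: tuple[float, float, float] | None = None):
    """Nonlinear least squares for the lower-boundary Arrhenius curve.

    ``scaled_rate`` are rates divided by the rate at ``T_ref`` (so the curve
    passes through 1 there by construction).  Returns the fitted
    :class:`ArrheniusParams` and a dict of standard errors.
    """
    T = np.asarray(T, dtype=float)
    rate = np.asarray(scaled_rate, dtype=float)
    if len(T) < 4:
        raise ValueError("need at least 4 points to fit three Arrhenius parameters")

    def model(Tv, T_A, T_AL, T_L):
        arr = ArrheniusParams(T_A=T_A, T_AL=T_AL, T_L=T_L, T_ref=T_ref)
        return temp_correction(Tv, arr)

    p0 = start if start is not None else (8000.0, 50000.0, float(np.min(T)) - 1.0)
    # the boundary temperature lies at or below the coldest assay temperature;
    # leaving it free up to T_ref lets it trade off against T_A
    T_L_cap = min(float(np.min(T)) + 1.0, T_ref - 1e-6)
    bounds = ([1.0, 1.0, 1.0], [1e6, 1e7, T_L_cap])
    try:
        popt, pcov = curve_fit(model, T, rate, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Arrhenius fit did not converge: {exc}") from exc
    if not np.all(np.isfinite(pcov)):
        raise RuntimeError("Arrhenius fit unidentifiable: singular covariance "
                           f"(condition of J'J not finite); estimates {popt}")
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    arr = ArrheniusParams(T_A=popt[0], T_AL=popt[1], T_L=popt[2], T_ref=T_ref)
    resid = rate - model(T, *popt)
    return arr, {"se_T_A": se[0], "se_T_AL": se[1], "se_T_L": se[2],
                 "rss": float(np.sum(resid**2))}


def fit_shape(L_w, W_d, weights=None):
    """Weighted least squares for W_d = (delta_M * L_w)^3.

    Linear in delta_M^3 against L_w^3, solved in closed form; the default
    weights 1/W_d^2 make the criterion a relative one.  Returns
    (delta_M, sd) with the dispersion propagated from the slope.
    """
    L_w = np.asarray(L_w, dtype=float)
    W_d = np.asarray(W_d, dtype=float)
    if L_w.shape != W_d.shape or len(L_w) < 3:
        raise ValueError("need equal-length arrays with at least 3 points")
    if np.any(L_w <= 0) or np.any(W_d <= 0):
        raise ValueError("lengths and weights must be positive")
    w = np.full_like(W_d, 1.0) / W_d**2 if weights is None else np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    x = L_w**3
    sxx = np.sum(w * x * x)
    slope = np.sum(w * x * W_d) / sxx  # = delta_M^3
    if slope <= 0:
        raise ValueError("non-positive slope: data inconsistent with a cubic law")
    resid = W_d - slope * x
    dof = max(np.count_nonzero(w) - 1, 1)
    var_slope = np.sum(w * resid**2) / dof / sxx
    delta = slope ** (1.0 / 3.0)
    sd = np.sqrt(var_slope) / (3.0 * slope ** (2.0 / 3.0))
    return float(delta), float(sd)


def _growth_rate_vb(params: DEBParams, f: float, c_T: float) -> float:
    """von Bertalanffy rate of the constant-environment standard model (d^-1)."""
    comp = params.compound
    g = params.E_G / (params.kappa * comp.E_m)
    return comp.k_M * c_T * g / (3.0 * (f + g))


def _length_at_age(age, params: DEBParams, f: float, T: float, L_0: float) -> np.ndarray:
    """Structural length at age from birth under constant (f, T), e = f.

    Exact solution of the reduced growth equation
    dL/dt = r_B (f L_m - L); structure never shrinks, so growth floors at
    the larger of L_0 and the asymptote.
    """
    age = np.asarray(age, dtype=float)
    c_T = temp_correction(T, params.arr)
    r_B = _growth_rate_vb(params, f, c_T)
    L_inf = f * params.compound.L_m
    if L_inf <= L_0:
        return np.full_like(age, L_0)
    return L_inf + (L_0 - L_inf) * np.exp(-r_B * age)


def _birth_length_newborn(params: DEBParams) -> float:
    """Maintenance-free approximation of the structural length at birth.

    Ignoring the (small) maintenance drains, the kappa-rule ties structure
    built to maturation invested: E_G V_b / kappa = E_Hb / (1 - kappa),
    so V_b = kappa E_Hb / ((1 - kappa) E_G).  Used as the cheap growth-curve
    anchor inside the covariation loss; the embryo solver gives the exact
    value (difference < 1%).
    """
    V_b = params.kappa * params.E_Hb / ((1.0 - params.kappa) * params.E_G)
    return V_b ** (1.0 / 3.0)


def predict_dataset(params: DEBParams, ds: UniVariateData, L_b: float | None = None) -> np.ndarray:
    """Forward-model predictions aligned to a uni-variate dataset's x values."""
    comp = params.compound
    T = ds.temperature if ds.temperature is not None else params.arr.T_ref
    if ds.kind == "length_weight":
        L = params.delta_M * ds.x
        return L**3 * (params.d_V + params.rho_E * ds.f * comp.E_m)
    if ds.kind == "size_at_age":
        L_0 = L_b if L_b is not None else (
            ds.L_0 if ds.L_0 is not None else _birth_length_newborn(params))
        L = _length_at_age(ds.x, params, ds.f, T, L_0)
        return L / params.delta_M
    if ds.kind in ("respiration_size", "respiration_temperature"):
        if ds.kind == "respiration_size":
            lengths = ds.x
            temps = np.full_like(ds.x, T)
        else:
            if ds.shell_length is None:
                raise ValueError("respiration_temperature requires shell_length")
            lengths = np.full_like(ds.x, ds.shell_length)
            temps = ds.x
        out = np.empty_like(lengths)
        for i, (Lw, Tv) in enumerate(zip(lengths, temps)):
            L = params.delta_M * Lw
            V = L**3
            state = OrganismState(t=0.0, V=V, E=ds.f * comp.E_m * V, E_H=params.E_Hp)
            fx = compute_fluxes(state, ds.f if ds.include_assimilation else 0.0,
                                float(Tv), params, validate=False)
            out[i] = respiration(fx, ds.include_assimilation)["power"]
        return out
    raise ValueError(f"unsupported dataset kind: {ds.kind!r}")


def _predict_zero_variate(params: DEBParams, zv: ZeroVariateData) -> float:
    from . import lifecycle
    T = zv.temperature if zv.temperature is not None else params.arr.T_ref
    comp = params.compound
    if zv.name == "L_i":
        return lifecycle.ultimate_size(zv.f, params)[1]
    if zv.name == "dW_i":
        L = zv.f * comp.L_m
        return L**3 * (params.d_V + params.rho_E * zv.f * comp.E_m)
    if zv.name == "a_b":
        return lifecycle.age_length_at_birth(zv.f, T, params)[0]
    if zv.name == "L_b":
        return lifecycle.age_length_at_birth(zv.f, T, params)[2]
    if zv.name == "a_p":
        return lifecycle.age_length_at_puberty(zv.f, T, params)[0]
    if zv.name == "L_p":
        return lifecycle.age_length_at_puberty(zv.f, T, params)[1] / params.delta_M
    if zv.name == "dW_p":
        L = lifecycle.age_length_at_puberty(zv.f, T, params)[1]
        return L**3 * (params.d_V + params.rho_E * zv.f * comp.E_m)
    if zv.name == "GSI":
        return lifecycle.gsi(params, zv.f, T, 365.0)
    raise ValueError(f"unsupported zero-variate name: {zv.name!r}")


_LOGIT_PARAMS = {"kappa", "kappa_R"}  # constrained to (0, 1)


def _to_internal(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        return np.log(value / (1.0 - value))
    return np.log(value)


def _from_internal(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        return 1.0 / (1.0 + np.exp(-value))
    return np.exp(value)


def _dataset_label(i: int, ds: UniVariateData) -> str:
    pop = f":{ds.population}" if ds.population else ""
    return f"{ds.kind}{pop}#{i}"


def covariation_fit(data: CalibrationDataset, start: DEBParams,
                    free: list[str] | tuple[str, ...] | set[str],
                    *, max_evals: int = 5000, xtol: float = 1e-6) -> FitResult:
    """Covariation-method parameter estimation.

    Minimises the weighted relative least-squares loss

        sum_datasets weight * mean((pred - obs)^2 / obs^2)
            + sum_pseudo weight * ((p - prior)/prior)^2

    over the ``free`` parameter names with a Nelder–Mead simplex in a
    transformed space (log for positive parameters, logit for fractions),
    restarting once if the simplex collapses before convergence.
    """
    free = list(free)
    valid = {"p_Am", "p_M", "E_G", "kappa", "v", "k_J", "E_Hb", "E_Hp",
             "delta_M", "delta_M_lrv", "d_V", "kappa_R", "T_A", "T_AL", "T_L"}
    unknown = set(free) - valid
    if unknown:
        raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")

    def build(theta: np.ndarray) -> DEBParams:
        updates = {name: _from_internal(name, t) for name, t in zip(free, theta)}
        return start.with_updates(**updates)

    def loss_fn(theta: np.ndarray) -> float:
        try:
            p = build(theta)
        except Exception:
            return 1e12
        total = 0.0
        for zv in data.zero_variates:
            try:
                pred = _predict_zero_variate(p, zv)
            except Exception:
                return 1e12
            total += zv.weight * (pred - zv.observed) ** 2 / zv.observed**2
        for ds in data.uni_variates:
            pred = predict_dataset(p, ds)
            total += ds.weight * float(np.mean((pred - ds.y) ** 2 / ds.y**2))
        for pd in data.pseudo_data:
            val = p.get(pd.name)
            total += pd.weight * ((val - pd.value) / pd.value) ** 2
        return total

    def report(p: DEBParams, loss: float, n_iter: int, converged: bool) -> FitResult:
        by_ds: dict[str, float] = {}
        all_rel: list[np.ndarray] = []
        for zv in data.zero_variates:
            pred = _predict_zero_variate(p, zv)
            rel = np.array([abs(pred - zv.observed) / abs(zv.observed)])
            by_ds[f"zero:{zv.name}"] = float(rel[0])
            all_rel.append(rel)
        for i, ds in enumerate(data.uni_variates):
            pred = predict_dataset(p, ds)
            rel = np.abs(pred - ds.y) / np.abs(ds.y)
            by_ds[_dataset_label(i, ds)] = float(np.mean(rel))
            all_rel.append(rel)
        total = float(np.mean(np.concatenate(all_rel))) if all_rel else 0.0
        return FitResult(params=p, loss=loss, mre_total=total,
                         mre_by_dataset=by_ds, n_iter=n_iter, converged=converged)

    if not free:
        return report(start, loss_fn(np.array([])), 0, True)

    theta0 = np.array([_to_internal(name, start.get(name)) for name in free])
    budget = max_evals
    best = None
    n_iter = 0
    for attempt in range(2):
        res = minimize(loss_fn, theta0, method="Nelder-Mead",
                       options={"maxfev": budget, "xatol": xtol, "fatol": xtol**2,
                                "adaptive": len(free) > 2})
        n_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        # restart from the collapsed simplex location with the remaining budget
        theta0 = res.x
        budget = max(budget - res.nfev, 200)
    return report(build(best.x), float(best.fun), n_iter, bool(best.success))
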