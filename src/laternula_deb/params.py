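"""Parameter containers for the standard DEB model of *Laternula elliptica*.

The model keeps the conventional split between *primary* parameters (the
quantities the estimation procedure acts on) and *compound* parameters that
are always recomputed from the primary set.  All rates are stated at the
reference temperature ``T_ref`` and corrected at run time through the
Arrhenius relation in :mod:`laternula_deb.core`.

Internal units are strict: energies in J, lengths in cm, masses in g
ash-free dry weight (AFDW), times in days, temperatures in kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ArrheniusParams",
    "DEBParams",
    "CompoundParams",
    "load_params",
    "default_params",
    "ParamFileError",
]


class ParamFileError(ValueError):
    """Raised when a parameter file is malformed or violates an invariant."""


@dataclass(frozen=True)
class ArrheniusParams:
    """Three-parameter Arrhenius temperature response (lower boundary only).

    Parameters
    ----------
    T_A : float
        Arrhenius temperature (K), slope of log rate against 1/T.
    T_AL : float
        Arrhenius temperature governing the rate depression below the
        lower boundary (K).
    T_L : float
        Lower boundary temperature (K).
    T_ref : float
        Reference temperature at which all rate parameters are stated (K).
    """

    T_A: float
    T_AL: float
    T_L: float
    T_ref: float = 273.15

    def __post_init__(self) -> None:
        for name in ("T_A", "T_AL", "T_L", "T_ref"):
            if getattr(self, name) <= 0:
                raise ParamFileError(f"Arrhenius parameter {name} must be > 0")
        if self.T_L >= self.T_ref:
            raise ParamFileError("invariant violated: T_L < T_ref required")


@dataclass(frozen=True)
class CompoundParams:
    """Compound DEB quantities, always derived from the primary set.

    E_m = {p_Am}/v  (maximum reserve density, J cm^-3);
    L_m = kappa*{p_Am}/[p_M]  (maximum structural length, cm);
    k_M = [p_M]/[E_G]  (somatic maintenance rate coefficient, d^-1).
    """

    E_m: float
    L_m: float
    k_M: float


@dataclass(frozen=True)
class DEBParams:
    """Primary parameter set of the standard DEB model for an isomorph.

    Rates refer to ``arr.T_ref``.  ``rho_E`` converts reserve energy to
    AFDW and must stay consistent with ``w_E / (1000 * mu_E)``.
    """

    p_Am: float       # max surface-area-specific assimilation rate, J d-1 cm-2
    p_M: float        # volume-specific somatic maintenance, J d-1 cm-3
    E_G: float        # volume-specific cost of structure, J cm-3
    kappa: float      # allocation fraction to soma, -
    v: float          # energy conductance, cm d-1
    k_J: float        # maturity maintenance rate coefficient, d-1
    E_Hb: float       # maturity at birth, J
    E_Hp: float       # maturity at puberty, J
    delta_M: float    # post-metamorphic shape coefficient, -
    delta_M_lrv: float  # pre-metamorphic shape coefficient, -
    d_V: float        # density of structure, g cm-3
    rho_E: float      # weight-energy coupler for reserve, g J-1
    w_E: float        # molar weight of reserve, g mol-1
    mu_E: float       # chemical potential of reserve, kJ mol-1
    kappa_R: float = 0.95  # reproduction efficiency, -
    arr: ArrheniusParams = field(
        default_factory=lambda: ArrheniusParams(T_A=4832.0, T_AL=19966.0, T_L=271.0)
    )

    def __post_init__(self) -> None:
        positive = (
            "p_Am", "p_M", "E_G", "kappa", "v", "k_J", "E_Hb", "E_Hp",
            "delta_M", "delta_M_lrv", "d_V", "rho_E", "w_E", "mu_E", "kappa_R",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParamFileError(f"parameter {name} must be > 0")
        if not 0 < self.kappa < 1:
            raise ParamFileError("invariant violated: 0 < kappa < 1 required")
        if not 0 < self.kappa_R <= 1:
            raise ParamFileError("invariant violated: 0 < kappa_R <= 1 required")
        if not self.E_Hb < self.E_Hp:
            raise ParamFileError("invariant violated: E_Hb < E_Hp required")
        implied = self.w_E / (1000.0 * self.mu_E)
        if abs(self.rho_E - implied) / self.rho_E >= 0.01:
            raise ParamFileError(
                "invariant violated: rho_E inconsistent with w_E/(1000*mu_E) "
                f"({self.rho_E:g} vs {implied:g})"
            )

    @property
    def compound(self) -> CompoundParams:
        return CompoundParams(
            E_m=self.p_Am / self.v,
            L_m=self.kappa * self.p_Am / self.p_M,
            k_M=self.p_M / self.E_G,
        )

    def with_updates(self, **kwargs: float) -> "DEBParams":
        """Return a copy with the given primary parameters replaced."""
        arr_keys = {k: v for k, v in kwargs.items() if k in ("T_A", "T_AL", "T_L", "T_ref")}
        rest = {k: v for k, v in kwargs.items() if k not in arr_keys}
        arr = replace(self.arr, **arr_keys) if arr_keys else self.arr
        return replace(self, arr=arr, **rest)

    def get(self, name: str) -> float:
        """Fetch a primary parameter by name (Arrhenius names included)."""
        if name in ("T_A", "T_AL", "T_L", "T_ref"):
            return getattr(self.arr, name)
        return getattr(self, name)


_PARAM_KEYS = {f.name for f in fields(DEBParams)} - {"arr"}
_ARR_KEYS = {"T_A", "T_AL", "T_L", "T_ref"}
_SITE_KEYS = {"f_MC", "f_PC", "f_R"}
_OPTIONAL_KEYS = {"kappa_R", "T_ref"} | _SITE_KEYS


def _parse_kv(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParamFileError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        try:
            out[key] = float(val.strip())
        except ValueError as exc:
            raise ParamFileError(f"line {lineno}: non-numeric value for {key!r}") from exc
    return out


def params_from_mapping(values: Mapping[str, float]) -> tuple[DEBParams, dict[str, float]]:
    """Build :class:`DEBParams` from a flat symbol->value mapping.

    Returns the parameter object and a dict of site-level scaled functional
    responses (``f_MC``, ``f_PC``, ``f_R``) if present.  Unknown keys are
    rejected by name; missing mandatory symbols raise naming the symbol.
    """
    known = _PARAM_KEYS | _ARR_KEYS | _SITE_KEYS
    for key in values:
        if key not in known:
            raise ParamFileError(f"unknown parameter key: {key!r}")
    required = (_PARAM_KEYS | _ARR_KEYS) - _OPTIONAL_KEYS
    missing = sorted(required - set(values))
    if missing:
        raise ParamFileError(f"missing parameter(s): {', '.join(missing)}")
    arr = ArrheniusParams(
        T_A=values["T_A"],
        T_AL=values["T_AL"],
        T_L=values["T_L"],
        T_ref=values.get("T_ref", 273.15),
    )
    core = {k: values[k] for k in _PARAM_KEYS - {"kappa_R"} if k in values}
    params = DEBParams(arr=arr, kappa_R=values.get("kappa_R", 0.95), **core)
    sites = {k: values[k] for k in _SITE_KEYS if k in values}
    return params, sites


def load_params(path: str | Path) -> DEBParams:
    """Load a ``key = value`` parameter file and validate all invariants."""
    params, _ = params_from_mapping(_parse_kv(Path(path).read_text()))
    return params


def load_site_f(path: str | Path) -> dict[str, float]:
    """Return the per-site scaled functional responses stored in a file."""
    _, sites = params_from_mapping(_parse_kv(Path(path).read_text()))
    return sites


def default_params() -> DEBParams:
    """The shipped reference parameter set for *L. elliptica*."""
    text = resources.files("laternula_deb.data").joinpath("laternula_table1.txt").read_text()
    params, _ = params_from_mapping(_parse_kv(text))
    return params


def default_site_f() -> dict[str, float]:
    """Per-site scaled functional responses of the reference set."""
    text = resources.files("laternula_deb.data").joinpath("laternula_table1.txt").read_text()
    _, sites = params_from_mapping(_parse_kv(text))
    return sites


def default_params_path() -> Path:
    """Filesystem path of the shipped parameter file."""
    return Path(str(resources.files("laternula_deb.data").joinpath("laternula_table1.txt")))
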