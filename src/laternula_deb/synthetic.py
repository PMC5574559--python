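"""Synthetic study-condition generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: daily
temperature/food forcing with an Antarctic seasonal structure, repeated
field campaigns measuring shell length, gonad-free AFDW and gonad AFDW,
calibration bundles (length-weight, size-at-age, respiration) and monthly
environmental covariates (chlorophyll, POC flux, lithogenic flux).  All
randomness flows from the single ``seed`` through numpy's PCG64
generator, so identical configurations reproduce identical data; each
generator returns the observables together with the generating truth,
never mixed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Forcing, temp_correction
from .estimation import CalibrationDataset, UniVariateData, _birth_length_newborn, predict_dataset
from .params import DEBParams
from .seasonal import FieldCampaign, SpawnConfig, _in_window

__all__ = ["ScenarioConfig", "gen_forcing", "gen_campaign",
           "gen_calibration_bundle", "gen_covariates"]


@dataclass
class ScenarioConfig:
    """Study-condition settings for all generators.

    Defaults emulate the Marian Cove setting: near-freezing water with a
    1.5 K seasonal cycle, food pulsing from a winter floor of f = 0.15 to
    a summer peak of f = 0.40, monthly condition sampling of 20
    individuals over two years, 10% lognormal mass noise and 0.05 cm
    length noise.
    """

    seed: int = 0
    years: int = 2
    start_date: str = "1998-04-01"
    # temperature: annual sinusoid (K)
    temp_mean_K: float = 272.7
    temp_amplitude_K: float = 1.5
    temp_peak_doy: int = 32          # early February (austral summer)
    # food: seasonal pulse in the scaled functional response
    f_floor: float = 0.15
    f_peak: float = 0.40
    bloom_peak_doy: int = 15         # mid-January
    bloom_width_d: float = 60.0
    # sampling plan
    events_per_year: int = 12
    individuals_per_event: int = 20
    shell_mean_cm: float = 6.0
    shell_sd_cm: float = 1.0
    shell_min_cm: float = 2.5
    # noise model
    mass_cv: float = 0.10            # lognormal CV on masses
    length_sd_cm: float = 0.05       # additive normal on lengths
    calibration_noise_cv: float = 0.05
    # covariate link (standardised-covariate scale)
    cov_intercept: float = 0.28
    cov_b_chl: float = 0.08
    cov_b_litho: float = -0.05
    cov_b_interaction: float = 0.03
    cov_noise_sd: float = 0.02
    cov_n_periods: int = 20
    spawn: SpawnConfig = field(default_factory=SpawnConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.f_floor <= self.f_peak <= 1:
            raise ValueError("need 0 <= f_floor <= f_peak <= 1")
        if self.years <= 0 or self.events_per_year <= 0 or self.individuals_per_event < 0:
            raise ValueError("counts must be positive (individuals may be zero)")

    def rng(self, stream: str) -> np.random.Generator:
        # stable per-stream substreams (crc32 is platform- and run-independent)
        key = zlib.crc32(stream.encode()) % 2**31
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


def _circular_bump(doy: np.ndarray, peak: float, width: float) -> np.ndarray:
    """Gaussian bump in circular day-of-year distance, max 1 at the peak."""
    d = np.minimum(np.abs(doy - peak), 365.25 - np.abs(doy - peak))
    return np.exp(-0.5 * (d / width) ** 2)


def gen_forcing(config: ScenarioConfig) -> tuple[Forcing, pd.DataFrame]:
    """Daily forcing over the scenario horizon plus the ground-truth table.

    Temperature is an annual sinusoid; the scaled functional response is
    the winter floor plus a seasonal bloom pulse.  Deterministic given the
    configuration (no sampling noise on the forcing itself).
    """
    n_days = int(round(config.years * 365)) + 1
    dates = pd.date_range(config.start_date, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    T = config.temp_mean_K + config.temp_amplitude_K * np.cos(
        2.0 * np.pi * (doy - config.temp_peak_doy) / 365.25)
    f = config.f_floor + (config.f_peak - config.f_floor) * _circular_bump(
        doy, float(config.bloom_peak_doy), config.bloom_width_d)
    times = np.arange(n_days, dtype=float)
    truth = pd.DataFrame({"date": dates, "temp_K": T, "f": f})
    return Forcing(times=times, T=T, f=f), truth


def _reserve_trajectories(lengths: np.ndarray, forcing_truth: pd.DataFrame,
                          params: DEBParams) -> np.ndarray:
    """Daily e(t) per individual (rows: days, cols: individuals).

    Solves de/dt = (f - e) v_T / L with the exponential one-day integrator
    (exact for day-wise constant forcing); individuals start in
    equilibrium with the initial food level.
    """
    T = forcing_truth["temp_K"].to_numpy(dtype=float)
    f = forcing_truth["f"].to_numpy(dtype=float)
    L = params.delta_M * lengths
    v_T = params.v * temp_correction(T, params.arr)
    e = np.empty((len(f), len(L)))
    e[0] = f[0]
    for i in range(1, len(f)):
        decay = np.exp(-v_T[i - 1] / L)
        e[i] = f[i - 1] + (e[i - 1] - f[i - 1]) * decay
    return e


def _gonad_trajectories(e: np.ndarray, lengths: np.ndarray,
                        forcing_truth: pd.DataFrame, spawn: SpawnConfig,
                        params: DEBParams) -> np.ndarray:
    """Daily reproduction buffer (J) per individual under the spawning rules."""
    dates = pd.DatetimeIndex(forcing_truth["date"])
    T = forcing_truth["temp_K"].to_numpy(dtype=float)
    c_T = temp_correction(T, params.arr)
    in_win = _in_window(dates, spawn)
    edges = np.flatnonzero(np.diff(np.r_[0, in_win.astype(int), 0]))
    windows = list(zip(edges[::2], edges[1::2]))
    L = params.delta_M * lengths
    V = L**3
    comp = params.compound
    E_R = np.zeros(len(L))
    out = np.empty_like(e)
    onset: dict[tuple, np.ndarray] = {}
    schedules = {}
    for w0, w1 in windows:
        length = w1 - w0
        k = 2.0 * np.log(19.0) / length
        t_rel = np.arange(length + 1, dtype=float)
        cdf = 1.0 / (1.0 + np.exp(-k * (t_rel - length / 2.0)))
        cdf = (cdf - cdf[0]) / (cdf[-1] - cdf[0])
        schedules[(w0, w1)] = np.diff(cdf)
    for i in range(e.shape[0]):
        E_density = np.clip(e[i], 0.0, None) * comp.E_m
        p_C = (E_density * (params.E_G * params.v * L**2 + params.p_M * V)
               / (params.E_G + params.kappa * E_density)) * c_T[i]
        p_R = (1.0 - params.kappa) * p_C - params.k_J * params.E_Hp * c_T[i]
        deficit = np.clip(params.p_M * V * c_T[i] - params.kappa * p_C, 0.0, None)
        drain = np.clip(deficit - np.clip(p_R, 0.0, None), 0.0, None)
        p_R_net = np.clip(p_R - deficit, 0.0, None)
        window = next((w_ for w_ in windows if w_[0] <= i < w_[1]), None)
        if window is None:
            E_R = np.clip(E_R + params.kappa_R * p_R_net - drain, 0.0, None)
        else:
            if window not in onset:
                onset[window] = E_R.copy()
            release = spawn.released_fraction * onset[window] * schedules[window][i - window[0]]
            E_R = np.clip(E_R - release - drain, 0.0, None)
        out[i] = E_R
    return out


def gen_campaign(config: ScenarioConfig, params: DEBParams
                 ) -> tuple[FieldCampaign, pd.DataFrame]:
    """Synthetic repeated condition sampling with per-individual truth.

    Individuals are drawn from the scenario length distribution, their
    reserve and reproduction-buffer trajectories simulated under the
    scenario forcing, and each sampling event measures fresh individuals
    with the configured mass and length noise.  Returns the campaign and
    a ground-truth table (true e, true masses, true E_R per individual).
    """
    forcing, truth_f = gen_forcing(config)
    dates = pd.DatetimeIndex(truth_f["date"])
    n_events = config.years * config.events_per_year
    event_idx = np.linspace(14, len(dates) - 15, n_events).round().astype(int)
    rng = config.rng("campaign")
    comp = params.compound

    rows = []
    truth_rows = []
    for idx in event_idx:
        n = config.individuals_per_event
        lengths = np.clip(rng.normal(config.shell_mean_cm, config.shell_sd_cm, n),
                          config.shell_min_cm, None)
        if n == 0:
            continue
        e_traj = _reserve_trajectories(lengths, truth_f, params)
        g_traj = _gonad_trajectories(e_traj, lengths, truth_f, config.spawn, params)
        e_now = e_traj[idx]
        E_R_now = g_traj[idx]
        L = params.delta_M * lengths
        V = L**3
        soft_true = params.d_V * V + params.rho_E * e_now * comp.E_m * V
        gonad_true = params.rho_E * E_R_now
        sigma = np.sqrt(np.log(1.0 + config.mass_cv**2))
        soft_obs = soft_true * rng.lognormal(-0.5 * sigma**2, sigma, n)
        gonad_obs = gonad_true * rng.lognormal(-0.5 * sigma**2, sigma, n)
        len_obs = np.clip(lengths + rng.normal(0.0, config.length_sd_cm, n), 0.1, None)
        date = dates[idx]
        for j in range(n):
            rows.append((date, len_obs[j], soft_obs[j], gonad_obs[j]))
            truth_rows.append((date, lengths[j], e_now[j], soft_true[j],
                               gonad_true[j], E_R_now[j]))
    samples = pd.DataFrame(rows, columns=["date", "shell_length_cm",
                                          "soft_afdw_g", "gonad_afdw_g"])
    truth = pd.DataFrame(truth_rows, columns=["date", "shell_length_cm_true", "e_true",
                                              "soft_afdw_g_true", "gonad_afdw_g_true",
                                              "E_R_true"])
    temperature = truth_f[["date", "temp_K"]].copy()
    return FieldCampaign(samples=samples, temperature=temperature), truth


def gen_calibration_bundle(config: ScenarioConfig, params: DEBParams,
                           noise_cv: float | None = None) -> CalibrationDataset:
    """Synthetic calibration bundle for the covariation method.

    Four uni-variate datasets at the study food levels: length-weight
    (Marian Cove, f = 0.332), size-at-age (Potter Cove, f = 0.384,
    274.15 K), respiration against size (274.15 K, starved) and
    respiration against temperature for a standard 7.5 cm individual.
    Multiplicative lognormal noise at ``noise_cv`` (scenario default);
    pass 0 for a noiseless bundle.
    """
    cv = config.calibration_noise_cv if noise_cv is None else noise_cv
    rng = config.rng("calibration")
    L_b = _birth_length_newborn(params)
    datasets = [
        UniVariateData("length_weight", x=np.linspace(1.5, 8.0, 25), y=np.zeros(25),
                       f=0.332, population="MC"),
        UniVariateData("size_at_age", x=np.linspace(100.0, 5000.0, 25), y=np.zeros(25),
                       f=0.384, temperature=274.15, population="PC", L_0=L_b),
        UniVariateData("respiration_size", x=np.linspace(2.0, 8.0, 15), y=np.zeros(15),
                       f=0.8, temperature=274.15, population="R"),
        UniVariateData("respiration_temperature", x=np.linspace(271.2, 279.0, 12),
                       y=np.zeros(12), f=0.8, shell_length=7.5, population="R"),
    ]
    for ds in datasets:
        y = predict_dataset(params, ds)
        if cv > 0:
            sigma = np.sqrt(np.log(1.0 + cv**2))
            y = y * rng.lognormal(-0.5 * sigma**2, sigma, len(y))
        ds.y = y
    return CalibrationDataset(uni_variates=datasets)


def gen_covariates(config: ScenarioConfig, f_truth: pd.DataFrame | None = None,
                   *, structure: str = "chl_x_litho"
                   ) -> tuple[pd.DataFrame, dict]:
    """Monthly covariate series with a known linear link to the response.

    Chlorophyll and POC flux are correlated transforms of the seasonal
    food driver (correlation >= 0.8 by construction); the lithogenic flux
    is an independent summer-peaking series.  The synthetic response
    ``f_syn`` follows the requested generating ``structure`` on
    standardised covariates with the configured coefficients and noise.
    Returns the covariate table and the ground-truth coefficient dict.
    """
    if f_truth is None:
        _, f_truth = gen_forcing(config)
    rng = config.rng("covariates")
    dates = pd.DatetimeIndex(f_truth["date"])
    n = config.cov_n_periods
    edges = np.linspace(0, len(dates) - 1, n + 1).round().astype(int)
    starts, ends = edges[:-1], edges[1:]
    f_daily = f_truth["f"].to_numpy(dtype=float)
    driver = np.array([f_daily[a:b + 1].mean() for a, b in zip(starts, ends)])
    driver_z = (driver - driver.mean()) / driver.std()

    chl = np.clip(0.5 + 1.2 * driver_z + 0.25 * rng.standard_normal(n), 0.02, None)
    poc = np.clip(80.0 + 120.0 * ((chl - chl.mean()) / chl.std())
                  + 25.0 * rng.standard_normal(n), 1.0, None)
    doy_mid = dates[(starts + ends) // 2].dayofyear.to_numpy(dtype=float)
    litho_season = _circular_bump(doy_mid, 40.0, 70.0)  # summer melt runoff
    litho = np.clip(200.0 + 900.0 * litho_season + 120.0 * rng.standard_normal(n),
                    10.0, None)

    chl_z = (chl - chl.mean()) / chl.std()
    litho_z = (litho - litho.mean()) / litho.std()
    coeffs = {"intercept": config.cov_intercept, "chl": 0.0, "litho": 0.0,
              "interaction": 0.0}
    resp = np.full(n, config.cov_intercept)
    if "chl" in structure:
        coeffs["chl"] = config.cov_b_chl
        resp = resp + config.cov_b_chl * chl_z
    if "litho" in structure:
        coeffs["litho"] = config.cov_b_litho
        resp = resp + config.cov_b_litho * litho_z
    if "_x_" in structure:
        coeffs["interaction"] = config.cov_b_interaction
        resp = resp + config.cov_b_interaction * chl_z * litho_z
    resp = resp + config.cov_noise_sd * rng.standard_normal(n)

    table = pd.DataFrame({
        "period_start": dates[starts],
        "period_end": dates[ends],
        "chl": chl,
        "poc_flux": poc,
        "litho_flux": litho,
        "f_syn": resp,
    })
    truth = {"structure": structure, "coefficients": coeffs,
             "noise_sd": config.cov_noise_sd,
             "chl_poc_correlation": float(np.corrcoef(chl, poc)[0, 1])}
    return table, truth
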