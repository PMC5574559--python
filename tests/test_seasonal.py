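import numpy as np
import pandas as pd
import pytest

from laternula_deb import (Forcing, OrganismState, ReserveSeries, SpawnConfig,
                           flux_series, integrate, observables, reconstruct_f,
                           scaled_reserve_from_condition, simulate_gonad,
                           smooth_reserve, temp_correction)


def _series(dates, e, band=0.0):
    e = np.asarray(e, dtype=float)
    return ReserveSeries(dates=dates, e_mean=e, e_lower=e - band, e_upper=e + band)


def _temps(dates, T=272.7):
    return pd.DataFrame({"date": dates, "temp_K": np.full(len(dates), T)})


class TestScaledReserve:
    def test_structural_mass_only_gives_zero(self, params):
        shell = 6.0
        L = params.delta_M * shell
        assert scaled_reserve_from_condition(shell, params.d_V * L**3, params) \
            == pytest.approx(0.0, abs=1e-12)

    def test_full_reserve_gives_one(self, params):
        shell = 6.0
        L = params.delta_M * shell
        W = (params.d_V + params.rho_E * params.compound.E_m) * L**3
        assert scaled_reserve_from_condition(shell, W, params) == pytest.approx(1.0)

    def test_round_trip_with_observables(self, params):
        e = 0.33
        V = 8.0
        state = OrganismState(t=0.0, V=V, E=e * params.compound.E_m * V, E_H=params.E_Hp)
        obs = observables(state, params)
        back = scaled_reserve_from_condition(obs["shell_length"],
                                             obs["gonadfree_afdw"], params)
        assert back == pytest.approx(e, rel=1e-12)

    def test_non_positive_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            scaled_reserve_from_condition(0.0, 1.0, params)


def _raw_events(n_events=12, per_event=20, amplitude=0.0, noise=0.02, seed=0,
                mean=0.3, period=365.0):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("1998-01-15", periods=n_events, freq="30D")
    rows = []
    for d in dates:
        day = (d - dates[0]).days
        mu = mean + amplitude * np.sin(2 * np.pi * day / period)
        rows.extend((d, mu + noise * rng.standard_normal()) for _ in range(per_event))
    return pd.DataFrame(rows, columns=["date", "e"])


class TestSmoothReserve:
    def test_flat_signal_stays_flat(self):
        raw = _raw_events(amplitude=0.0, noise=0.02, seed=1)
        series = smooth_reserve(raw, knot_budget=8)
        assert np.ptp(series.e_mean) < 0.03
        assert abs(series.e_mean.mean() - 0.3) < 0.01

    def test_seasonal_amplitude_recovered(self):
        raw = _raw_events(amplitude=0.1, noise=0.02, seed=2)
        series = smooth_reserve(raw, knot_budget=8)
        recovered = np.ptp(series.e_mean) / 2.0
        assert recovered == pytest.approx(0.1, rel=0.2)

    def test_heavier_knot_budget_never_increases_rss(self):
        raw = _raw_events(amplitude=0.08, noise=0.03, seed=3)
        def rss(budget):
            series = smooth_reserve(raw, knot_budget=budget,
                                    dates_out=pd.DatetimeIndex(raw["date"].unique()))
            fit = pd.Series(series.e_mean, index=series.dates)
            pred = raw["date"].map(fit).to_numpy()
            return float(np.sum((raw["e"].to_numpy() - pred) ** 2))
        assert rss(8) >= rss(10) >= rss(12)

    def test_too_few_events_rejected(self):
        raw = _raw_events(n_events=4)
        with pytest.raises(ValueError, match="at least 6"):
            smooth_reserve(raw)

    def test_budget_above_event_count_advises_reduction(self):
        raw = _raw_events(n_events=7)
        with pytest.raises(ValueError, match="budget"):
            smooth_reserve(raw, knot_budget=10)


class TestReconstructF:
    def test_constant_reserve_reads_equilibrium_food(self, params):
        dates = pd.date_range("1998-01-01", periods=200, freq="D")
        series = _series(dates, np.full(200, 0.3))
        out = reconstruct_f(series, 2.0, _temps(dates), params)
        np.testing.assert_allclose(out["f"], 0.3, atol=1e-12)

    def test_rising_reserve_implies_food_above_reserve(self, params):
        dates = pd.date_range("1998-01-01", periods=100, freq="D")
        e = np.linspace(0.2, 0.3, 100)
        out = reconstruct_f(_series(dates, e), 2.0, _temps(dates), params)
        assert np.all(out["f"].to_numpy()[1:-1] > e[1:-1])

    def test_step_food_round_trip_through_integrator(self, params):
        # forward-simulate reserve under a step in food, then invert
        f_lo, f_hi, T = 0.2, 0.6, 272.7
        n = 400
        times = np.arange(n, dtype=float)
        f_true = np.where(times < 200, f_lo, f_hi)
        forcing = Forcing(times=times, T=np.full(n, T), f=f_true)
        L = 2.0
        V = L**3
        state0 = OrganismState(t=0.0, V=V, E=f_lo * params.compound.E_m * V,
                               E_H=params.E_Hp)
        traj = integrate(state0, forcing, params, t_eval=times)
        e = traj["E"] / (params.compound.E_m * traj["V"])
        dates = pd.date_range("1998-01-01", periods=n, freq="D")
        Ls = traj["V"] ** (1 / 3)
        out = reconstruct_f(_series(dates, e), Ls, _temps(dates, T), params)
        away = (np.abs(times - 200) > 10)
        np.testing.assert_allclose(out["f"].to_numpy()[away], f_true[away], atol=0.05 * f_hi)

    def test_misaligned_temperature_record_rejected(self, params):
        dates = pd.date_range("1998-01-01", periods=100, freq="D")
        series = _series(dates, np.full(100, 0.3))
        bad_temps = _temps(pd.date_range("2001-01-01", periods=100, freq="D"))
        with pytest.raises(ValueError):
            reconstruct_f(series, 2.0, bad_temps, params)


class TestFluxSeries:
    def test_high_reserve_covers_maintenance(self, params):
        dates = pd.date_range("1998-01-01", periods=50, freq="D")
        out = flux_series(_series(dates, np.full(50, 0.8)), _temps(dates),
                          np.array([6.0, 7.0]), params)
        assert (out["p_C"] > out["p_maint"]).all()

    def test_depleted_winter_reserve_fails_maintenance_for_large_animals(self, params):
        dates = pd.date_range("1998-07-01", periods=50, freq="D")
        out = flux_series(_series(dates, np.full(50, 0.1)), _temps(dates, 271.2),
                          np.array([8.0]), params)
        assert (out["p_C"] < out["p_maint"]).all()

    def test_maintenance_tracks_temperature_correction(self, params):
        dates = pd.date_range("1998-01-01", periods=100, freq="D")
        T = np.linspace(271.5, 274.5, 100)
        temps = pd.DataFrame({"date": dates, "temp_K": T})
        out = flux_series(_series(dates, np.full(100, 0.5)), temps,
                          np.array([6.0]), params)
        ratio = out["p_maint"].to_numpy() / temp_correction(T, params.arr)
        assert np.ptp(ratio) / ratio.mean() < 1e-12

    def test_linear_in_population_weights(self, params):
        dates = pd.date_range("1998-01-01", periods=20, freq="D")
        series = _series(dates, np.full(20, 0.4))
        lengths = np.array([4.0, 6.0, 8.0])
        a = flux_series(series, _temps(dates), lengths, params,
                        weights=np.array([1.0, 2.0, 3.0]), aggregate="sum")
        single = [flux_series(series, _temps(dates), np.array([l]), params,
                              aggregate="sum") for l in lengths]
        expected = 1.0 * single[0]["p_C"] + 2.0 * single[1]["p_C"] + 3.0 * single[2]["p_C"]
        np.testing.assert_allclose(a["p_C"], expected, rtol=1e-12)


class TestSimulateGonad:
    def test_linear_growth_at_constant_conditions(self, params):
        # span chosen outside any spawning window
        dates = pd.date_range("1998-04-05", "1998-12-10", freq="D")
        series = _series(dates, np.full(len(dates), 0.4))
        out = simulate_gonad(series, _temps(dates), np.array([7.0]),
                             SpawnConfig(), params)
        g = out["gonad_afdw"].to_numpy()
        rates = np.diff(g)
        assert np.all(rates > 0)
        assert np.ptp(rates) / rates.mean() < 1e-9

    def test_steep_logistic_releases_exactly_half_at_window_end(self, params):
        dates = pd.date_range("1998-04-05", "1999-04-10", freq="D")
        series = _series(dates, np.full(len(dates), 0.4))
        spawn = SpawnConfig(steepness=5.0)
        out = simulate_gonad(series, _temps(dates), np.array([7.0]), spawn, params)
        out = out.set_index("date")["gonad_afdw"]
        onset = out["1998-12-14"]
        at_end = out["1999-03-31"]
        assert at_end == pytest.approx(0.5 * onset, rel=1e-6)

    def test_starvation_halts_gonad_accretion(self, params):
        # reserve far below the maintenance break-even for a large individual
        dates = pd.date_range("1998-05-01", "1998-09-30", freq="D")
        series = _series(dates, np.full(len(dates), 0.05))
        out = simulate_gonad(series, _temps(dates, 271.2), np.array([8.0]),
                             SpawnConfig(), params, E_R0=1000.0)
        g = out["gonad_afdw"].to_numpy()
        assert np.all(np.diff(g) <= 1e-15)

    def test_gonad_never_negative_and_band_ordered(self, params):
        dates = pd.date_range("1998-04-05", "1999-06-30", freq="D")
        e = 0.25 + 0.1 * np.sin(np.arange(len(dates)) / 58.0)
        series = _series(dates, e, band=0.05)
        out = simulate_gonad(series, _temps(dates), np.array([5.0, 7.0]),
                             SpawnConfig(), params)
        assert (out["gonad_afdw"] >= 0).all()
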