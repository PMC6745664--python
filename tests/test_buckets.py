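import datetime as dt

import numpy as np
import pytest

import newtflow as nf
from newtflow.buckets import UNIT_NAMES, BucketState, step_unit
from newtflow.calibrate import default_parameter_ranges


def flat_params(**overrides) -> nf.UnitParameters:
    base = dict(
        tau_quick=1.0, tau_soil=2.0, tau_gw=5.0, field_capacity=100.0,
        soil_to_gw_fraction=0.5, et_degreeday=0.0, et_temp_threshold=0.0,
        et_adjustment=1.0, melt_degreeday=3.0,
    )
    base.update(overrides)
    return nf.UnitParameters(**base)


class TestStepUnit:
    def test_groundwater_only_linear_reservoir(self):
        state = BucketState(groundwater=10.0)
        params = flat_params(tau_gw=5.0)
        new, runoff, aet = step_unit(state, temperature=-5.0, precipitation=0.0,
                                     params=params, snow=False)
        assert runoff == pytest.approx(2.0)
        assert new.groundwater == pytest.approx(8.0)
        assert aet == 0.0

    def test_recession_is_geometric(self):
        """With no rain, base flow decays as V(0)*(1-1/tau)^t (closed form)."""
        tau = 7.0
        state = BucketState(groundwater=50.0)
        params = flat_params(tau_gw=tau)
        for t in range(30):
            state, runoff, _ = step_unit(state, 5.0, 0.0, params, snow=False)
            expected_v = 50.0 * (1 - 1 / tau) ** (t + 1)
            assert state.groundwater == pytest.approx(expected_v, rel=1e-12)
            assert runoff == pytest.approx(50.0 * (1 - 1 / tau) ** t / tau, rel=1e-12)

    def test_aet_equals_pet_at_field_capacity(self):
        params = flat_params(et_degreeday=0.3, et_adjustment=2.7, field_capacity=120.0)
        state = BucketState(soil=120.0)
        _, _, aet = step_unit(state, 10.0, 0.0, params, snow=False)
        assert aet == pytest.approx(0.3 * 10.0)

    def test_et_adjustment_monotonically_limits_aet(self):
        """Raising the exponent never increases AET when the soil is dry."""
        aets = []
        for adj in (0.0, 0.5, 1.0, 2.0, 4.0):
            params = flat_params(et_degreeday=0.3, et_adjustment=adj, field_capacity=200.0)
            _, _, aet = step_unit(BucketState(soil=50.0), 15.0, 0.0, params, snow=False)
            aets.append(aet)
        assert all(a >= b for a, b in zip(aets, aets[1:]))

    def test_snow_accumulates_then_melts(self):
        params = flat_params(melt_degreeday=2.0)
        cold, runoff, _ = step_unit(BucketState(), -3.0, 10.0, params,
                                    snow_temp_threshold=0.0)
        assert cold.snowpack == 10.0 and runoff == 0.0
        warm, _, _ = step_unit(cold, 2.0, 0.0, params, snow_temp_threshold=0.0)
        assert warm.snowpack == pytest.approx(6.0)  # melt = 2 mm/degC * 2 degC

    def test_non_finite_forcing_rejected(self):
        with pytest.raises(nf.ForcingError):
            step_unit(BucketState(), np.nan, 0.0, flat_params())

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            nf.UnitParameters(tau_gw=0.5)
        with pytest.raises(ValueError):
            nf.UnitParameters(soil_to_gw_fraction=1.5)
        with pytest.raises(ValueError):
            nf.UnitParameters(field_capacity=0.0)


class TestParameterVector:
    def test_28_exposed_parameters(self):
        names = nf.ParameterSet.parameter_names()
        assert len(names) == 28
        assert "global.snow_temp_threshold" in names
        assert sum(n.startswith("holm_oak.") for n in names) == 9

    def test_vector_round_trip(self, default_params):
        names = nf.ParameterSet.parameter_names()
        vec = default_params.to_vector(names)
        rebuilt = default_params.replace_from_vector(names, vec)
        np.testing.assert_array_equal(rebuilt.to_vector(names), vec)

    def test_ranges_cover_every_parameter(self):
        assert set(default_parameter_ranges()) == set(nf.ParameterSet.parameter_names())


def uniform_forcing(n_days, temp=12.0, precip=0.0, start=dt.date(2011, 1, 1)):
    return nf.ClimateForcing(
        temperature=nf.DailySeries(start, np.full(n_days, float(temp)), nf.DEG_C),
        precipitation=nf.DailySeries(start, np.full(n_days, float(precip)), nf.MM),
    )


def single_unit_setup(unit_params):
    catchment = nf.CatchmentSpec(2.0, {"holm_oak": 1.0, "beech": 0.0, "heathland": 0.0})
    params = nf.ParameterSet(
        units={"holm_oak": unit_params, "beech": unit_params, "heathland": unit_params},
        initial_storage={u: BucketState() for u in UNIT_NAMES},
    )
    return catchment, params


class TestSimulate:
    def test_zero_precip_zero_storage_zero_flow(self):
        catchment, params = single_unit_setup(flat_params())
        result = nf.simulate(uniform_forcing(40, precip=0.0), catchment, params,
                             spinup_days=0, snow=False)
        np.testing.assert_array_equal(result.streamflow.values, 0.0)

    def test_mass_balance_closes(self, forcing_6yr, catchment, default_params):
        result = nf.simulate(forcing_6yr, catchment, default_params)
        assert result.balance_closure() <= 1e-6
        for ledger in result.balance.values():
            assert ledger["cum_q"] >= 0 and ledger["cum_aet"] >= 0

    def test_streamflow_never_negative_or_missing(self, forcing_6yr, catchment,
                                                  default_params):
        q = nf.simulate(forcing_6yr, catchment, default_params).streamflow
        assert np.isfinite(q.values).all()
        assert (q.values >= 0).all()

    def test_impulse_peak_lags_rain_by_at_least_one_day(self):
        """20 mm on a dry catchment: the peak arrives after the rain day.

        A 1-day quick residence routes the whole input to the stream within
        the rain day itself; the flashy-but-lagged response of the study
        catchment corresponds to a ~2-day quick box (the default), whose
        impulse response peaks the following day.
        """
        catchment, params = single_unit_setup(
            flat_params(tau_quick=2.0, tau_soil=3.0, field_capacity=1e-6))
        forcing = uniform_forcing(30, temp=12.0, precip=0.0)
        forcing.precipitation.values[5] = 20.0
        q = nf.simulate(forcing, catchment, params, spinup_days=0, snow=False).streamflow
        p = forcing.precipitation
        assert nf.best_lag(p, nf.convert_flow_series(q, nf.LITRES_PER_SECOND, 2.0),
                           max_lag=5) >= 1

    def test_spinup_excluded_from_output(self, forcing_6yr, catchment, default_params):
        result = nf.simulate(forcing_6yr, catchment, default_params, spinup_days=365)
        assert len(result.streamflow) == len(forcing_6yr) - 365
        assert result.streamflow.start == forcing_6yr.start + dt.timedelta(days=365)

    def test_missing_forcing_rejected(self, catchment, default_params):
        forcing = uniform_forcing(30)
        forcing.precipitation.values[3] = np.nan
        with pytest.raises(nf.ForcingError, match="gap-fill"):
            nf.simulate(forcing, catchment, default_params, spinup_days=0)

    def test_misaligned_forcing_rejected(self):
        t = nf.DailySeries(dt.date(2011, 1, 1), np.zeros(10), nf.DEG_C)
        p = nf.DailySeries(dt.date(2011, 1, 2), np.zeros(10), nf.MM)
        with pytest.raises(ValueError):
            nf.ClimateForcing(t, p)

    def test_simulate_matches_composed_step_unit(self):
        """The jitted day loop and the reference per-day update agree exactly."""
        rng = np.random.default_rng(3)
        n = 200
        forcing = nf.ClimateForcing(
            temperature=nf.DailySeries(dt.date(2012, 1, 1),
                                       rng.normal(11, 6, n), nf.DEG_C),
            precipitation=nf.DailySeries(dt.date(2012, 1, 1),
                                         rng.gamma(0.7, 8, n) * (rng.uniform(size=n) < 0.3),
                                         nf.MM),
        )
        params = nf.ParameterSet(snow_temp_threshold=0.5)
        catchment = nf.montseny_reference_catchment()
        result = nf.simulate(forcing, catchment, params, spinup_days=0)

        manual = np.zeros(n)
        for unit, frac in catchment.cover_fractions.items():
            state = params.storage_of(unit)
            for t in range(n):
                state, runoff, _ = step_unit(
                    state, forcing.temperature.values[t], forcing.precipitation.values[t],
                    params.units[unit], params.snow_temp_threshold)
                manual[t] += frac * runoff
        np.testing.assert_allclose(result.streamflow.values, manual, rtol=1e-12, atol=1e-15)

    def test_mixture_degeneracy(self):
        """Two identical units split (a, 1-a) behave like a single unit."""
        up = flat_params(et_degreeday=0.2, tau_gw=12.0)
        forcing = nf.generate_weather(nf.WeatherConfig(), 2, seed=11)
        single = nf.CatchmentSpec(2.0, {"holm_oak": 1.0, "beech": 0.0, "heathland": 0.0})
        mixed = nf.CatchmentSpec(2.0, {"holm_oak": 0.3, "beech": 0.7, "heathland": 0.0})
        params = nf.ParameterSet(
            units={u: up for u in UNIT_NAMES},
            initial_storage={u: BucketState(soil=50.0, groundwater=20.0)
                             for u in UNIT_NAMES},
        )
        q1 = nf.simulate(forcing, single, params, spinup_days=0).streamflow.values
        q2 = nf.simulate(forcing, mixed, params, spinup_days=0).streamflow.values
        np.testing.assert_allclose(q1, q2, rtol=1e-12)


class TestLinearReservoirOracle:
    def test_impulse_response_matches_analytic_convolution(self):
        """ET off, negligible field capacity: the cascade is linear and its
        impulse response is the convolution of geometric reservoir kernels."""
        tau_q, tau_s, tau_g, f_gw = 2.0, 3.0, 8.0, 0.4
        n = 120
        impulse = 25.0
        catchment, params = single_unit_setup(
            flat_params(tau_quick=tau_q, tau_soil=tau_s, tau_gw=tau_g,
                        soil_to_gw_fraction=f_gw, field_capacity=1e-12,
                        et_degreeday=0.0))
        forcing = uniform_forcing(n, temp=10.0, precip=0.0)
        forcing.precipitation.values[0] = impulse
        q = nf.simulate(forcing, catchment, params, spinup_days=0,
                        snow=False).streamflow.values

        t = np.arange(n)
        def kernel(tau):
            return (1 / tau) * (1 - 1 / tau) ** t
        h_qs = np.convolve(kernel(tau_q), kernel(tau_s))[:n]
        h_qsg = np.convolve(h_qs, kernel(tau_g))[:n]
        expected = impulse * ((1 - f_gw) * h_qs + f_gw * h_qsg)
        np.testing.assert_allclose(q, expected, atol=1e-9)


def test_water_balance_over_random_parameter_sets(forcing_6yr, catchment):
    """Conservation holds across the whole admissible parameter space."""
    rng = np.random.default_rng(123)
    names = nf.ParameterSet.parameter_names()
    ranges = default_parameter_ranges()
    lo = np.array([ranges[n][0] for n in names])
    hi = np.array([ranges[n][1] for n in names])
    base = nf.ParameterSet()
    for _ in range(50):
        params = base.replace_from_vector(names, rng.uniform(lo, hi))
        result = nf.simulate(forcing_6yr, catchment, params, spinup_days=0)
        assert result.balance_closure() <= 1e-6
        assert (result.streamflow.values >= 0).all()
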