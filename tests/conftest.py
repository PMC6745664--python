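import datetime as dt

import numpy as np
import pytest

import newtflow as nf


@pytest.fixture(scope="session")
def catchment() -> nf.CatchmentSpec:
    return nf.montseny_reference_catchment()


@pytest.fixture(scope="session")
def default_params() -> nf.ParameterSet:
    return nf.ParameterSet()


@pytest.fixture(scope="session")
def forcing_6yr() -> nf.ClimateForcing:
    """Six calendar years of default synthetic weather: 1 spin-up + 5 analysed."""
    return nf.generate_weather(nf.WeatherConfig(), years=6, seed=7)


@pytest.fixture(scope="session")
def truth_run(forcing_6yr, catchment, default_params):
    """Noise-free, gap-free synthetic observations with the known truth."""
    obs, truth = nf.generate_truth_run(
        forcing_6yr, catchment, default_params,
        noise_sd=0.0, missing_fraction=0.0, seed=7,
    )
    return obs, truth


def mk_series(values, units=nf.LITRES_PER_SECOND, start=dt.date(2011, 1, 1)):
    return nf.DailySeries(start, np.asarray(values, dtype=float), units)
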