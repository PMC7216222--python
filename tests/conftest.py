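import datetime as dt

import numpy as np
import pytest

from koreicus.popmodel import ParameterSet, TemperatureSeries, default_rates
from koreicus.synthdata import SynthConfig, city_temperature, gen_captures, gen_temperature


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def synth_temps(synth_cfg):
    return gen_temperature(synth_cfg)


@pytest.fixture(scope="session")
def city_temps(synth_temps):
    return city_temperature(synth_temps)


@pytest.fixture(scope="session")
def synth_study(synth_cfg, synth_temps):
    """(CaptureData, per-trap frame, trajectories) for the default truth."""
    return gen_captures(synth_cfg, synth_temps)


@pytest.fixture()
def default_params() -> ParameterSet:
    return ParameterSet(alpha=0.015, K_by_year={2018: 200.0}, rates=default_rates())


def constant_series(year: int, temp: float, n_days: int = 275) -> TemperatureSeries:
    """A constant-temperature series starting Jan 1."""
    return TemperatureSeries(dt.date(year, 1, 1), np.full(n_days, float(temp)))
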