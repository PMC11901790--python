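"""Shared fixtures: synthetic seasons and one reusable full forward run."""

from __future__ import annotations

import pytest
from hypothesis import settings

from greenwater.forward import run_forward
from greenwater.meteo import SeasonCalendar
from greenwater.synth import WeatherGenSpec, gen_lai, gen_weather, species_templates

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def templates():
    return species_templates()


@pytest.fixture(scope="session")
def weather_2019():
    return gen_weather(WeatherGenSpec(seed=1, year=2019))


@pytest.fixture(scope="session")
def cal_2019():
    return SeasonCalendar(2019)


@pytest.fixture(scope="session")
def rp_template(templates):
    return templates["R. pseudoacacia"]


@pytest.fixture(scope="session")
def rp_forward(rp_template, weather_2019, cal_2019):
    """Full-season forward run of the R. pseudoacacia plot (reused widely)."""
    lai = gen_lai(rp_template, cal_2019)
    return run_forward(rp_template, weather_2019, lai)
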