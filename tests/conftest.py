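import numpy as np
import pytest

from ricesist.crop import CropParams
from ricesist.meteo import MeteoDay, solar_geometry
from ricesist.scenes import synthetic_meteo


@pytest.fixture(scope="session")
def meteo_2017():
    return synthetic_meteo(2017, seed=0)


@pytest.fixture(scope="session")
def meteo_2018():
    return synthetic_meteo(2018, seed=0)


@pytest.fixture(scope="session")
def default_params():
    return CropParams()


@pytest.fixture(scope="session")
def constant_rs15_meteo():
    """Season of weather whose sunshine hours yield Rs = 15 MJ m-2 d-1 daily."""
    days = []
    for doy in range(160, 256):
        geom = solar_geometry(doy, 27.7)
        n = geom.daylength_hours * ((15.0 / geom.ra) - 0.18) / 0.55
        days.append(
            MeteoDay(
                doy=doy,
                tmax=31.0,
                tmin=23.0,
                sunshine_hours=float(np.clip(n, 0.0, 24.0)),
                latitude_deg=27.7,
            )
        )
    return days
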