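"""Daily sunshine-hour records converted to solar radiation forcing.

The conversion follows the classical astronomical chain: inverse-square
Earth-Sun distance factor, solar declination, sunset hour angle,
extraterrestrial radiation, potential day length, and finally the
Angstrom-Prescott relation mapping observed sunshine hours to surface
shortwave radiation in MJ m-2 d-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import InvalidInputError, MissingForcingError

#: Amplitude of the declination seasonal cycle (radians).
_DECL_AMPLITUDE = 0.4209
#: Angular frequency of the annual cycle (radians per day).
_ANNUAL_FREQ = 0.0172
#: Extraterrestrial radiation coefficient (MJ m-2 d-1).
_RA_COEFF = 37.6


@dataclass(frozen=True)
class AngstromCoefficients:
    """Angstrom-Prescott regression constants for a temperate climate."""

    a_s: float = 0.18
    b_s: float = 0.55

    def __post_init__(self) -> None:
        if not (self.a_s > 0 and self.b_s > 0):
            raise InvalidInputError("Angstrom coefficients must be positive")
        if self.a_s + self.b_s > 1.0 + 1e-12:
            raise InvalidInputError("a_s + b_s must not exceed 1")


DEFAULT_ANGSTROM = AngstromCoefficients()


@dataclass(frozen=True)
class MeteoDay:
    """One day of weather forcing at a site.

    Parameters
    ----------
    doy
        Day of year, 1..366.
    tmax, tmin
        Daily extreme air temperatures, degrees Celsius.
    sunshine_hours
        Observed bright-sunshine duration ``n``, hours.
    latitude_deg
        Site latitude ``phi`` in decimal degrees.
    """

    doy: int
    tmax: float
    tmin: float
    sunshine_hours: float
    latitude_deg: float

    def __post_init__(self) -> None:
        if not 1 <= self.doy <= 366:
            raise InvalidInputError(f"doy {self.doy} outside [1, 366]")
        if self.tmax < self.tmin:
            raise InvalidInputError(
                f"tmax {self.tmax} < tmin {self.tmin} on doy {self.doy}"
            )
        if not 0.0 <= self.sunshine_hours <= 24.0:
            raise InvalidInputError("sunshine_hours must be within [0, 24]")
        if not -90.0 < self.latitude_deg < 90.0:
            raise InvalidInputError("latitude_deg must be within (-90, 90)")


@dataclass(frozen=True)
class RadiationResult:
    """Solar geometry and radiation terms for one day.

    ``rs`` is ``nan`` when only the geometric terms were requested.
    """

    dr: float
    declination_rad: float
    omega_s_rad: float
    ra: float
    daylength_hours: float
    rs: float = field(default=float("nan"))


def solar_geometry(doy: int, latitude_deg: float) -> RadiationResult:
    """Compute Earth-Sun geometry and extraterrestrial radiation for a day.

    The sunset-hour-angle arccos argument is clamped to [-1, 1] so that
    latitudes beyond the polar circles degrade to 0 h or 24 h day length
    instead of raising a domain error.
    """
    if not 1 <= int(doy) <= 366:
        raise InvalidInputError(f"doy {doy} outside [1, 366]")
    if not -90.0 < latitude_deg < 90.0:
        raise InvalidInputError("latitude_deg must be within (-90, 90)")

    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(_ANNUAL_FREQ * doy)
    decl = _DECL_AMPLITUDE * math.sin(_ANNUAL_FREQ * doy - 1.39)
    cos_ws = -math.tan(phi) * math.tan(decl)
    omega_s = math.acos(min(1.0, max(-1.0, cos_ws)))
    ra = _RA_COEFF * dr * (
        omega_s * math.sin(phi) * math.sin(decl)
        + math.cos(phi) * math.cos(decl) * math.sin(omega_s)
    )
    daylength = 24.0 / math.pi * omega_s
    return RadiationResult(
        dr=dr,
        declination_rad=decl,
        omega_s_rad=omega_s,
        ra=max(ra, 0.0),
        daylength_hours=daylength,
    )


def sunshine_to_radiation(
    day: MeteoDay, coeffs: AngstromCoefficients = DEFAULT_ANGSTROM
) -> RadiationResult:
    """Surface shortwave radiation Rs = (a_s + b_s * n/N) * Ra, MJ m-2 d-1."""
    geom = solar_geometry(day.doy, day.latitude_deg)
    if geom.daylength_hours <= 0.0:
        raise InvalidInputError(
            f"zero day length on doy {day.doy} at latitude {day.latitude_deg}"
        )
    frac = day.sunshine_hours / geom.daylength_hours
    rs = (coeffs.a_s + coeffs.b_s * frac) * geom.ra
    return RadiationResult(
        dr=geom.dr,
        declination_rad=geom.declination_rad,
        omega_s_rad=geom.omega_s_rad,
        ra=geom.ra,
        daylength_hours=geom.daylength_hours,
        rs=rs,
    )


def read_meteo_csv(
    path: str | Path,
    latitude_deg: float,
    required_doys: Sequence[int] | None = None,
) -> list[MeteoDay]:
    """Read one year of daily weather from CSV.

    Expected header: ``doy,tmax,tmin,sunshine_hours``.  When
    ``required_doys`` is given, every listed day must be present;
    gaps raise :class:`MissingForcingError` listing the missing days.
    """
    df = pd.read_csv(path)
    expected = {"doy", "tmax", "tmin", "sunshine_hours"}
    if not expected.issubset(df.columns):
        raise InvalidInputError(
            f"meteo CSV {path} must have columns {sorted(expected)}, "
            f"got {list(df.columns)}"
        )
    days = [
        MeteoDay(
            doy=int(row.doy),
            tmax=float(row.tmax),
            tmin=float(row.tmin),
            sunshine_hours=float(row.sunshine_hours),
            latitude_deg=latitude_deg,
        )
        for row in df.itertuples()
    ]
    if required_doys is not None:
        have = {d.doy for d in days}
        missing = set(int(d) for d in required_doys) - have
        if missing:
            raise MissingForcingError(missing)
    return days
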