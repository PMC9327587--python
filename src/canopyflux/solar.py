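"""Solar geometry and clear-sky shortwave irradiance.

Implements the Iqbal parametric clear-sky model (Model C): direct-beam
irradiance attenuated by Rayleigh, ozone, uniformly-mixed-gas, water-vapour
and aerosol transmittances, plus a three-part diffuse term (Rayleigh
scattering, aerosol scattering, and ground-sky multiple reflection).
All quantities refer to the shortwave band (0.3-3 um), hence the 0.9751
spectral factor on the direct beam.

Angle conventions: degrees at every public interface; azimuth is measured
clockwise from north in [0, 360) so that morning azimuths are < 180 at
northern mid-latitudes; the beam direction points from the Sun toward the
ground in an (x east, y north, z up) frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteTime",
    "SolarState",
    "AtmosphericParams",
    "IrradianceBreakdown",
    "declination",
    "eccentricity_factor",
    "air_mass",
    "solar_position",
    "transmittances",
    "Transmittances",
    "tau_aerosol_absorption",
    "sky_albedo",
    "direct_irradiance",
    "diffuse_irradiance",
    "total_irradiance",
    "irradiance_table",
]

SOLAR_CONSTANT = 1367.0  # W/m^2
SPECTRAL_FACTOR = 0.9751  # fraction of the solar constant in 0.3-3 um


@dataclass(frozen=True)
class SiteTime:
    """A site location and a local solar time instant.

    latitude : degrees, +N; longitude : degrees, +E (metadata only, the hour
    angle is taken from local *solar* time directly); day_of_year in [1, 366];
    solar_time : decimal hours in [0, 24).
    """

    latitude: float
    day_of_year: int
    solar_time: float
    longitude: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not 1 <= self.day_of_year <= 366:
            raise ValueError(f"day_of_year {self.day_of_year} outside [1, 366]")
        if not 0.0 <= self.solar_time < 24.0:
            raise ValueError(f"solar_time {self.solar_time} outside [0, 24)")


@dataclass(frozen=True)
class SolarState:
    """Solar geometry at one instant: all angles in degrees.

    ``beam_direction`` is the unit propagation vector of sunlight (from the
    Sun toward the ground), so its z component is negative whenever the Sun
    is above the horizon.
    """

    declination: float
    hour_angle: float
    altitude: float
    azimuth: float
    beam_direction: np.ndarray
    r0: float = 1.0  # Earth-orbit eccentricity correction for the date

    @property
    def above_horizon(self) -> bool:
        return self.altitude > 0.0


@dataclass(frozen=True)
class AtmosphericParams:
    """Atmospheric column and surface inputs of the clear-sky model.

    The band transmittances tau_* are computed from ``ozone_cm``
    (ozone column, atm-cm), ``water_cm`` (precipitable water, cm),
    ``visibility_km`` (horizontal visibility) and the air mass; they are not
    stored here.  The defaults were calibrated once for the subtropical
    study site (humid early-summer atmosphere) and shipped frozen; see
    ``scripts/calibrate_atmosphere.py``.
    """

    solar_constant: float = SOLAR_CONSTANT
    ozone_cm: float = 0.35
    water_cm: float = 4.0
    visibility_km: float = 6.2
    ground_albedo: float = 0.2
    single_scattering_albedo: float = 0.9  # omega_o
    forward_scatter_fraction: float = 0.84  # F_c
    aerosol_urban_factor: float = 0.79

    def __post_init__(self) -> None:
        for name in ("ground_albedo", "single_scattering_albedo",
                     "forward_scatter_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.visibility_km <= 0:
            raise ValueError("visibility_km must be positive")
        if self.ozone_cm < 0 or self.water_cm < 0:
            raise ValueError("ozone_cm and water_cm must be non-negative")


@dataclass(frozen=True)
class IrradianceBreakdown:
    """Shortwave irradiance components on a horizontal surface, W/m^2."""

    direct: float
    diffuse_rayleigh: float
    diffuse_aerosol: float
    diffuse_multireflect: float

    @property
    def diffuse_total(self) -> float:
        return (self.diffuse_rayleigh + self.diffuse_aerosol
                + self.diffuse_multireflect)

    @property
    def total(self) -> float:
        return self.direct + self.diffuse_total

    @staticmethod
    def zero() -> "IrradianceBreakdown":
        return IrradianceBreakdown(0.0, 0.0, 0.0, 0.0)


def _day_angle(day_of_year: int) -> float:
    return 2.0 * math.pi * (day_of_year - 1) / 365.0


def declination(day_of_year: int) -> float:
    """Solar declination in degrees from the Spencer Fourier series."""
    if not 1 <= day_of_year <= 366:
        raise ValueError(f"day_of_year {day_of_year} outside [1, 366]")
    g = _day_angle(day_of_year)
    rad = (0.006918
           - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
           - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
           - 0.002697 * math.cos(3 * g) + 0.001480 * math.sin(3 * g))
    return math.degrees(rad)


def eccentricity_factor(day_of_year: int) -> float:
    """Earth-orbit eccentricity correction r0 (Spencer series), unitless."""
    g = _day_angle(day_of_year)
    return (1.000110
            + 0.034221 * math.cos(g) + 0.001280 * math.sin(g)
            + 0.000719 * math.cos(2 * g) + 0.000077 * math.sin(2 * g))


def air_mass(altitude_deg: float) -> float:
    """Relative optical air mass (Kasten formula, standard pressure)."""
    if altitude_deg <= 0:
        raise ValueError("air mass undefined at or below the horizon")
    a = altitude_deg
    return 1.0 / (math.sin(math.radians(a)) + 0.15 * (a + 3.885) ** -1.253)


def solar_position(site_time: SiteTime) -> SolarState:
    """Solar declination, hour angle, altitude, azimuth and beam direction.

    The hour angle is 15 deg per hour from local solar noon; altitude follows
    sin(alt) = sin(lat) sin(dec) + cos(lat) cos(dec) cos(h).  Azimuth is
    resolved clockwise from north with morning values east (< 180 deg).
    """
    dec = declination(site_time.day_of_year)
    hour_angle = 15.0 * (site_time.solar_time - 12.0)
    lat_r = math.radians(site_time.latitude)
    dec_r = math.radians(dec)
    h_r = math.radians(hour_angle)

    sin_alt = (math.sin(lat_r) * math.sin(dec_r)
               + math.cos(lat_r) * math.cos(dec_r) * math.cos(h_r))
    sin_alt = min(1.0, max(-1.0, sin_alt))
    alt_r = math.asin(sin_alt)
    altitude = math.degrees(alt_r)

    cos_alt = math.cos(alt_r)
    if cos_alt < 1e-12:
        # Sun at the zenith: azimuth is degenerate; report due south.
        azimuth = 180.0
    else:
        cos_az = ((math.sin(dec_r) - sin_alt * math.sin(lat_r))
                  / (cos_alt * math.cos(lat_r)))
        cos_az = min(1.0, max(-1.0, cos_az))
        az = math.degrees(math.acos(cos_az))  # angle from north, [0, 180]
        azimuth = az if hour_angle <= 0.0 else 360.0 - az
    azimuth %= 360.0

    az_r = math.radians(azimuth)
    # Unit vector pointing toward the Sun, then negated: from Sun to ground.
    beam = -np.array([cos_alt * math.sin(az_r),
                      cos_alt * math.cos(az_r),
                      sin_alt])
    beam /= np.linalg.norm(beam)
    return SolarState(declination=dec, hour_angle=hour_angle,
                      altitude=altitude, azimuth=azimuth, beam_direction=beam,
                      r0=eccentricity_factor(site_time.day_of_year))


@dataclass(frozen=True)
class Transmittances:
    """Band transmittances of the five attenuating processes, in (0, 1]."""

    rayleigh: float
    ozone: float
    gas: float
    water: float
    aerosol: float


def transmittances(altitude_deg: float, atmos: AtmosphericParams) -> Transmittances:
    """Iqbal Model C parameterizations of the five broadband transmittances."""
    m = air_mass(altitude_deg)
    tau_r = math.exp(-0.0903 * m ** 0.84 * (1.0 + m - m ** 1.01))
    u3 = atmos.ozone_cm * m
    tau_o = 1.0 - (0.1611 * u3 * (1.0 + 139.48 * u3) ** -0.3035
                   - 0.002715 * u3
                   / (1.0 + 0.044 * u3 + 0.0003 * u3 ** 2))
    tau_g = math.exp(-0.0127 * m ** 0.26)
    u1 = atmos.water_cm * m
    tau_w = 1.0 - 2.4959 * u1 / ((1.0 + 79.034 * u1) ** 0.6828 + 6.385 * u1)
    # Aerosol transmittance from horizontal visibility (5-180 km validity).
    tau_a = (0.97 - 1.265 * atmos.visibility_km ** -0.66) ** (m ** 0.9)
    taus = Transmittances(tau_r, tau_o, tau_g, tau_w, tau_a)
    for name, v in vars(taus).items():
        if not 0.0 < v <= 1.0:
            raise ValueError(f"transmittance {name} = {v} outside (0, 1]")
    return taus


def direct_irradiance(state: SolarState, atmos: AtmosphericParams,
                      taus: Transmittances | None = None) -> float:
    """Direct-beam shortwave irradiance on a horizontal surface, W/m^2.

    0.9751 * I_sc * r0 * tau_r tau_o tau_g tau_w tau_a * sin(altitude);
    zero at or below the horizon.
    """
    if state.altitude <= 0:
        return 0.0
    if taus is None:
        taus = transmittances(state.altitude, atmos)
    return (SPECTRAL_FACTOR * atmos.solar_constant * state.r0
            * taus.rayleigh * taus.ozone * taus.gas * taus.water * taus.aerosol
            * math.sin(math.radians(state.altitude)))


def tau_aerosol_absorption(air_mass_value: float, tau_a: float,
                           omega_o: float = 0.9) -> float:
    """Transmittance of direct radiation due to aerosol absorptance:
    tau_aa = 1 - (1 - omega_o)(1 - m + m^1.02)(1 - tau_a)."""
    return 1.0 - (1.0 - omega_o) * (1.0 - air_mass_value
                                    + air_mass_value ** 1.02) * (1.0 - tau_a)


def sky_albedo(tau_as: float, forward_scatter_fraction: float = 0.84) -> float:
    """Cloudless-sky albedo rho_a = 0.0685 + (1 - F_c)(1 - tau_as)."""
    return 0.0685 + (1.0 - forward_scatter_fraction) * (1.0 - tau_as)


def diffuse_irradiance(state: SolarState, atmos: AtmosphericParams,
                       direct: float,
                       taus: Transmittances | None = None) -> IrradianceBreakdown:
    """Diffuse components (Rayleigh, aerosol, multiple-reflection), W/m^2.

    tau_aa = 1 - (1-omega_o)(1 - m + m^1.02)(1 - tau_a) is the aerosol
    absorptance transmittance, tau_as = tau_a/tau_aa the scattering part, and
    the sky albedo rho_a = 0.0685 + (1-F_c)(1-tau_as) closes the geometric
    series of ground-sky reflections.
    """
    if state.altitude <= 0:
        return IrradianceBreakdown.zero()
    if taus is None:
        taus = transmittances(state.altitude, atmos)
    m = air_mass(state.altitude)
    r0 = state.r0
    sin_a = math.sin(math.radians(state.altitude))
    isc = atmos.solar_constant

    tau_aa = tau_aerosol_absorption(m, taus.aerosol,
                                    atmos.single_scattering_albedo)
    tau_as = taus.aerosol / tau_aa

    denom = 1.0 - m + m ** 1.02
    common = isc * r0 * taus.ozone * taus.gas * taus.water * tau_aa * sin_a
    i_dr = common * (1.0 - taus.rayleigh) / (2.0 * denom)
    i_da = (atmos.aerosol_urban_factor * common
            * atmos.forward_scatter_fraction * (1.0 - tau_as) / denom)

    rho_a = sky_albedo(tau_as, atmos.forward_scatter_fraction)
    rho_g = atmos.ground_albedo
    if rho_g * rho_a >= 1.0:
        raise ValueError("rho_g * rho_a >= 1: multiple-reflection series diverges")
    i_dm = (direct + i_dr + i_da) * rho_g * rho_a / (1.0 - rho_g * rho_a)
    return IrradianceBreakdown(direct=direct, diffuse_rayleigh=i_dr,
                               diffuse_aerosol=i_da, diffuse_multireflect=i_dm)


def total_irradiance(site_time: SiteTime,
                     atmos: AtmosphericParams | None = None) -> IrradianceBreakdown:
    """Total clear-sky shortwave irradiance breakdown for a site and instant.

    Returns an all-zero breakdown when the Sun is at or below the horizon.
    """
    if atmos is None:
        atmos = AtmosphericParams()
    state = solar_position(site_time)
    if state.altitude <= 0:
        return IrradianceBreakdown.zero()
    taus = transmittances(state.altitude, atmos)
    direct = direct_irradiance(state, atmos, taus)
    return diffuse_irradiance(state, atmos, direct, taus)


def irradiance_table(latitude: float, days: Sequence[int], hours: Sequence[float],
                     atmos: AtmosphericParams | None = None,
                     longitude: float = 0.0) -> pd.DataFrame:
    """Hourly irradiance grid over dates: one row per (day, hour).

    Columns: day_of_year, hour, altitude, azimuth, direct, diffuse, total.
    """
    if len(days) == 0 or len(hours) == 0:
        raise ValueError("days and hours must be nonempty")
    rows = []
    for day in days:
        for hour in hours:
            st = SiteTime(latitude=latitude, day_of_year=int(day),
                          solar_time=float(hour), longitude=longitude)
            state = solar_position(st)
            bd = total_irradiance(st, atmos)
            rows.append({"day_of_year": int(day), "hour": float(hour),
                         "altitude": state.altitude, "azimuth": state.azimuth,
                         "direct": bd.direct, "diffuse": bd.diffuse_total,
                         "total": bd.total})
    return pd.DataFrame(rows)
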