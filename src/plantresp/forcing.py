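"""Synthetic gridded forcing and vegetation generator.

Stands in for the observational/emulated climate drivers of a land-surface
run so that every stage of the respiration chain is testable without
external data. Generated fields:

- daily near-surface air temperature with a latitudinal gradient, a
  hemisphere-phased seasonal cycle, an optional linear warming trend and
  Gaussian weather noise (leaf temperature is taken equal to air
  temperature);
- growth temperature T_G as the exact 10-day trailing mean of air
  temperature (the first nine days are back-filled with the day-1 value);
- daily-mean downward shortwave irradiance;
- per-PFT leaf area index and fractional cover from smooth latitude-
  dependent mixtures (tropics broadleaf-dominated, high latitudes
  needleleaf/shrub), with an agriculture remainder excluded from PFT cover;
- a soil-moisture stress factor beta in [0,1] with subtropical dry belts;
- a gross-primary-productivity driver increasing smoothly in irradiance
  and temperature.

Generation is a pure function of (config, seed). Real-data mode simply
bypasses this module: any object exposing the same arrays can drive the
experiment runner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pfts import PFT_NAMES

EARTH_RADIUS_M = 6.371e6


@dataclass(frozen=True)
class GridConfig:
    """Regular latitude-longitude grid specification (degrees)."""

    n_lat: int = 72
    n_lon: int = 96
    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -180.0
    lon_max: float = 180.0

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must have at least one cell per axis")
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ValueError("degenerate grid extent")
        if self.lat_min < -90.0 or self.lat_max > 90.0:
            raise ValueError("latitude extent outside [-90, 90]")


@dataclass(frozen=True)
class GridDomain:
    """Cell-centre coordinates, land mask and spherical-cap cell areas."""

    lat: np.ndarray          # (n_lat,) cell centres, ascending
    lon: np.ndarray          # (n_lon,)
    land_mask: np.ndarray    # (n_lat, n_lon) bool
    area: np.ndarray         # (n_lat, n_lon) m^2

    @property
    def shape(self) -> tuple[int, int]:
        return self.land_mask.shape


def make_grid(config: GridConfig = GridConfig(),
              land_mask: np.ndarray | None = None) -> GridDomain:
    """Build a regular grid; cell area = R^2 * dlon * (sin(lat2) - sin(lat1)).

    The default mask is all-land (the generator has no ocean model); pass an
    explicit boolean mask to restrict the domain.
    """
    c = config
    lat_edges = np.linspace(c.lat_min, c.lat_max, c.n_lat + 1)
    lon_edges = np.linspace(c.lon_min, c.lon_max, c.n_lon + 1)
    lat = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    dlon_rad = np.deg2rad(lon_edges[1] - lon_edges[0])
    band = EARTH_RADIUS_M ** 2 * dlon_rad * np.diff(np.sin(np.deg2rad(lat_edges)))
    area = np.repeat(band[:, None], c.n_lon, axis=1)
    if land_mask is None:
        land_mask = np.ones((c.n_lat, c.n_lon), dtype=bool)
    else:
        land_mask = np.asarray(land_mask, dtype=bool)
        if land_mask.shape != (c.n_lat, c.n_lon):
            raise ValueError("land mask shape does not match grid")
    return GridDomain(lat=lat, lon=lon, land_mask=land_mask, area=area)


@dataclass(frozen=True)
class ClimateScenario:
    """Statistical description of the synthetic climate.

    air T(t, lat) = t_pole_offset + t_gradient*cos(lat)
                    + seasonal_amplitude*sin(lat)*sin(2 pi (d - phase)/365)
                    + warming_rate * t_years + noise.
    """

    t_pole_offset: float = -12.0   # degC at the poles
    t_gradient: float = 38.0       # equator-pole contrast, degC
    seasonal_amplitude: float = 8.0  # degC at the poles, hemisphere-phased
    warming_rate: float = 0.0      # degC per year
    noise_std: float = 2.0         # daily weather noise, degC
    n_days: int = 365
    sw_max: float = 250.0          # peak daily-mean shortwave, W m^-2
    sw_floor: float = 0.25         # polar fraction of sw_max

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError("noise std must be non-negative")
        if self.n_days < 1:
            raise ValueError("need at least one day")


@dataclass
class ForcingFields:
    """Daily climate forcing on the grid (time, lat, lon)."""

    air_temp: np.ndarray
    t_growth: np.ndarray
    irradiance: np.ndarray


@dataclass
class VegetationFields:
    """Per-PFT vegetation state plus shared beta and GPP driver."""

    lai: np.ndarray     # (pft, lat, lon)
    frac: np.ndarray    # (pft, lat, lon)
    beta: np.ndarray    # (lat, lon)
    gpp: np.ndarray     # (time, lat, lon), umol CO2 m^-2 s^-1


def trailing_mean_10day(series: np.ndarray, axis: int = 0) -> np.ndarray:
    """Exact 10-day trailing mean along ``axis``; the window before day 10
    is filled by repeating the first sample (back-fill initialisation)."""
    x = np.moveaxis(np.asarray(series, dtype=float), axis, 0)
    pad = np.repeat(x[:1], 9, axis=0)
    xp = np.concatenate([pad, x], axis=0)
    cs = np.cumsum(xp, axis=0)
    out = (cs[9:] - np.concatenate([np.zeros_like(cs[:1]), cs[:-10]], axis=0)) / 10.0
    return np.moveaxis(out, 0, axis)


def generate_climate(domain: GridDomain, scenario: ClimateScenario = ClimateScenario(),
                     seed: int = 0) -> ForcingFields:
    """Generate the daily temperature and irradiance fields (seeded)."""
    rng = np.random.default_rng(seed)
    sc = scenario
    days = np.arange(sc.n_days, dtype=float)
    lat_r = np.deg2rad(domain.lat)
    n_lon = domain.lon.size

    base = sc.t_pole_offset + sc.t_gradient * np.cos(lat_r)          # (lat,)
    season = (sc.seasonal_amplitude * np.sin(lat_r)[None, :]
              * np.sin(2.0 * np.pi * (days[:, None] - 36.0) / 365.0))  # (t, lat)
    trend = sc.warming_rate * days / 365.0                            # (t,)
    t2d = base[None, :] + season + trend[:, None]
    air = (t2d[:, :, None]
           + rng.normal(0.0, sc.noise_std, size=(sc.n_days, domain.lat.size, n_lon)))

    sw_lat = sc.sw_max * (sc.sw_floor + (1.0 - sc.sw_floor) * np.cos(lat_r))
    sw_season = 1.0 + 0.3 * np.sin(lat_r)[None, :] * np.sin(
        2.0 * np.pi * (days[:, None] - 36.0) / 365.0)
    sw = np.clip(sw_lat[None, :] * sw_season, 0.0, None)
    irr = np.repeat(sw[:, :, None], n_lon, axis=2)

    return ForcingFields(air_temp=air,
                         t_growth=trailing_mean_10day(air, axis=0),
                         irradiance=irr)


#: Latitude-mixture parameters per PFT: (centre |lat| deg, width deg, weight).
_PFT_BUMPS = {
    "broadleaf_tree": (0.0, 18.0, 1.0),
    "needleleaf_tree": (55.0, 10.0, 0.9),
    "shrub": (68.0, 14.0, 0.8),
    "c3_grass": (35.0, 12.0, 0.7),
    "c4_grass": (12.0, 8.0, 0.5),
}

#: Maximum leaf area index per PFT at its preferred latitude.
_PFT_LAI_MAX = {
    "broadleaf_tree": 5.0,
    "needleleaf_tree": 4.0,
    "shrub": 1.5,
    "c3_grass": 2.0,
    "c4_grass": 2.5,
}

AGRICULTURE_FRACTION = 0.15


def generate_vegetation(domain: GridDomain, seed: int = 0,
                        climate: ForcingFields | None = None,
                        gpp_max: float = 15.0,
                        agriculture_fraction: float = AGRICULTURE_FRACTION,
                        lai_jitter: float = 0.1) -> VegetationFields:
    """Generate per-PFT cover and LAI, soil-moisture beta, and a GPP driver.

    Cover is a smooth latitude mixture normalised so the five PFTs sum to
    (1 - agriculture_fraction) on every cell; an equatorial cell is always
    broadleaf-dominated. The GPP driver is Michaelis-type in irradiance
    times a logistic ramp in temperature (monotone increasing in both).
    When no climate is supplied the driver uses the latitudinal radiation
    profile alone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    alat = np.abs(domain.lat)
    w = np.empty((len(PFT_NAMES), domain.lat.size))
    for i, name in enumerate(PFT_NAMES):
        centre, width, weight = _PFT_BUMPS[name]
        w[i] = weight * np.exp(-((alat - centre) / width) ** 2)
    w /= np.sum(w, axis=0, keepdims=True)
    frac = (1.0 - agriculture_fraction) * np.repeat(
        w[:, :, None], domain.lon.size, axis=2)

    suit = w / np.max(w, axis=1, keepdims=True)  # 1 at each PFT's best latitude
    lai_lat = np.array([_PFT_LAI_MAX[n] for n in PFT_NAMES])[:, None] * suit
    jitter = rng.lognormal(0.0, lai_jitter, size=(len(PFT_NAMES),
                                                  domain.lat.size, domain.lon.size))
    lai = lai_lat[:, :, None] * jitter

    dry_belt = 0.35 * np.exp(-((alat - 20.0) / 10.0) ** 2)
    beta = np.clip(1.0 - dry_belt[:, None]
                   + rng.normal(0.0, 0.03, size=domain.shape), 0.0, 1.0)

    if climate is not None:
        sw = climate.irradiance
        t = climate.air_temp
    else:
        sw = (250.0 * (0.25 + 0.75 * np.cos(np.deg2rad(domain.lat))))[None, :, None] \
            * np.ones((1,) + domain.shape)
        t = (-12.0 + 38.0 * np.cos(np.deg2rad(domain.lat)))[None, :, None] \
            * np.ones((1,) + domain.shape)
    gpp = gpp_max * (sw / (sw + 150.0)) / (1.0 + np.exp(-0.25 * (t - 8.0)))

    return VegetationFields(lai=lai, frac=frac, beta=beta, gpp=gpp)
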