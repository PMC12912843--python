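"""Seeded synthetic lake scenes and surveys with the structure the analysis assumes.

The generator emulates the statistical features the downstream pipeline
relies on, without claiming radiative-transfer realism:

* chlorophyll = shore-distance ramp + Gaussian estuary hotspots, modulated
  by a sinusoidal season peaking near day-of-year 200 (mid-July), with
  multiplicative lognormal pixel noise;
* surface temperature follows a smooth 0-25 degC seasonal curve with small
  additive Gaussian noise;
* daily PAR and daylength come from standard solar-declination geometry at
  the configured latitude (clear-sky transmittance 0.7, PAR fraction 0.45);
* Kd490 increases linearly with chlorophyll, so the euphotic depth is
  shallower in productive estuary water;
* random cloud/quality gaps flag pixel-days non-nominal;
* an August acoustic survey whose segment densities integrate exactly to a
  known true biomass in the zero-noise limit, plus a gill-net length/weight
  sample following W = 0.01 L^3.

Every output is a pure function of (config, date/year), so identical
configurations reproduce bit-identical data.
"""

from __future__ import annotations

import calendar
import datetime
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ConfigurationError, SceneConfig
from .scenes import GridScene, TruthRecord
from . import vgpm

__all__ = [
    "default_lake_geometry",
    "generate_scene",
    "generate_series",
    "generate_survey",
    "lake_volume_m3",
    "seasonal_factor",
    "daily_par",
]

SEASON_MONTHS = (5, 6, 7, 8, 9, 10)
_SEASON_PEAK_DOY = 200.0  # chlorophyll maximum, mid-July
_ESTUARY_SIGMA_CELLS = 2.0
_ESTUARY_AMPLITUDE = 2.0  # in units of chl_base
_KD490_OFFSET, _KD490_PER_CHL = 0.08, 0.08  # m^-1 and m^-1 per mg m^-3
_LW_A, _LW_B = 0.01, 3.0  # weight [g] = a * length[cm]^b


def default_lake_geometry(grid_shape: Tuple[int, int]) -> np.ndarray:
    """Inscribed-ellipse water template leaving a one-cell land rim."""
    rows, cols = grid_shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc = np.mgrid[0:rows, 0:cols]
    a = max(rows / 2.0 - 1.0, 0.5)
    b = max(cols / 2.0 - 1.0, 0.5)
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


def _water(config: SceneConfig) -> np.ndarray:
    if config.lake_geometry is not None:
        return config.lake_geometry
    return default_lake_geometry(tuple(config.grid_shape))


def lake_volume_m3(config: SceneConfig) -> float:
    """Water-cell area (1 km^2 cells) times the constant lake depth."""
    return float(_water(config).sum()) * 1e6 * config.lake_depth_m


def seasonal_factor(day_of_year: float, amplitude: float) -> float:
    """Sinusoidal seasonal modulation, maximum at day-of-year ~200."""
    return 1.0 + amplitude * np.cos(2.0 * np.pi * (day_of_year - _SEASON_PEAK_DOY) / 365.0)


def daily_par(latitude_deg: float, day_of_year: int) -> float:
    """Clear-sky daily PAR [mol quanta m^-2 day^-1] from solar geometry.

    Extraterrestrial daily insolation scaled by a bulk atmospheric
    transmittance (0.7), the PAR fraction of shortwave (0.45) and the
    energy-to-quanta conversion (4.57 umol quanta per J of PAR).
    """
    S = 1361.0  # W m^-2
    doy = float(day_of_year)
    decl = np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    lat = np.deg2rad(latitude_deg)
    ws = np.arccos(np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0))
    h0 = (86400.0 * S / np.pi) * (1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)) * (
        np.cos(lat) * np.cos(decl) * np.sin(ws) + ws * np.sin(lat) * np.sin(decl)
    )
    return float(max(h0, 0.0) * 0.7 * 0.45 * 4.57e-6)


def _true_chl_pattern(config: SceneConfig) -> np.ndarray:
    """Season-independent chlorophyll pattern: shore ramp + estuary bumps (NaN on land)."""
    water = _water(config)
    dist = ndimage.distance_transform_edt(water)
    dmax = dist.max() if dist.max() > 0 else 1.0
    shore = 1.0 + config.chl_shore_gain * (1.0 - dist / dmax)
    field = config.chl_base * shore
    rows, cols = water.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    for (er, ec) in config.estuary_centres:
        d2 = (rr - er) ** 2 + (cc - ec) ** 2
        field = field + _ESTUARY_AMPLITUDE * config.chl_base * np.exp(
            -d2 / (2.0 * _ESTUARY_SIGMA_CELLS**2)
        )
    out = np.where(water, field, np.nan)
    return out


def _true_sst(day_of_year: float) -> float:
    """Smooth seasonal surface temperature, 0 degC (mid-January) to 25 degC (mid-July)."""
    return 12.5 * (1.0 - np.cos(2.0 * np.pi * (day_of_year - 15.0) / 365.0))


def _scene_rng(config: SceneConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *[int(k) for k in keys]])


def generate_scene(config: SceneConfig, date: datetime.date) -> Tuple[GridScene, TruthRecord]:
    """One day's rasters plus the noise-free truth used by recovery tests."""
    if date.month not in SEASON_MONTHS and not config.allow_off_season:
        raise ConfigurationError(
            f"date {date} outside the May-October open-water season "
            "(set allow_off_season=True to permit)"
        )
    water = _water(config)
    doy = date.timetuple().tm_yday
    rng = _scene_rng(config, date.year, doy)

    season = seasonal_factor(doy, config.season_amplitude)
    true_chl = _true_chl_pattern(config) * season
    sst_true = _true_sst(doy)
    par_val = daily_par(config.latitude_deg, doy)
    kd490 = np.where(water, _KD490_OFFSET + _KD490_PER_CHL * true_chl, np.nan)
    dirr = vgpm.daylength(config.latitude_deg, doy)
    true_pp = np.where(
        water,
        vgpm.vgpm_daily(
            np.where(water, true_chl, 0.0), sst_true,
            np.full(water.shape, par_val), np.where(water, kd490, 1.0),
            dirr, depth_cap_m=config.lake_depth_m,
        ),
        np.nan,
    )

    if config.noise_cv > 0:
        sigma2 = np.log1p(config.noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=water.shape)
    else:
        noise = np.ones(water.shape)
    chl = np.where(water, true_chl * noise, np.nan)
    sst = np.where(
        water, sst_true + config.sst_noise_sd * rng.standard_normal(water.shape), np.nan
    )
    par = np.where(water, par_val, np.nan)

    cloud = rng.random(water.shape) < config.cloud_fraction
    flags = np.where(water & cloud, 1, 0)
    straylight = np.zeros(water.shape)
    risky = rng.random(water.shape) < config.straylight_fraction
    straylight[risky] = rng.uniform(5.0, 10.0, size=int(risky.sum()))
    ice = np.where(date.month in SEASON_MONTHS, 0, 1) * np.ones(water.shape, dtype=int)

    scene = GridScene(
        date=date, chl=chl, sst=sst, par=par, kd490=kd490,
        flags=flags, straylight_pct=straylight, ice=ice, water=water,
    )
    truth = TruthRecord(true_chl=np.where(water, true_chl, np.nan), true_pp=true_pp)
    return scene, truth


def generate_series(
    config: SceneConfig,
    years: Sequence[int],
    months: Sequence[int] = SEASON_MONTHS,
) -> Tuple[List[GridScene], List[TruthRecord], Dict[Tuple[int, int], np.ndarray]]:
    """Daily scenes for every (year, month), plus per-month nominal-day counts per cell.

    The count map lets callers check the >=5-valid-day compositing rule
    before building composites.
    """
    if len(years) == 0 or len(months) == 0:
        raise ConfigurationError("years/months: must be non-empty")
    bad = [m for m in months if m not in SEASON_MONTHS]
    if bad and not config.allow_off_season:
        raise ConfigurationError(f"months: {bad} outside the May-October season")
    scenes: List[GridScene] = []
    truths: List[TruthRecord] = []
    nominal_days: Dict[Tuple[int, int], np.ndarray] = {}
    for year in years:
        for month in months:
            counts = np.zeros(tuple(config.grid_shape), dtype=int)
            for day in range(1, calendar.monthrange(year, month)[1] + 1):
                scene, truth = generate_scene(config, datetime.date(year, month, day))
                scenes.append(scene)
                truths.append(truth)
                counts += (
                    scene.water
                    & (scene.flags == 0)
                    & (scene.straylight_pct < 5.0)
                    & (scene.ice == 0)
                ).astype(int)
            nominal_days[(year, month)] = counts
    return scenes, truths, nominal_days


def generate_survey(
    config: SceneConfig,
    year: int,
    true_biomass_t: float,
    sampling_cv: float = 0.05,
    n_segments: int = 40,
    n_fish: int = 200,
    length_mean_cm: float = 25.0,
    length_sd_cm: float = 4.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Acoustic transect densities and a gill-net sample consistent with a known biomass.

    The gill-net lengths are unimodal (normal, truncated to [8, 45] cm) and
    weights follow W = 0.01 L^3. Segment densities are the biomass-closing
    base density d0 = B*1e6 / (mean weight * lake volume) perturbed by
    mean-one lognormal noise of the given CV, so the implied biomass
    (mean density x mean weight x volume x 1e-6) equals ``true_biomass_t``
    exactly when ``sampling_cv`` is 0 and within the CV otherwise.
    """
    if true_biomass_t <= 0:
        raise ConfigurationError("true_biomass_t: must be > 0")
    if sampling_cv < 0:
        raise ConfigurationError("sampling_cv: must be >= 0")
    rng = _scene_rng(config, year, 8888)
    lengths = np.clip(
        rng.normal(length_mean_cm, length_sd_cm, size=n_fish), 8.0, 45.0
    )
    weights = _LW_A * lengths**_LW_B
    gillnet = pd.DataFrame(
        {"fish_id": np.arange(1, n_fish + 1), "length_cm": lengths, "weight_g": weights}
    )
    volume = lake_volume_m3(config)
    d0 = true_biomass_t * 1e6 / (weights.mean() * volume)
    if sampling_cv > 0:
        sigma2 = np.log1p(sampling_cv**2)
        mult = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n_segments)
    else:
        mult = np.ones(n_segments)
    densities = pd.DataFrame(
        {"segment_id": np.arange(1, n_segments + 1), "density_ind_per_m3": d0 * mult}
    )
    return densities, gillnet
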