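"""Vertically Generalised Production Model (VGPM) primary production.

Depth-integrated daily phytoplankton primary production is estimated from
surface chlorophyll, surface temperature, photosynthetically active
radiation (PAR), euphotic depth and daylength:

    PP = 0.66125 * PBopt(T) * E0 / (E0 + 4.1) * Zeu * Chl * Dirr

with PP in mg C m^-2 day^-1, Chl in mg m^-3, E0 (daily PAR) in
mol quanta m^-2 day^-1, Zeu in m and Dirr (daylength) in hours.
PBopt, the optimal chlorophyll-specific carbon fixation rate
(mg C (mg Chl)^-1 h^-1), follows the published seventh-order polynomial in
temperature with its constant clamps outside [-1, 28.5] degC. The euphotic
(1% surface light) depth is derived from the diffuse attenuation
coefficient Kd490 through a KdPAR relation and capped at the lake depth so
no production is credited below the lakebed.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "popt_b",
    "kd_par_from_kd490",
    "euphotic_depth",
    "daylength",
    "vgpm_daily",
    "monthly_pp",
    "PPField",
]

# PBopt(T) polynomial coefficients, ascending order (T in degC), and clamps
# as published for the VGPM: 1.13 below -1 degC, 4.00 above 28.5 degC, zero
# below -10 degC. The clamp constants do not exactly equal the polynomial at
# the handoff temperatures (1.1055 at -1, 4.0231 at 28.5); the published
# piecewise form is kept as-is.
_PBOPT_COEFFS = np.array(
    [1.2956, 2.749e-1, 6.17e-2, -2.05e-2, 2.462e-3, -1.348e-4, 3.4132e-6, -3.27e-8]
)
_PBOPT_LOW_T, _PBOPT_LOW = -1.0, 1.13
_PBOPT_HIGH_T, _PBOPT_HIGH = 28.5, 4.00
_PBOPT_FREEZE_T = -10.0


def popt_b(sst):
    """Optimal photosynthetic rate PBopt [mg C (mg Chl)^-1 h^-1] at temperature ``sst`` [degC]."""
    t = np.asarray(sst, dtype=float)
    poly = np.polynomial.polynomial.polyval(np.clip(t, _PBOPT_LOW_T, _PBOPT_HIGH_T), _PBOPT_COEFFS)
    out = np.where(t < _PBOPT_LOW_T, _PBOPT_LOW, poly)
    out = np.where(t > _PBOPT_HIGH_T, _PBOPT_HIGH, out)
    out = np.where(t < _PBOPT_FREEZE_T, 0.0, out)
    return out if np.ndim(sst) else float(out)


def kd_par_from_kd490(kd490, relation: Optional[Callable] = None):
    """Diffuse attenuation of PAR [m^-1] from Kd490 [m^-1].

    The default relation is the empirical broadband form
    ``KdPAR = 0.0665 + 0.874*Kd490 - 0.00121/Kd490`` (valid for typical lake
    Kd490 > ~0.02 m^-1), floored at a small positive value; any other
    callable ``kd490 -> kd_par`` may be supplied.
    """
    k = np.asarray(kd490, dtype=float)
    if np.any(k[np.isfinite(k)] <= 0):
        raise ValueError("kd490 must be > 0")
    if relation is None:
        kp = 0.0665 + 0.874 * k - 0.00121 / k
    else:
        kp = np.asarray(relation(k), dtype=float)
    kp = np.maximum(kp, 1e-6)
    return kp if np.ndim(kd490) else float(kp)


def euphotic_depth(kd_par, depth_cap_m: float = 20.0):
    """Euphotic (1% light) depth Zeu = ln(100)/KdPAR [m], capped at the lake depth."""
    kp = np.asarray(kd_par, dtype=float)
    if np.any(kp[np.isfinite(kp)] <= 0):
        raise ValueError("kd_par must be > 0")
    zeu = np.minimum(np.log(100.0) / kp, depth_cap_m)
    return zeu if np.ndim(kd_par) else float(zeu)


def daylength(latitude_deg: float, day_of_year) -> float:
    """Astronomical daylength [h] from solar declination geometry.

    Valid only for sub-polar latitudes (|lat| < 66.5 deg); day_of_year in 1..366.
    """
    if abs(latitude_deg) >= 66.5:
        raise ValueError("daylength undefined at polar latitudes (|lat| >= 66.5 deg)")
    doy = np.asarray(day_of_year, dtype=float)
    decl = np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    lat = np.deg2rad(latitude_deg)
    cos_ha = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    hours = 2.0 * np.rad2deg(np.arccos(cos_ha)) / 15.0
    return hours if np.ndim(day_of_year) else float(hours)


def vgpm_daily(chl, sst, par, kd490, dirr_hours, depth_cap_m: float = 20.0):
    """Daily depth-integrated primary production [mg C m^-2 day^-1].

    NaNs propagate (undefined inputs give undefined production); output is
    non-negative and linear in chlorophyll with the other inputs held fixed.
    """
    chl = np.asarray(chl, dtype=float)
    par = np.asarray(par, dtype=float)
    finite = np.isfinite(chl)
    if np.any(chl[finite] < 0):
        raise ValueError("chl must be >= 0")
    if np.any(par[np.isfinite(par)] < 0):
        raise ValueError("par must be >= 0")
    d = np.asarray(dirr_hours, dtype=float)
    if np.any((d < 0) | (d > 24)):
        raise ValueError("dirr_hours must be within [0, 24]")
    zeu = euphotic_depth(kd_par_from_kd490(kd490), depth_cap_m)
    light = par / (par + 4.1)
    pp = 0.66125 * popt_b(sst) * light * zeu * chl * d
    return pp if pp.ndim else float(pp)


@dataclass
class PPField:
    """Primary production for one calendar month on the lake grid."""

    year: int
    month: int
    pp_daily: np.ndarray  # mg C m^-2 day^-1
    pp_monthly: np.ndarray  # mg C m^-2 month^-1
    zeu: np.ndarray  # m
    popt_b: np.ndarray  # mg C (mg Chl)^-1 h^-1


def monthly_pp(composite, latitude_deg: float = 36.9, depth_cap_m: float = 20.0) -> PPField:
    """Monthly primary production from a gap-filled monthly composite.

    The VGPM is evaluated on the composite (monthly-mean) inputs with the
    daylength of the month's middle day, then scaled by days-in-month:
    pp_monthly = pp_daily * n_days. Cells undefined in the composite stay
    undefined (NaN).
    """
    n_days = calendar.monthrange(composite.year, composite.month)[1]
    mid_doy = _day_of_year(composite.year, composite.month, 15)
    dirr = daylength(latitude_deg, mid_doy)
    kd = np.where(composite.kd490 > 0, composite.kd490, np.nan)
    pp_d = vgpm_daily(composite.chl, composite.sst, composite.par, kd, dirr, depth_cap_m)
    return PPField(
        year=composite.year,
        month=composite.month,
        pp_daily=pp_d,
        pp_monthly=pp_d * n_days,
        zeu=euphotic_depth(kd_par_from_kd490(kd), depth_cap_m),
        popt_b=popt_b(composite.sst),
    )


def _day_of_year(year: int, month: int, day: int) -> int:
    import datetime

    return datetime.date(year, month, day).timetuple().tm_yday
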