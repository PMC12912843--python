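"""Scene quality control, compositing, gap-filling and matchup calibration.

The processing contract mirrors standard ocean-colour practice for lakes:

* a **unified lake mask** is the minimum water extent over the full scene
  archive, so shrinking or flickering shorelines cannot masquerade as
  productivity trends;
* a pixel-day is **valid** only if retrieval flags are nominal (0),
  straylight risk < 5% and ice cover = 0;
* **monthly composites** are per-cell means over valid days and require at
  least ``min_valid_days`` (default 5) valid days, otherwise the cell is
  undefined for that month;
* interior temporal gaps are **linearly interpolated** per cell, but only
  when the cell's missing-month fraction stays below 10%;
* satellite/field **matchups** take the median of a pixel box centred on
  the station and are valid within a +/-12 h window when the box
  SD/mean < 20%;
* a **type II (reduced major axis) regression** on valid matchups yields
  the chlorophyll correction applied before production modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .scenes import GridScene

__all__ = [
    "LakeMask",
    "MonthlyComposite",
    "MatchupPair",
    "CorrectionModel",
    "build_lake_mask",
    "apply_quality_filters",
    "monthly_composite",
    "gap_fill",
    "extract_matchup",
    "fit_chla_correction",
    "apply_chla_correction",
    "split_matchups",
]

STRAYLIGHT_MAX_PCT = 5.0
MATCHUP_WINDOW_H = 12.0
MATCHUP_SD_OVER_MEAN_MAX = 0.20


@dataclass
class LakeMask:
    water: np.ndarray  # minimum-extent water mask
    excluded_fraction: float  # fraction of ever-wet cells removed


@dataclass
class MonthlyComposite:
    year: int
    month: int
    chl: np.ndarray
    sst: np.ndarray
    par: np.ndarray
    kd490: np.ndarray
    valid_days: np.ndarray  # int per cell
    filled: np.ndarray  # bool per cell


@dataclass
class MatchupPair:
    station_id: str
    variable_name: str
    satellite_value: float
    field_value: float
    time_offset_h: float
    box_sd_over_mean: float
    valid: bool


@dataclass
class CorrectionModel:
    slope: float
    intercept: float  # mg m^-3
    n_fit: int
    fit_method: str = "reduced_major_axis"


def build_lake_mask(scenes: Sequence[GridScene]) -> LakeMask:
    """Minimum-extent water mask over all scenes, with the excluded fraction of ever-wet cells."""
    if len(scenes) == 0:
        raise ValueError("build_lake_mask needs at least one scene")
    always = np.ones(scenes[0].shape, dtype=bool)
    ever = np.zeros(scenes[0].shape, dtype=bool)
    for sc in scenes:
        always &= sc.water
        ever |= sc.water
    n_ever = int(ever.sum())
    excluded = 0.0 if n_ever == 0 else float((n_ever - always.sum()) / n_ever)
    return LakeMask(water=always, excluded_fraction=excluded)


def apply_quality_filters(scene: GridScene) -> Tuple[GridScene, int]:
    """Invalidate data layers where quality criteria fail; return (scene, n_valid).

    A water cell passes iff flags == 0, straylight risk < 5% and ice == 0.
    Failing cells (and land) get NaN in chl/sst/par/kd490.
    """
    ok = (
        scene.water
        & (scene.flags == 0)
        & (scene.straylight_pct < STRAYLIGHT_MAX_PCT)
        & (scene.ice == 0)
    )
    out = scene.copy()
    for name in ("chl", "sst", "par", "kd490"):
        layer = out.__dict__[name].astype(float)
        layer[~ok] = np.nan
        out.__dict__[name] = layer
    return out, int(ok.sum())


def monthly_composite(
    scenes: Sequence[GridScene],
    mask: LakeMask,
    min_valid_days: int = 5,
    stat: str = "mean",
) -> MonthlyComposite:
    """Per-cell composite over valid days; cells with < min_valid_days stay undefined."""
    if len(scenes) == 0:
        raise ValueError("no scenes to composite")
    ym = {(s.date.year, s.date.month) for s in scenes}
    if len(ym) > 1:
        raise ValueError(f"scenes span multiple months: {sorted(ym)}")
    (year, month), = ym
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown composite statistic: {stat}")
    reduce_ = np.nanmean if stat == "mean" else np.nanmedian

    filtered = [apply_quality_filters(s)[0] for s in scenes]
    stacks = {
        name: np.stack([getattr(s, name) for s in filtered]) for name in ("chl", "sst", "par", "kd490")
    }
    valid_days = np.isfinite(stacks["chl"]).sum(axis=0).astype(int)
    defined = (valid_days >= min_valid_days) & mask.water
    out = {}
    with np.errstate(invalid="ignore"):
        for name, stack in stacks.items():
            comp = np.full(stack.shape[1:], np.nan)
            if defined.any():
                comp[defined] = reduce_(stack[:, defined], axis=0)
            out[name] = comp
    valid_days = np.where(mask.water, valid_days, 0)
    return MonthlyComposite(
        year=year,
        month=month,
        valid_days=valid_days,
        filled=np.zeros_like(defined, dtype=bool),
        **out,
    )


def gap_fill(
    series: Sequence[MonthlyComposite],
    max_missing_fraction: float = 0.10,
) -> List[MonthlyComposite]:
    """Fill interior temporal gaps per cell by linear interpolation in time.

    A cell is eligible only if its missing fraction over the series is
    below ``max_missing_fraction``; leading/trailing gaps are never
    extrapolated. Filled cells are flagged ``filled=True``. The input
    series must be time-ordered.
    """
    order = [(c.year, c.month) for c in series]
    if order != sorted(order):
        raise ValueError("series must be time-ordered")
    if len(series) < 3:
        return list(series)
    t = np.arange(len(series), dtype=float)
    chl_stack = np.stack([c.chl for c in series])
    missing = ~np.isfinite(chl_stack)
    frac_missing = missing.mean(axis=0)
    eligible = (frac_missing > 0) & (frac_missing < max_missing_fraction)
    out = [
        replace(c, chl=c.chl.copy(), sst=c.sst.copy(), par=c.par.copy(),
                kd490=c.kd490.copy(), filled=c.filled.copy())
        for c in series
    ]
    for r, c in zip(*np.nonzero(eligible)):
        known = ~missing[:, r, c]
        if known.sum() < 2:
            continue
        lo, hi = t[known].min(), t[known].max()
        interior = missing[:, r, c] & (t > lo) & (t < hi)
        if not interior.any():
            continue
        for name in ("chl", "sst", "par", "kd490"):
            col = np.array([getattr(comp, name)[r, c] for comp in out])
            kn = np.isfinite(col)
            filled_vals = np.interp(t[interior], t[kn], col[kn])
            for ti, val in zip(np.nonzero(interior)[0], filled_vals):
                getattr(out[ti], name)[r, c] = val
        for ti in np.nonzero(interior)[0]:
            out[ti].filled[r, c] = True
    return out


def extract_matchup(
    scene: GridScene,
    row: int,
    col: int,
    field_value: float,
    time_offset_h: float,
    variable: str = "chl",
    box_size: int = 1,
    station_id: str = "",
) -> MatchupPair:
    """Median-of-box satellite value paired with a field measurement.

    The box (default 1 cell on the 1 km grid, configurable to 3x3 for
    sub-pixel stations) is centred on the station; validity requires
    |time offset| <= 12 h and box SD/mean < 20%.
    """
    rows, cols = scene.shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise ValueError(f"station ({row}, {col}) outside grid {scene.shape}")
    if variable not in ("chl", "sst", "par", "kd490"):
        raise ValueError(f"unknown variable: {variable}")
    half = box_size // 2
    box = getattr(scene, variable)[
        max(0, row - half): row + half + 1, max(0, col - half): col + half + 1
    ]
    vals = box[np.isfinite(box)]
    if vals.size == 0:
        sat, sd_over_mean = np.nan, np.inf
    else:
        sat = float(np.median(vals))
        mu = float(np.mean(vals))
        sd_over_mean = float(np.std(vals) / mu) if mu != 0 else np.inf
    valid = (
        np.isfinite(sat)
        and abs(time_offset_h) <= MATCHUP_WINDOW_H
        and sd_over_mean < MATCHUP_SD_OVER_MEAN_MAX
    )
    return MatchupPair(
        station_id=station_id,
        variable_name=variable,
        satellite_value=sat,
        field_value=float(field_value),
        time_offset_h=float(time_offset_h),
        box_sd_over_mean=sd_over_mean,
        valid=bool(valid),
    )


def split_matchups(
    matchups: Sequence[MatchupPair], fit_fraction: float = 0.5
) -> Tuple[List[MatchupPair], List[MatchupPair]]:
    """Chronological calibration/validation split (earliest fraction fits, rest validates)."""
    if not 0 < fit_fraction < 1:
        raise ValueError("fit_fraction must be in (0, 1)")
    n_fit = max(1, int(round(len(matchups) * fit_fraction)))
    return list(matchups[:n_fit]), list(matchups[n_fit:])


def fit_chla_correction(matchups: Iterable[MatchupPair]) -> CorrectionModel:
    """Type II (reduced major axis) regression of field on satellite chlorophyll.

    RMA treats both coordinates as error-bearing: slope = sign(r)*sd(y)/sd(x),
    intercept = mean(y) - slope*mean(x). Only valid matchups enter the fit.
    """
    valid = [m for m in matchups if m.valid]
    if len(valid) < 3:
        raise ValueError(f"need >= 3 valid matchups, got {len(valid)}")
    x = np.array([m.satellite_value for m in valid])
    y = np.array([m.field_value for m in valid])
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in matchup values; correction undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * float(sy / sx)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return CorrectionModel(slope=slope, intercept=intercept, n_fit=len(valid))


def apply_chla_correction(chl, model: CorrectionModel):
    """chl' = slope*chl + intercept, clipped at zero. Accepts arrays or a MonthlyComposite."""
    if isinstance(chl, MonthlyComposite):
        return replace(chl, chl=apply_chla_correction(chl.chl, model))
    arr = np.asarray(chl, dtype=float)
    out = np.maximum(model.slope * arr + model.intercept, 0.0)
    return out if out.ndim else float(out)
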