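"""Fish Carrying Capacity Index (FCCI): annual ratio, spatial maps and zoning.

FCCI = FP / Gross Annual FPP — the observed fish population biomass over
the fish biomass the year's primary production can sustain. An index at or
below 1 means the food-energy supply exceeds the population's demand;
values above 1 indicate overexploitation. Management reporting uses strict
thresholds: < 0.3 underutilised, > 0.5 high food-demand pressure, > 0.6
over the empirical overexploitation benchmark, > 1.0 beyond the
theoretical maximum sustainable yield. Boundary values fall to the
lower-severity class, mirroring the strict printed inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .config import ThresholdConfig

__all__ = [
    "FCCIRecord",
    "fcci_annual",
    "fcci_map",
    "classify_zones",
    "allocate_fp",
    "ZONE_LABELS",
]

ZONE_LABELS = ("underutilised", "moderate", "high_pressure", "over_benchmark", "overexploited")


@dataclass
class FCCIRecord:
    year: int
    fp_t: float
    gross_annual_fpp_t: float
    fcci: float
    status: str


def _status(fcci: float, thr: ThresholdConfig) -> str:
    if fcci > thr.max_sustainable:
        return "overexploited"
    if fcci == thr.max_sustainable:
        return "at_theoretical_maximum"
    if fcci > thr.benchmark:
        return "over_benchmark"
    if fcci > thr.high_pressure:
        return "high_pressure"
    if fcci < thr.underutilised:
        return "underutilised"
    return "moderate"


def fcci_annual(
    fp_t: float,
    gross_annual_fpp_t: float,
    year: int = 0,
    thresholds: Optional[ThresholdConfig] = None,
) -> FCCIRecord:
    """Annual lake-wide FCCI = FP / Gross Annual FPP with its management status."""
    if gross_annual_fpp_t <= 0:
        raise ValueError("gross annual FPP must be > 0 (index undefined)")
    if fp_t < 0:
        raise ValueError("fish population biomass must be >= 0")
    thr = thresholds or ThresholdConfig()
    ratio = fp_t / gross_annual_fpp_t
    return FCCIRecord(
        year=year,
        fp_t=float(fp_t),
        gross_annual_fpp_t=float(gross_annual_fpp_t),
        fcci=float(ratio),
        status=_status(ratio, thr),
    )


def allocate_fp(
    fp_t: float, weight_surface: np.ndarray, water: np.ndarray
) -> np.ndarray:
    """Allocate lake-wide FP [t] over cells proportionally to a density surface.

    ``weight_surface`` is any non-negative field (e.g. an acoustic density
    surface); a uniform surface is the fallback when none is available.
    """
    w = np.where(water, np.asarray(weight_surface, dtype=float), 0.0)
    if np.any(w[water] < 0):
        raise ValueError("allocation weights must be >= 0")
    total = w.sum()
    if total == 0:
        w = water.astype(float)
        total = w.sum()
    out = np.where(water, fp_t * w / total, np.nan)
    return out


def fcci_map(fp_density_t: np.ndarray, annual_net_fpp_t: np.ndarray) -> np.ndarray:
    """Per-cell FCCI from per-cell FP [t] and per-cell annual FPP [t].

    Cells with zero FPP and zero FP map to 0; zero FPP with positive FP is
    an error (the grids are inconsistent). NaN cells propagate.
    """
    fp = np.asarray(fp_density_t, dtype=float)
    fpp = np.asarray(annual_net_fpp_t, dtype=float)
    if fp.shape != fpp.shape:
        raise ValueError(f"misaligned grids: {fp.shape} vs {fpp.shape}")
    both = np.isfinite(fp) & np.isfinite(fpp)
    bad = both & (fpp == 0) & (fp > 0)
    if bad.any():
        raise ValueError("cells with positive FP but zero FPP: index undefined there")
    out = np.full(fp.shape, np.nan)
    nz = both & (fpp > 0)
    out[nz] = fp[nz] / fpp[nz]
    out[both & (fpp == 0) & (fp == 0)] = 0.0
    return out


def classify_zones(
    fcci_grid: np.ndarray, thresholds: Optional[ThresholdConfig] = None
) -> Tuple[np.ndarray, Dict]:
    """Label each cell by management zone and summarise restocking guidance.

    Returns (labels, summary): ``labels`` is an integer grid indexing
    :data:`ZONE_LABELS` (-1 for undefined cells) and ``summary`` holds the
    per-zone cell counts plus the recommended release zone — the largest
    4-connected region of underutilised cells.
    """
    thr = thresholds or ThresholdConfig()
    f = np.asarray(fcci_grid, dtype=float)
    labels = np.full(f.shape, -1, dtype=int)
    defined = np.isfinite(f)
    labels[defined & (f < thr.underutilised)] = 0
    labels[defined & (f >= thr.underutilised) & (f <= thr.high_pressure)] = 1
    labels[defined & (f > thr.high_pressure) & (f <= thr.benchmark)] = 2
    labels[defined & (f > thr.benchmark) & (f <= thr.max_sustainable)] = 3
    labels[defined & (f > thr.max_sustainable)] = 4

    counts = {name: int((labels == i).sum()) for i, name in enumerate(ZONE_LABELS)}
    under = labels == 0
    release_mask = np.zeros(f.shape, dtype=bool)
    if under.any():
        comp, n_comp = ndimage.label(under)
        sizes = ndimage.sum_labels(under, comp, index=np.arange(1, n_comp + 1))
        release_mask = comp == (int(np.argmax(sizes)) + 1)
    summary = {
        "counts": counts,
        "n_defined": int(defined.sum()),
        "release_zone_cells": int(release_mask.sum()),
        "release_zone_mask": release_mask,
    }
    return labels, summary
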