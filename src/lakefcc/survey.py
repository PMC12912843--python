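"""Annual fish population biomass from hydroacoustic and gill-net surveys.

Echo-integration itself (waveform -> volumetric density) happens upstream
in vendor software; densities enter this module as tabulated transect
segment values. The acoustic target strength of a single fish,

    TS [dB] = 19.1 * log10(L [cm]) - 0.9 * log10(f [kHz]) - 62,

is the species-specific calibration used when simulating or validating
density tables. Lake-wide biomass follows the mean-density formula:

    FP [t] = mean density [ind m^-3] * mean weight [g] * lake volume [m^3] * 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "target_strength",
    "mean_weight",
    "pooled_density",
    "fish_population",
    "GillnetSample",
    "FPEstimate",
]


@dataclass
class GillnetSample:
    """Length (cm) / weight (g) records from multi-mesh gill-net catches."""

    records: pd.DataFrame  # columns: length_cm, weight_g
    mesh_range_mm: tuple = (10, 100)

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("gill-net sample needs at least one record")
        if (self.records["length_cm"] <= 0).any() or (self.records["weight_g"] <= 0).any():
            raise ValueError("lengths and weights must be positive")


@dataclass
class FPEstimate:
    year: int
    mean_density: float  # ind m^-3
    mean_weight_g: float
    lake_volume_m3: float
    fp_tonnes: float


def target_strength(length_cm, frequency_khz: float = 210.0):
    """Single-fish acoustic target strength [dB] at body length L and transducer frequency f."""
    L = np.asarray(length_cm, dtype=float)
    if np.any(L <= 0) or frequency_khz <= 0:
        raise ValueError("length and frequency must be positive")
    ts = 19.1 * np.log10(L) - 0.9 * np.log10(frequency_khz) - 62.0
    return ts if ts.ndim else float(ts)


def mean_weight(sample: GillnetSample) -> float:
    """Arithmetic mean fresh weight [g] of the gill-net catch."""
    return float(sample.records["weight_g"].mean())


def pooled_density(
    segment_densities: Sequence[float],
    segment_volumes: Optional[Sequence[float]] = None,
) -> float:
    """Lake-wide mean density [ind m^-3]: volume-weighted mean over transect segments."""
    d = np.asarray(segment_densities, dtype=float)
    if d.size == 0:
        raise ValueError("no transect segments")
    if np.any(d < 0):
        raise ValueError("densities must be >= 0")
    if segment_volumes is None:
        return float(d.mean())
    v = np.asarray(segment_volumes, dtype=float)
    if v.shape != d.shape or np.any(v <= 0):
        raise ValueError("segment volumes must be positive and match densities")
    return float(np.average(d, weights=v))


def fish_population(
    mean_density: float,
    mean_weight_g: float,
    lake_volume_m3: float,
    year: int = 0,
) -> FPEstimate:
    """Lake-wide fish population biomass [t] from mean density, weight and volume."""
    if mean_density < 0 or mean_weight_g < 0 or lake_volume_m3 < 0:
        raise ValueError("density, weight and volume must be >= 0")
    fp = mean_density * mean_weight_g * lake_volume_m3 * 1e-6
    return FPEstimate(
        year=year,
        mean_density=float(mean_density),
        mean_weight_g=float(mean_weight_g),
        lake_volume_m3=float(lake_volume_m3),
        fp_tonnes=float(fp),
    )
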