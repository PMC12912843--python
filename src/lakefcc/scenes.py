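"""In-memory containers for one day's co-registered lake rasters."""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["GridScene", "TruthRecord"]

_DATA_LAYERS = ("chl", "sst", "par", "kd490")
_QUALITY_LAYERS = ("flags", "straylight_pct", "ice", "water")


@dataclass
class GridScene:
    """One date's co-registered rasters over a rectangular 1 km grid.

    Data layers: chlorophyll-a [mg m^-3], surface temperature [degC], daily
    PAR [mol quanta m^-2 day^-1] and Kd490 [m^-1]. Quality layers: integer
    retrieval flags (0 = nominal), straylight risk [%], ice cover (0/1) and
    the water mask. NaN in a data layer means "undefined"; zero is a legal
    chlorophyll value and is never used as a sentinel.
    """

    date: datetime.date
    chl: np.ndarray
    sst: np.ndarray
    par: np.ndarray
    kd490: np.ndarray
    flags: np.ndarray
    straylight_pct: np.ndarray
    ice: np.ndarray
    water: np.ndarray

    def __post_init__(self) -> None:
        shape = np.asarray(self.chl).shape
        for name in _DATA_LAYERS + _QUALITY_LAYERS:
            layer = getattr(self, name)
            if layer is None:
                raise ValueError(f"missing layer: {name}")
            arr = np.asarray(layer)
            if arr.shape != shape:
                raise ValueError(f"layer {name} shape {arr.shape} != {shape}")
            setattr(self, name, arr)
        self.water = self.water.astype(bool)

    @property
    def shape(self):
        return self.chl.shape

    def copy(self) -> "GridScene":
        return replace(
            self,
            **{name: getattr(self, name).copy() for name in _DATA_LAYERS + _QUALITY_LAYERS},
        )


@dataclass
class TruthRecord:
    """Noise-free ground truth accompanying a synthetic scene (water cells only)."""

    true_chl: np.ndarray  # mg m^-3
    true_pp: np.ndarray  # mg C m^-2 day^-1
    true_biomass: Optional[float] = None  # tonnes, when a survey truth is attached
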