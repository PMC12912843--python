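"""Parameter and configuration types shared across the pipeline.

Every tunable constant of the assessment lives here: the trophic
energy-transfer parameters that convert primary production into fish
potential production, the management thresholds applied to the carrying
capacity index, the Monte-Carlo design, and the synthetic-scene generator
settings. Validation raises :class:`ConfigurationError` naming the
offending field so CLI users get actionable messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ConfigurationError",
    "SceneConfig",
    "TrophicParams",
    "ThresholdConfig",
    "MCConfig",
]


class ConfigurationError(ValueError):
    """A configuration field violates its invariant."""


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{fieldname}: {msg}")


@dataclass
class SceneConfig:
    """Settings for the synthetic lake-scene generator.

    The defaults describe a high-altitude, ~4500 km^2, ~20 m deep lake at
    36.9 deg N with a May-October open-water season: chlorophyll is highest
    along the shore and at tributary estuaries, peaks in mid-summer, and
    carries multiplicative lognormal retrieval noise; a fraction of
    pixel-days is lost to cloud/quality flags.
    """

    grid_shape: Tuple[int, int] = (40, 40)
    lake_geometry: Optional[np.ndarray] = None  # boolean water template; default: inscribed ellipse
    estuary_centres: Sequence[Tuple[int, int]] = ()
    season_amplitude: float = 0.5
    chl_base: float = 1.0  # mg m^-3, lake-centre summer-mean chlorophyll
    chl_shore_gain: float = 1.5  # relative shoreline enhancement
    noise_cv: float = 0.25  # lognormal CV of chlorophyll retrieval noise
    cloud_fraction: float = 0.15  # probability a water pixel-day is flagged
    straylight_fraction: float = 0.02  # probability of a 5-10% straylight-risk pixel
    sst_noise_sd: float = 0.3  # deg C, additive Gaussian noise on surface temperature
    latitude_deg: float = 36.9
    lake_depth_m: float = 20.0
    seed: int = 0
    allow_off_season: bool = False

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        _require(rows > 0 and cols > 0, "grid_shape", "must be positive")
        _require(0.0 <= self.cloud_fraction <= 1.0, "cloud_fraction", "must be in [0, 1]")
        _require(0.0 <= self.straylight_fraction < 1.0, "straylight_fraction", "must be in [0, 1)")
        _require(self.chl_base > 0, "chl_base", "must be > 0")
        _require(self.noise_cv >= 0, "noise_cv", "must be >= 0")
        _require(self.sst_noise_sd >= 0, "sst_noise_sd", "must be >= 0")
        _require(abs(self.latitude_deg) < 66.5, "latitude_deg", "must be sub-polar")
        _require(self.lake_depth_m > 0, "lake_depth_m", "must be > 0")
        if self.lake_geometry is not None:
            geom = np.asarray(self.lake_geometry, dtype=bool)
            _require(geom.shape == tuple(self.grid_shape), "lake_geometry",
                     f"shape {geom.shape} != grid_shape {tuple(self.grid_shape)}")
            _require(bool(geom.any()), "lake_geometry", "needs at least one water cell")
            self.lake_geometry = geom
        for rc in self.estuary_centres:
            r, c = rc
            _require(0 <= r < rows and 0 <= c < cols, "estuary_centres",
                     f"centre {rc} outside grid {self.grid_shape}")


@dataclass
class TrophicParams:
    """Energy-transfer constants linking primary production to fish biomass.

    ``a`` is the trophic transfer efficiency per step (0.10 here), ``n`` the
    trophic level of the target fish (2 for an obligate zooplanktivore),
    ``pb`` the production-to-biomass ratio of the plankton food base
    (30, plausible range 30-50), and ``e_kj_per_g`` the energy content of
    fish fresh weight (2.5 kJ/g). ``kj_per_mgc`` houses the bookkeeping
    equivalence 1 kJ = 1 mg C m^-2 used when converting fixed carbon to
    energy; it is a named factor so alternative unit readings are a config
    switch rather than a code change.

    Net FPP [g m^-2] = Net PP [mg C m^-2] * a^n * pb * kj_per_mgc / e_kj_per_g.
    """

    a: float = 0.10
    n: float = 2.0
    pb: float = 30.0
    e_kj_per_g: float = 2.5
    a_lake_m2: float = 4500e6
    kj_per_mgc: float = 1.0
    lake_depth_m: float = 20.0

    def __post_init__(self) -> None:
        _require(0.0 < self.a < 1.0, "a", "must be in (0, 1)")
        _require(self.n >= 1.0, "n", "must be >= 1")
        _require(self.pb > 0, "pb", "must be > 0")
        _require(self.e_kj_per_g > 0, "e_kj_per_g", "must be > 0")
        _require(self.a_lake_m2 > 0, "a_lake_m2", "must be > 0")
        _require(self.kj_per_mgc > 0, "kj_per_mgc", "must be > 0")

    @property
    def net_fpp_factor(self) -> float:
        """Multiplier taking net PP (mg C m^-2) to net FPP (g fresh weight m^-2)."""
        return self.a ** self.n * self.pb * self.kj_per_mgc / self.e_kj_per_g

    @property
    def lake_volume_m3(self) -> float:
        return self.a_lake_m2 * self.lake_depth_m

    def replace(self, **kw: float) -> "TrophicParams":
        d = {f: getattr(self, f) for f in
             ("a", "n", "pb", "e_kj_per_g", "a_lake_m2", "kj_per_mgc", "lake_depth_m")}
        d.update(kw)
        return TrophicParams(**d)


@dataclass(frozen=True)
class ThresholdConfig:
    """Carrying-capacity index thresholds used for management classification.

    An index <= 1 means available production exceeds the fish population's
    energy demand; 0.6 is the empirical benchmark above which fisheries
    have frequently become overexploited; > 0.5 flags high food-demand
    pressure and < 0.3 an underutilised zone. Comparisons are strict, so a
    value exactly on a boundary falls to the lower-severity class.
    """

    underutilised: float = 0.3
    high_pressure: float = 0.5
    benchmark: float = 0.6
    max_sustainable: float = 1.0

    def __post_init__(self) -> None:
        seq = (self.underutilised, self.high_pressure, self.benchmark, self.max_sustainable)
        _require(all(x < y for x, y in zip(seq, seq[1:])), "thresholds",
                 "must be strictly increasing")


@dataclass
class MCConfig:
    """Monte-Carlo sensitivity design: uniform +/-`variation` on each varied parameter."""

    iterations: int = 1000
    variation: float = 0.20
    varied_params: Tuple[str, ...] = ("a", "pb", "n", "e_kj_per_g")
    seed: int = 0
    batch_sizes: Tuple[int, ...] = (500, 800, 1000)

    def __post_init__(self) -> None:
        _require(self.iterations >= 1, "iterations", "must be >= 1")
        _require(0.0 <= self.variation < 1.0, "variation", "must be in [0, 1)")
        allowed = {"a", "pb", "n", "e_kj_per_g"}
        bad = set(self.varied_params) - allowed
        _require(not bad, "varied_params", f"unknown parameters {sorted(bad)}")
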