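"""Fish potential production (FPP) via trophic energy transfer.

Monthly net primary production per grid cell is converted to the fish
fresh-weight biomass it can sustain:

    net FPP [g m^-2 month^-1] = net PP [mg C m^-2 month^-1] * a^n * (P/B) / E

(with the kJ <-> mg C equivalence folded into the factor; see
:class:`lakefcc.config.TrophicParams`). Lake-wide aggregation follows the
three-tier scheme: Gross Monthly FPP [t] = mean(net FPP) * A_lake * 1e-6,
and Gross Annual FPP [t] is the May-October sum of the monthlies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np

from .config import TrophicParams

__all__ = ["net_fpp", "gross_monthly_fpp", "gross_annual_fpp", "FPPField", "SEASON_MONTHS"]

SEASON_MONTHS: Sequence[int] = (5, 6, 7, 8, 9, 10)  # May-October open-water season


@dataclass
class FPPField:
    year: int
    month: int
    net_fpp: np.ndarray  # g m^-2 month^-1 per cell (NaN = undefined)
    gross_monthly_t: float  # tonnes, lake-wide


def net_fpp(net_pp, params: TrophicParams):
    """Per-cell net FPP [g m^-2] from net PP [mg C m^-2]. NaN propagates."""
    pp = np.asarray(net_pp, dtype=float)
    if np.any(pp[np.isfinite(pp)] < 0):
        raise ValueError("net_pp must be >= 0")
    out = pp * params.net_fpp_factor
    return out if out.ndim else float(out)


def gross_monthly_fpp(net_fpp_field, params: TrophicParams) -> float:
    """Lake-wide monthly FPP [t]: mean of defined cells * A_lake * 1e-6.

    The mean over *defined* cells is extrapolated over the full lake area
    (the lake-wide aggregation formula); the fraction of undefined cells is
    a coverage diagnostic reported by the workflow, not subtracted here.
    """
    f = np.asarray(net_fpp_field, dtype=float)
    defined = np.isfinite(f)
    if not defined.any():
        raise ValueError("no defined net FPP cells to aggregate")
    return float(np.mean(f[defined]) * params.a_lake_m2 * 1e-6)


def gross_annual_fpp(
    monthlies: Mapping[int, float] | Iterable[FPPField],
    months: Sequence[int] = SEASON_MONTHS,
    strict: bool = True,
) -> float:
    """Gross Annual FPP [t] as the sum of gross monthly FPP over the season.

    ``monthlies`` maps month number -> tonnes (or is an iterable of
    :class:`FPPField`). In strict mode a missing or duplicated season month
    raises; with ``strict=False`` partial years sum what is present.
    """
    if not isinstance(monthlies, Mapping):
        table: Dict[int, float] = {}
        for fld in monthlies:
            if fld.month in table:
                raise ValueError(f"duplicate month {fld.month}")
            table[fld.month] = fld.gross_monthly_t
        monthlies = table
    missing = [m for m in months if m not in monthlies]
    if missing and strict:
        raise ValueError(f"missing season months: {missing}")
    return float(sum(monthlies[m] for m in months if m in monthlies))
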