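"""Validation statistics for modelled-vs-surveyed comparisons.

ARE  = (1/n) * sum((Xm - Xs)/Xs) * 100          [%]  signed mean relative error
CC   = Pearson correlation of Xm and Xs               [-1, 1]
RMSE = sqrt((1/n) * sum((Xm - Xs)^2))                 [variable units]
EA   = (1 - RMSE / mean(Xs)) * 100              [%]  estimation accuracy

EA can be negative when the RMSE exceeds the surveyed mean; it is reported
as-is (the formula permits it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping

import numpy as np
from scipy import stats

__all__ = ["ValidationReport", "compare", "validate_pipeline"]


@dataclass
class ValidationReport:
    variable_name: str
    n: int
    are_pct: float
    cc: float
    rmse: float
    ea_pct: float


def compare(modelled, surveyed, variable_name: str = "") -> ValidationReport:
    """Compute ARE/CC/RMSE/EA for a modelled series against a surveyed series."""
    xm = np.asarray(modelled, dtype=float)
    xs = np.asarray(surveyed, dtype=float)
    if xm.shape != xs.shape:
        raise ValueError(f"length mismatch: {xm.shape} vs {xs.shape}")
    n = xm.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(xs == 0):
        raise ValueError("surveyed values must be non-zero for ARE")
    if np.std(xm) == 0 or np.std(xs) == 0:
        raise ValueError("zero variance: correlation undefined")
    are = float(np.mean((xm - xs) / xs) * 100.0)
    cc = float(stats.pearsonr(xm, xs).statistic)
    rmse = float(np.sqrt(np.mean((xm - xs) ** 2)))
    ea = float((1.0 - rmse / np.mean(xs)) * 100.0)
    return ValidationReport(variable_name=variable_name, n=n, are_pct=are,
                            cc=cc, rmse=rmse, ea_pct=ea)


def validate_pipeline(matchups_by_variable: Mapping[str, Iterable]) -> List[ValidationReport]:
    """One report per variable from its valid matchup pairs.

    ``matchups_by_variable`` maps a variable name (e.g. "sst", "chl", "pp")
    to an iterable of :class:`lakefcc.qc.MatchupPair`; only pairs flagged
    valid contribute. Raises if a variable has fewer than two valid pairs.
    """
    reports: List[ValidationReport] = []
    for var, pairs in matchups_by_variable.items():
        valid = [p for p in pairs if p.valid]
        if len(valid) < 2:
            raise ValueError(f"{var}: fewer than 2 valid matchups")
        reports.append(
            compare(
                [p.satellite_value for p in valid],
                [p.field_value for p in valid],
                variable_name=var,
            )
        )
    return reports
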