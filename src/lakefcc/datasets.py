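"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_assessment"]


def load_reference_assessment() -> pd.DataFrame:
    """Published annual assessment series for Qinghai Lake, 2002-2024.

    Columns: ``year``, ``fp_t`` (August hydroacoustic fish population
    biomass, tonnes), ``fpp_t`` (Gross Annual FPP, tonnes) and ``fcci``
    (the lake-wide index as printed, 4 decimals). Used as the bypass-mode
    input for assessment and sensitivity runs that do not start from
    rasters.
    """
    with resources.files("lakefcc.data").joinpath("qinghai_annual_assessment.csv").open() as fh:
        return pd.read_csv(fh)
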