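"""Packaged reference tables for the 11 Australasian cities.

Two small CSVs ship with the package so the composition, ranking and
ordination stages run without any external download:

* ``table2_composition.csv`` — site x taxon percentage composition of the
  dominant airborne pollen taxa for Darwin through Dunedin, as published.
  Trace cells below the reporting precision are stored verbatim as the
  ``<0.1`` token and read back as 0.05 (midpoint convention).
* ``table3_environment.csv`` — per-city land-cover fractions within a
  100 km radius (% water / agricultural / grass / forest) and climate
  normals (MaxT, MinT in °C; MAP in mm).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .composition import load_composition

__all__ = ["load_city_composition", "load_city_environment"]


def _data_path(name: str):
    return files("aeropollen").joinpath("data", name)


def load_city_composition() -> pd.DataFrame:
    """Site x taxon percentage matrix for the 11 cities (NaN = absent)."""
    with _data_path("table2_composition.csv").open("r") as fh:
        return load_composition(fh)


def load_city_environment() -> pd.DataFrame:
    """Land-cover and climate covariates per city, indexed by site."""
    with _data_path("table3_environment.csv").open("r") as fh:
        return pd.read_csv(fh, index_col=0)
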