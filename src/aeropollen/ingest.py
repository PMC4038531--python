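"""Reading raw daily pollen-count tables and station metadata.

The on-disk dialect is deliberately plain: a delimited text file with one
row per (site, taxon, day) observation and ISO-8601 dates.  Days with no
record are gaps — they are never silently treated as zero, and downstream
annual sums simply exclude them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError, DuplicateRecordError, SchemaError, ValidationError
from .samplers import SamplerSpec

__all__ = [
    "REQUIRED_COLUMNS",
    "load_daily_counts",
    "load_station_specs",
    "load_zone_map",
    "aggregate_taxa",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("site_id", "taxon", "date", "raw_count")


def load_daily_counts(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Load and validate a daily count table.

    Parameters
    ----------
    path:
        Delimited text file with columns ``site_id, taxon, date, raw_count``
        and optionally ``counted_fraction`` (defaults to 1.0 — whole deposit
        counted — with a logged warning).
    schema:
        Optional mapping from canonical column name to the column name used
        in the file, e.g. ``{"site_id": "station"}``.

    Returns
    -------
    DataFrame sorted by (site_id, taxon, date) with ``date`` as
    ``datetime64`` and ``counted_fraction`` filled in.

    Raises
    ------
    SchemaError
        A mapped column is absent.
    ValidationError
        Negative counts, fractions outside (0, 1], or unparsable dates;
        the message names the offending row numbers (1-based data rows).
    DuplicateRecordError
        Repeated (site_id, taxon, date) keys.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"counts file not found: {path}")
    raw = pd.read_csv(path, sep=sep, dtype={"taxon": str})
    rename = {v: k for k, v in (schema or {}).items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df = raw.copy()
    if "counted_fraction" not in df.columns:
        logger.warning("%s: no counted_fraction column; assuming 1.0 (whole deposit)", path)
        df["counted_fraction"] = 1.0
    df["counted_fraction"] = df["counted_fraction"].fillna(1.0)

    def _bad_rows(mask: pd.Series) -> str:
        rows = (mask[mask].index + 2).tolist()  # +2: header + 1-based
        return ", ".join(map(str, rows[:10])) + ("…" if len(rows) > 10 else "")

    counts = pd.to_numeric(df["raw_count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts % 1 != 0)
    if bad.any():
        raise ValidationError(
            f"{path}: raw_count must be a non-negative integer; bad row(s) {_bad_rows(bad)}"
        )
    df["raw_count"] = counts.astype(int)
    frac = pd.to_numeric(df["counted_fraction"], errors="coerce")
    bad = frac.isna() | (frac <= 0) | (frac > 1)
    if bad.any():
        raise ValidationError(
            f"{path}: counted_fraction must be in (0, 1]; bad row(s) {_bad_rows(bad)}"
        )
    df["counted_fraction"] = frac
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = dates.isna()
    if bad.any():
        raise ValidationError(
            f"{path}: unparsable ISO-8601 date(s) at row(s) {_bad_rows(bad)}"
        )
    df["date"] = dates
    dup = df.duplicated(subset=["site_id", "taxon", "date"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["site_id", "taxon", "date"]].drop_duplicates()
        first = keys.iloc[0]
        raise DuplicateRecordError(
            f"{path}: {len(keys)} duplicated (site, taxon, date) key(s), "
            f"e.g. ({first.site_id}, {first.taxon}, {first.date.date()})"
        )
    df = df.sort_values(["site_id", "taxon", "date"]).reset_index(drop=True)
    logger.info("%s: loaded %d count records", path, len(df))
    return df[["site_id", "taxon", "date", "raw_count", "counted_fraction"]]


def load_station_specs(path: str | Path) -> dict[str, SamplerSpec]:
    """Read station metadata (YAML or JSON) keyed by site_id.

    Each entry mirrors the sampler fields, e.g.::

        Hobart: {kind: hirst, flow_rate_l_min: 10, monitor_height_m: 12}
        Dunedin: {kind: rotorod, rod_width_mm: 1.59, rod_length_mm: 32,
                  rotation_rate_rpm: 2400, duty_minutes_per_hour: 6}
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"station metadata file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping of site_id -> spec")
    return {site: SamplerSpec.from_dict(spec) for site, spec in data.items()}


def load_zone_map(path: str | Path) -> dict[str, str]:
    """Read the site -> climate-zone mapping (YAML/JSON).

    Zones are ``tropical`` (pollen year = calendar year) or
    ``temperate_s_hemisphere`` (pollen year July 1 – June 30).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"zone map file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping of site_id -> zone")
    return {str(k): str(v) for k, v in data.items()}


def aggregate_taxa(
    series: pd.DataFrame, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Merge taxa into broader groups (e.g. genera into their family).

    ``mapping`` is taxon -> group.  Taxa not in the mapping pass through
    unchanged; mapping keys never observed in the data are logged.  The
    total concentration per site x date is conserved exactly (summation
    only reorders terms).

    Accepts either the tidy concentration table (``grains_per_m3``) or a
    raw count table (``raw_count``); the value column is summed within
    groups.
    """
    if mapping and all(isinstance(v, (list, tuple)) for v in mapping.values()):
        mapping = validate_group_mapping(mapping)  # group -> [taxa] form
    value_col = "grains_per_m3" if "grains_per_m3" in series.columns else "raw_count"
    unobserved = sorted(set(mapping) - set(series["taxon"]))
    if unobserved:
        logger.warning("aggregate_taxa: unobserved mapping key(s): %s", unobserved)
    out = series.copy()
    out["taxon"] = out["taxon"].map(lambda t: mapping.get(t, t))
    grouped = (
        out.groupby(["site_id", "taxon", "date"], as_index=False)[value_col]
        .sum()
        .sort_values(["site_id", "taxon", "date"])
        .reset_index(drop=True)
    )
    return grouped


def validate_group_mapping(groups: Mapping[str, list[str]]) -> dict[str, str]:
    """Invert a group -> [taxa] mapping, rejecting taxa claimed twice."""
    inverted: dict[str, str] = {}
    for group, members in groups.items():
        for taxon in members:
            if taxon in inverted and inverted[taxon] != group:
                raise ConfigurationError(
                    f"taxon {taxon!r} mapped to both {inverted[taxon]!r} and {group!r}"
                )
            inverted[taxon] = group
    return inverted
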