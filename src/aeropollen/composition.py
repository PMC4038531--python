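"""Percentage composition and cross-city taxon rankings.

The unit of comparison between cities is the *pollen sum* percentage: the
total abundance of one taxon over the whole record, divided by the total
abundance of all taxa, times 100.  This transformation removes between-site
differences in trap efficiency, record length and absolute pollen flux, so
cities sampled with different instruments for different durations can be
compared on composition alone.

A composition matrix is a sites x taxa DataFrame of percentages in which a
missing value (NaN) means the taxon was never recorded at that site —
deliberately distinct from an observed 0.  Cross-site averages are taken
over occurring sites only, which is how multi-city composition tables are
conventionally summarised.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateSiteError

__all__ = [
    "percent_composition",
    "cross_site_average",
    "rank_taxa",
    "subtotal",
    "load_composition",
    "save_composition",
]

logger = logging.getLogger(__name__)


def percent_composition(series: pd.DataFrame) -> pd.DataFrame:
    """Site x taxon percentage matrix from a tidy concentration table.

    Each cell is 100 x (summed concentration of the taxon at the site) /
    (summed concentration of all taxa at the site).  Rows sum to 100.
    Site x taxon combinations with no records at all stay NaN (absent).
    """
    value_col = "grains_per_m3" if "grains_per_m3" in series.columns else "raw_count"
    wide = series.pivot_table(
        index="site_id", columns="taxon", values=value_col, aggfunc="sum"
    )
    totals = wide.sum(axis=1, skipna=True)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateSiteError(
            f"site(s) with zero total pollen: {sorted(zero.index)}"
        )
    pct = wide.div(totals, axis=0) * 100.0
    pct.index.name = "site_id"
    pct.columns.name = "taxon"
    return pct


def cross_site_average(matrix: pd.DataFrame, taxon: str) -> float:
    """Mean percentage of a taxon over the sites where it occurs.

    Absent cells (NaN) are excluded from the mean, so a taxon recorded in
    six of eleven cities is averaged over six.  Full precision; round to
    one decimal for reporting.
    """
    if taxon not in matrix.columns:
        raise LookupError(f"taxon {taxon!r} not in matrix")
    col = matrix[taxon].dropna()
    if col.empty:
        raise LookupError(f"taxon {taxon!r} absent from every site")
    return float(col.mean())


def rank_taxa(matrix: pd.DataFrame, min_sites: int = 2) -> pd.DataFrame:
    """Rank taxa by cross-site average percentage.

    Taxa occurring at fewer than ``min_sites`` sites are flagged
    ``excluded`` and reported with their average but no rank (a taxon seen
    in a single city says nothing about regional prevalence).  Ranks run
    1..K over the non-excluded taxa, descending by average; ties break
    alphabetically.

    Returns a DataFrame indexed by taxon with columns ``mean_pct``,
    ``n_sites``, ``excluded``, ``rank`` (nullable Int64), ordered ranked
    taxa first.
    """
    if matrix.size == 0 or matrix.notna().sum().sum() == 0:
        logger.warning("rank_taxa: empty composition matrix")
        return pd.DataFrame(
            columns=["mean_pct", "n_sites", "excluded", "rank"]
        ).rename_axis("taxon")
    n_sites = matrix.notna().sum(axis=0)
    mean_pct = matrix.mean(axis=0, skipna=True)
    out = pd.DataFrame({"mean_pct": mean_pct, "n_sites": n_sites})
    out = out[out["n_sites"] > 0]
    out["excluded"] = out["n_sites"] < min_sites
    out = (
        out.rename_axis("taxon")
        .reset_index()
        .sort_values(["excluded", "mean_pct", "taxon"], ascending=[True, False, True])
        .set_index("taxon")
    )
    ranks = np.arange(1, (~out["excluded"]).sum() + 1)
    out["rank"] = pd.array(
        list(ranks) + [pd.NA] * int(out["excluded"].sum()), dtype="Int64"
    )
    return out


def subtotal(matrix: pd.DataFrame, site: str, taxa: list[str]) -> float:
    """Sum of present percentage values at ``site`` over a taxa subset.

    Absent cells contribute nothing; an empty subset sums to 0.  The
    residual share of unlisted taxa is ``100 - subtotal``.
    """
    if site not in matrix.index:
        raise LookupError(f"site {site!r} not in matrix")
    cols = [t for t in taxa if t in matrix.columns]
    if not cols:
        return 0.0
    return float(matrix.loc[site, cols].sum(skipna=True))


def load_composition(path: str | Path, below_detection: float = 0.05) -> pd.DataFrame:
    """Read a composition CSV (sites as rows, taxa as columns).

    Blank cells are absent (NaN).  Trace cells printed as ``<x`` (below the
    reporting precision) are read as ``x / 2`` — e.g. ``<0.1`` becomes
    0.05 — which is the midpoint convention for censored trace values.
    """

    def _cell(v):
        if pd.isna(v):
            return np.nan
        s = str(v).strip()
        if not s:
            return np.nan
        if s.startswith("<"):
            return float(s[1:]) / 2.0
        return float(s)

    raw = pd.read_csv(path, index_col=0, dtype=str)
    out = raw.apply(lambda col: col.map(_cell))
    out.index.name = "site_id"
    out.columns.name = "taxon"
    return out


def save_composition(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a composition matrix CSV; NaN cells are left blank."""
    matrix.to_csv(path, float_format="%.10g")
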