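"""Pollen seasons (cumulative 5%/95% rule) and monthly calendars.

The season of a taxon in one pollen year runs from the first day on which
the cumulative daily concentration reaches 5% of the annual total to the
first day on which it reaches 95% — the central 90% of the year's pollen.
"Reaches" is the closed convention: cumulative sum >= threshold.

Annual totals are accumulated within a *pollen year* rather than a
calendar year so that austral spring/summer seasons are not split across
the year boundary: Southern-Hemisphere temperate and subtropical sites use
July 1 – June 30 (labelled "2009/2010"), tropical sites the calendar year.

Days with no record are gaps: they contribute nothing to the cumulative
sum and a season may legally span them.  Pollen years with fewer observed
days than ``min_coverage_days`` are flagged low-coverage and are excluded
from calendars by default, since a trap deployed for a few weeks cannot
anchor annual percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import pandas as pd

from .errors import ValidationError

__all__ = [
    "TROPICAL",
    "TEMPERATE_S",
    "PollenYearConvention",
    "assign_pollen_year",
    "detect_season",
    "detect_seasons",
    "SeasonWindow",
    "build_calendar",
    "calendar_frame",
    "windows_frame",
]

logger = logging.getLogger(__name__)

#: Minimum observed days for a pollen year to count as adequately sampled.
DEFAULT_MIN_COVERAGE_DAYS = 60


@dataclass(frozen=True)
class PollenYearConvention:
    """How calendar dates map to pollen-year labels.

    ``tropical`` years coincide with calendar years; ``temperate_s_hemisphere``
    years start on July 1 and are labelled "Y/Y+1".
    """

    zone: str = "temperate_s_hemisphere"

    def __post_init__(self) -> None:
        if self.zone not in ("tropical", "temperate_s_hemisphere"):
            raise ValueError(f"unknown zone {self.zone!r}")


TROPICAL = PollenYearConvention("tropical")
TEMPERATE_S = PollenYearConvention("temperate_s_hemisphere")


def assign_pollen_year(
    dates: pd.Series | date, convention: PollenYearConvention
) -> pd.Series | str:
    """Label each date with its pollen year.

    Temperate Southern-Hemisphere: Jul 1–Dec 31 belong to "Y/Y+1" of that
    July; Jan 1–Jun 30 to the year that started the preceding July.
    Tropical: the calendar year.
    """
    scalar = not isinstance(dates, pd.Series)
    s = pd.Series([pd.Timestamp(dates)]) if scalar else pd.to_datetime(dates)
    if convention.zone == "tropical":
        labels = s.dt.year.astype(str)
    else:
        start = s.dt.year.where(s.dt.month >= 7, s.dt.year - 1)
        labels = start.astype(str) + "/" + (start + 1).astype(str)
    return labels.iloc[0] if scalar else labels


@dataclass(frozen=True)
class SeasonWindow:
    """Detected pollen season for one site x taxon x pollen year."""

    site_id: str
    taxon: str
    pollen_year: str
    start: pd.Timestamp
    end: pd.Timestamp
    annual_total: float
    n_days_observed: int
    low_coverage: bool = False


def detect_season(
    series: pd.DataFrame,
    convention: PollenYearConvention = TEMPERATE_S,
    site_id: str = "",
    taxon: str = "",
    min_coverage_days: int = DEFAULT_MIN_COVERAGE_DAYS,
) -> list[SeasonWindow]:
    """Detect the 90% central pollen season in each pollen year.

    Parameters
    ----------
    series:
        One site x taxon time series: columns ``date`` and
        ``grains_per_m3`` (or ``concentration``), one row per observed day.
    convention:
        Pollen-year convention for the site.

    Returns
    -------
    One :class:`SeasonWindow` per pollen year with a positive annual
    total; all-zero or empty years yield no window (logged, not an error).
    """
    value_col = "grains_per_m3" if "grains_per_m3" in series.columns else "concentration"
    df = series[["date", value_col]].copy()
    df["date"] = pd.to_datetime(df["date"])
    if (df[value_col] < 0).any():
        raise ValidationError("negative concentration in series")
    df = df.sort_values("date")
    if df["date"].duplicated().any():
        raise ValidationError("duplicate dates in series")
    df["pollen_year"] = assign_pollen_year(df["date"], convention)
    windows: list[SeasonWindow] = []
    for year, grp in df.groupby("pollen_year", sort=True):
        total = grp[value_col].sum()
        if total <= 0:
            logger.info("no pollen in %s %s %s: no season", site_id, taxon, year)
            continue
        cum = grp[value_col].cumsum()
        start = grp.loc[cum >= 0.05 * total, "date"].iloc[0]
        end = grp.loc[cum >= 0.95 * total, "date"].iloc[0]
        windows.append(
            SeasonWindow(
                site_id=site_id,
                taxon=taxon,
                pollen_year=str(year),
                start=start,
                end=end,
                annual_total=float(total),
                n_days_observed=len(grp),
                low_coverage=len(grp) < min_coverage_days,
            )
        )
    return windows


def detect_seasons(
    concentrations: pd.DataFrame,
    zone_map: dict[str, str] | None = None,
    min_coverage_days: int = DEFAULT_MIN_COVERAGE_DAYS,
) -> list[SeasonWindow]:
    """Run season detection for every site x taxon in a tidy table."""
    zone_map = zone_map or {}
    windows: list[SeasonWindow] = []
    for (site, taxon), grp in concentrations.groupby(["site_id", "taxon"]):
        conv = PollenYearConvention(zone_map.get(site, "temperate_s_hemisphere"))
        windows.extend(
            detect_season(
                grp, conv, site_id=site, taxon=taxon, min_coverage_days=min_coverage_days
            )
        )
    return windows


def build_calendar(
    windows: list[SeasonWindow],
    min_days_per_month: int = 1,
    include_low_coverage: bool = False,
) -> dict[tuple[str, str], set[int]]:
    """Months (1-12) touched by any season window, per (taxon, site).

    A month is included when at least ``min_days_per_month`` days of a
    window fall in it; windows from different pollen years are unioned.
    """
    cells: dict[tuple[str, str], set[int]] = {}
    for w in windows:
        if w.low_coverage and not include_low_coverage:
            continue
        days = pd.date_range(w.start, w.end, freq="D")
        counts = pd.Series(1, index=days).groupby(days.month).sum()
        months = set(counts[counts >= min_days_per_month].index)
        cells.setdefault((w.taxon, w.site_id), set()).update(months)
    return cells


def calendar_frame(cells: dict[tuple[str, str], set[int]]) -> pd.DataFrame:
    """Tabular calendar: one row per (taxon, site), 12 binary month columns."""
    rows = []
    for (taxon, site), months in sorted(cells.items()):
        rows.append(
            {"taxon": taxon, "site_id": site}
            | {f"m{m:02d}": int(m in months) for m in range(1, 13)}
        )
    cols = ["taxon", "site_id"] + [f"m{m:02d}" for m in range(1, 13)]
    return pd.DataFrame(rows, columns=cols)


def windows_frame(windows: list[SeasonWindow]) -> pd.DataFrame:
    """Season windows as a tidy DataFrame for CSV export."""
    return pd.DataFrame(
        [
            {
                "site_id": w.site_id,
                "taxon": w.taxon,
                "pollen_year": w.pollen_year,
                "start": w.start.date(),
                "end": w.end.date(),
                "annual_total": w.annual_total,
                "n_days_observed": w.n_days_observed,
                "low_coverage": w.low_coverage,
            }
            for w in windows
        ]
    )
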