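"""Physical sampler models and count-to-concentration conversion.

Two volumetric sampler families are supported:

* **Hirst-type** suction traps (Burkard and clones) draw air at a constant
  flow rate, nominally 10 L/min, onto an adhesive tape read in 24-h
  segments.  The air volume sampled per day is simply ``flow_rate x 1440
  min``.

* **Rotorod** impaction samplers collect particles on the leading edges of
  greased rods spun by a motor, usually on a duty cycle (e.g. 6 min every
  hour).  The sampled volume is modelled as the volume swept by the rod
  faces: ``n_rods x rod_width x rod_length x (2 pi x rotation_radius) x
  rotation_rate x duty_minutes x 24``.

Concentrations are reported as pollen grains per cubic metre of air,
averaged over a day:

    grains/m3 = (raw_count / counted_fraction) / daily_sampled_volume

``counted_fraction`` is the fraction of the slide deposit actually examined
(e.g. 3 of 12 transects -> 0.25).  Collection efficiency is taken as 1.0:
no particle-size correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SamplerKind",
    "SamplerSpec",
    "daily_sampled_volume",
    "to_concentration",
    "convert_counts",
]

#: Default rotation radius (mm) of the rod tips about the motor axis.  With
#: the standard two 1.59 x 32 mm rods at 2400 rev/min this radius gives a
#: sampling rate of ~42.8 L/min while spinning, the nominal behaviour of
#: intermittent-cycling Rotorod samplers (~6.17 m3/day at 6 min/hour duty).
DEFAULT_ROTATION_RADIUS_MM = 27.9


class SamplerKind(str, Enum):
    HIRST = "hirst"
    ROTOROD = "rotorod"


@dataclass(frozen=True)
class SamplerSpec:
    """Physical description of one monitoring station's trap.

    Parameters
    ----------
    kind:
        ``"hirst"`` or ``"rotorod"``.
    flow_rate_l_min:
        Hirst pump flow rate in litres per minute (nominally 10).
    rod_width_mm, rod_length_mm, n_rods, rotation_rate_rpm,
    duty_minutes_per_hour, rotation_radius_mm:
        Rotorod geometry and duty cycle.
    monitor_height_m:
        Height of the trap above ground; metadata only, not used in the
        volume calculation.
    """

    kind: SamplerKind = SamplerKind.HIRST
    flow_rate_l_min: float | None = None
    rod_width_mm: float | None = None
    rod_length_mm: float | None = None
    n_rods: int = 2
    rotation_rate_rpm: float | None = None
    duty_minutes_per_hour: float | None = None
    rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM
    monitor_height_m: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", SamplerKind(self.kind))
        if self.kind is SamplerKind.HIRST:
            if self.flow_rate_l_min is None or self.flow_rate_l_min <= 0:
                raise ConfigurationError(
                    f"hirst sampler needs flow_rate_l_min > 0, got {self.flow_rate_l_min!r}"
                )
        else:
            for name in (
                "rod_width_mm",
                "rod_length_mm",
                "n_rods",
                "rotation_rate_rpm",
                "rotation_radius_mm",
            ):
                value = getattr(self, name)
                if value is None or value <= 0:
                    raise ConfigurationError(
                        f"rotorod sampler needs {name} > 0, got {value!r}"
                    )
            duty = self.duty_minutes_per_hour
            if duty is None or not (0 < duty <= 60):
                raise ConfigurationError(
                    f"duty_minutes_per_hour must be in (0, 60], got {duty!r}"
                )

    @classmethod
    def from_dict(cls, mapping: Mapping[str, object]) -> "SamplerSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown sampler fields: {sorted(unknown)}")
        return cls(**dict(mapping))  # type: ignore[arg-type]


def daily_sampled_volume(spec: SamplerSpec) -> float:
    """Volume of air (m3) the trap samples in one 24-hour day.

    Hirst: flow_rate [L/min] x 1440 min / 1000.
    Rotorod: swept-volume model; rods sweep a cylindrical shell of
    circumference ``2 pi x rotation_radius`` for ``duty_minutes_per_hour x
    24`` minutes per day.
    """
    if spec.kind is SamplerKind.HIRST:
        return spec.flow_rate_l_min * 1440.0 / 1000.0
    swept_mm3_per_min = (
        spec.n_rods
        * spec.rod_width_mm
        * spec.rod_length_mm
        * 2.0
        * math.pi
        * spec.rotation_radius_mm
        * spec.rotation_rate_rpm
    )
    minutes = spec.duty_minutes_per_hour * 24.0
    return swept_mm3_per_min * minutes / 1e9


def to_concentration(
    raw_count: float, counted_fraction: float, spec: SamplerSpec
) -> float:
    """Convert a raw slide/rod count to grains per m3 of air.

    Scales the count up by the fraction of the deposit examined, then
    divides by the daily sampled volume.  Linear in ``raw_count`` and
    inverse-linear in ``counted_fraction``.
    """
    if raw_count < 0:
        raise ConfigurationError(f"raw_count must be >= 0, got {raw_count}")
    if not (0 < counted_fraction <= 1):
        raise ConfigurationError(
            f"counted_fraction must be in (0, 1], got {counted_fraction}"
        )
    return (raw_count / counted_fraction) / daily_sampled_volume(spec)


def convert_counts(
    counts: pd.DataFrame, stations: Mapping[str, SamplerSpec]
) -> pd.DataFrame:
    """Vectorised conversion of a validated count table to concentrations.

    Parameters
    ----------
    counts:
        Tidy table with columns ``site_id, taxon, date, raw_count,
        counted_fraction`` (as returned by
        :func:`aeropollen.ingest.load_daily_counts`).
    stations:
        ``site_id -> SamplerSpec``; every site in ``counts`` must be keyed.

    Returns
    -------
    Tidy table ``site_id, taxon, date, grains_per_m3, sampler_kind``.
    """
    missing = sorted(set(counts["site_id"]) - set(stations))
    if missing:
        raise ConfigurationError(f"no sampler spec for site(s): {missing}")
    volumes = counts["site_id"].map(
        {site: daily_sampled_volume(spec) for site, spec in stations.items()}
    )
    out = counts[["site_id", "taxon", "date"]].copy()
    out["grains_per_m3"] = (
        counts["raw_count"] / counts["counted_fraction"]
    ) / volumes
    out["sampler_kind"] = counts["site_id"].map(
        {site: spec.kind.value for site, spec in stations.items()}
    )
    return out
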