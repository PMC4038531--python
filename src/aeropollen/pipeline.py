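"""End-to-end pipeline: convert -> compose/rank -> seasons -> ordination.

Configuration comes from a YAML file (see :class:`PipelineConfig`); every
stage writes tidy CSVs into the output directory plus a provenance
manifest recording inputs, seeds and the package version.  Given the same
config and seeds, all CSV outputs are byte-identical on re-run (the
manifest timestamp is the only volatile field).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .composition import percent_composition, rank_taxa, save_composition
from .errors import ConfigurationError
from .ingest import load_daily_counts, load_station_specs, load_zone_map
from .ordination import dissimilarity_matrix, fit_env_vectors, nmds, select_top_taxa
from .samplers import convert_counts
from .seasons import build_calendar, calendar_frame, detect_seasons, windows_frame

import pandas as pd

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and analysis options for a full run.

    Stages are skipped gracefully when their inputs are not configured:
    with only a composition matrix (no raw counts) the ranking and
    ordination stages still run, mirroring an analysis done from a
    published percentage table.
    """

    out_dir: str = "aeropollen_out"
    counts: str | None = None  # raw daily counts CSV
    stations: str | None = None  # sampler metadata YAML/JSON
    zone_map: str | None = None  # site -> pollen-year zone YAML/JSON
    composition: str | None = None  # pre-computed percentage matrix CSV
    environment: str | None = None  # site covariates CSV
    top_k: int = 8
    min_sites: int = 2
    transform: str = "sqrt"
    metric: str = "braycurtis"
    n_restarts: int = 50
    n_permutations: int = 999
    seed: int = 0
    min_coverage_days: int = 60

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all configured stages; return paths of written artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        concentrations = None
        if config.counts:
            stage = "convert"
            if not config.stations:
                raise ConfigurationError("counts given but no stations metadata")
            counts = load_daily_counts(config.counts)
            stations = load_station_specs(config.stations)
            concentrations = convert_counts(counts, stations)
            path = out_dir / "concentrations.csv"
            concentrations.assign(date=concentrations["date"].dt.date).to_csv(
                path, index=False, float_format="%.10g"
            )
            written["concentrations"] = path

        stage = "rank"
        if concentrations is not None:
            matrix = percent_composition(concentrations)
        elif config.composition:
            from .composition import load_composition

            matrix = load_composition(config.composition)
        else:
            matrix = None
        if matrix is not None:
            path = out_dir / "composition.csv"
            save_composition(matrix, path)
            written["composition"] = path
            ranking = rank_taxa(matrix, min_sites=config.min_sites)
            path = out_dir / "ranking.csv"
            ranking.to_csv(path, float_format="%.10g")
            written["ranking"] = path

        stage = "season"
        if concentrations is not None:
            zones = load_zone_map(config.zone_map) if config.zone_map else {}
            windows = detect_seasons(
                concentrations, zones, min_coverage_days=config.min_coverage_days
            )
            path = out_dir / "season_windows.csv"
            windows_frame(windows).to_csv(path, index=False, float_format="%.10g")
            written["season_windows"] = path
            path = out_dir / "calendar.csv"
            calendar_frame(build_calendar(windows)).to_csv(path, index=False)
            written["calendar"] = path

        stage = "ordinate"
        if matrix is not None and len(matrix) >= 3:
            top = select_top_taxa(matrix, k=config.top_k)
            dist = dissimilarity_matrix(
                top, metric=config.metric, transform=config.transform
            )
            result = nmds(
                dist, n_restarts=config.n_restarts, seed=config.seed
            )
            path = out_dir / "ordination.csv"
            result.coords.to_csv(path, float_format="%.10g")
            written["ordination"] = path
            stress_path = out_dir / "stress.json"
            stress_path.write_text(
                json.dumps(
                    {
                        "stress": result.stress,
                        "n_restarts": result.n_restarts,
                        "seed": result.seed,
                        "converged": result.converged,
                    },
                    indent=2,
                )
            )
            written["stress"] = stress_path
            if config.environment:
                env = pd.read_csv(config.environment, index_col=0)
                envfit = fit_env_vectors(
                    result,
                    env,
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                )
                path = out_dir / "envfit.csv"
                envfit.to_csv(path, float_format="%.10g")
                written["envfit"] = path
    except Exception as exc:
        from .errors import AeropollenError

        if isinstance(exc, AeropollenError):
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        raise

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "outputs": {k: str(v) for k, v in written.items()},
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = manifest_path
    logger.info("pipeline wrote %d artifact(s) to %s", len(written), out_dir)
    return written
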