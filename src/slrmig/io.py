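"""Readers and writers for the tool's table dialects and run configuration.

All tables are UTF-8, comma-delimited CSV with '.' decimals; identifiers are
opaque strings.  Every reader validates on load; every writer/reader pair
round-trips its own output bit-identically at full float precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from slrmig.effects import EffectsReport, _flag_col
from slrmig.models import MigrationMatrix, NeuralMigrationModel, validate_flow_table
from slrmig.zones import ScenarioTimeline, validate_exposure_table, validate_zone_table

__all__ = [
    "read_zone_table",
    "read_exposure_table",
    "read_flow_table",
    "write_flow_table",
    "read_timeline",
    "write_timeline",
    "read_distance_matrix",
    "write_matrix",
    "read_matrix",
    "write_effects_report",
    "read_effects_report",
    "save_neural_model",
    "load_neural_model",
    "RunConfig",
]


def read_zone_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a zone CSV (zone_id,county_id,lat,lon,population,coastal)."""
    return validate_zone_table(pd.read_csv(path, dtype={"zone_id": str, "county_id": str}))


def read_exposure_table(path: str | Path) -> pd.DataFrame:
    """Load and validate an exposure CSV (subzone_id,zone_id,slr_m,population,affected_population)."""
    return validate_exposure_table(pd.read_csv(path, dtype={"subzone_id": str, "zone_id": str}))


def read_flow_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a flow CSV (origin_id/origin,dest_id/dest,migrants[,year])."""
    return validate_flow_table(pd.read_csv(path, dtype={"origin": str, "dest": str, "origin_id": str, "dest_id": str}))


def write_flow_table(flows: pd.DataFrame, path: str | Path) -> None:
    validate_flow_table(flows).to_csv(path, index=False)


def read_timeline(path: str | Path) -> ScenarioTimeline:
    """Load a timeline JSON {"name": ..., "schedule": [[slr_m, year], ...]}."""
    payload = json.loads(Path(path).read_text())
    return ScenarioTimeline(payload["name"], tuple((float(s), int(y)) for s, y in payload["schedule"]))


def write_timeline(timeline: ScenarioTimeline, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"name": timeline.name, "schedule": [[s, y] for s, y in timeline.schedule]}, indent=2)
    )


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    """Load a long-form distance CSV (origin_id,dest_id,km) into a square matrix."""
    df = pd.read_csv(path, dtype={"origin_id": str, "dest_id": str})
    mat = df.pivot(index="origin_id", columns="dest_id", values="km")
    return mat


def write_matrix(matrix: MigrationMatrix, path: str | Path) -> None:
    """Write a migration matrix as CSV origin,dest,migrants[,year][,component]."""
    matrix.to_frame().to_csv(path, index=False)


def read_matrix(path: str | Path) -> MigrationMatrix:
    df = pd.read_csv(path, dtype={"origin": str, "dest": str})
    label = str(df["component"].iloc[0]) if "component" in df.columns and len(df) else ""
    year = int(df["year"].iloc[0]) if "year" in df.columns and len(df) else None
    return MigrationMatrix.from_frame(df[["origin", "dest", "migrants"]], label=label, year=year)


def write_effects_report(report: EffectsReport, county_csv: str | Path, summary_json: str | Path) -> None:
    """Write the per-county effects CSV plus the summary JSON."""
    report.counties.rename_axis("county_id").to_csv(county_csv)
    Path(summary_json).write_text(json.dumps(report.summary(), indent=2))


def read_effects_report(county_csv: str | Path, summary_json: str | Path) -> EffectsReport:
    summary = json.loads(Path(summary_json).read_text())
    counties = pd.read_csv(county_csv, index_col="county_id", dtype={"county_id": str})
    thresholds = tuple(float(d) for d in summary["indirectly_affected_population"])
    for d in thresholds:
        counties[_flag_col(d)] = counties[_flag_col(d)].astype(bool)
    return EffectsReport(
        slr_m=float(summary["slr_m"]),
        year=int(summary["year"]),
        directly_affected=float(summary["directly_affected"]),
        counties=counties,
        thresholds=thresholds,
    )


def save_neural_model(model: NeuralMigrationModel, path: str | Path) -> None:
    Path(path).write_text(model.to_json())


def load_neural_model(path: str | Path) -> NeuralMigrationModel:
    return NeuralMigrationModel.from_json(Path(path).read_text())


@dataclass
class RunConfig:
    """Resolved configuration of a simulation run, written alongside its outputs."""

    zones: str = ""
    exposure: str = ""
    scenario: str = "high"
    population_mode: str = "exogenous"
    model_mode: str = "dual"
    model_climate: str = "radiation"
    model_bau: str = "radiation"
    alpha: float = 0.5
    rate_climate: float = 1.0
    rate_bau: float = 0.03
    thresholds: tuple[float, ...] = (0.5, 1.0, 3.0, 6.0, 9.0)
    seed: int = 0
    out_dir: str = "."

    def write(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["thresholds"] = list(self.thresholds)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        if "thresholds" in payload:
            payload["thresholds"] = tuple(payload["thresholds"])
        return cls(**payload)
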