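"""Spatial zones, sea-level-rise scenario timelines, and the zone-partition step.

A *zone* is a county-scale spatial unit carrying a centroid, a population and
a coastal flag.  Exposure arrives at a finer sub-zone granularity (census
block-group analogue): for each sub-zone and each SLR increment the table
states the sub-zone population and the portion of it living on land flooded at
that increment.  The climate step splits every zone into an affected half
(``theta_A``, population on flooded land) and an unaffected half (``theta_U``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ZONE_COLUMNS = ["zone_id", "county_id", "lat", "lon", "population", "coastal"]
EXPOSURE_COLUMNS = ["subzone_id", "zone_id", "slr_m", "population", "affected_population"]

#: SLR increments (metres) the exposure tables are expected to cover.
STANDARD_INCREMENTS = (0.3, 0.6, 0.9, 1.2, 1.5, 1.8)


def validate_zone_table(zones: pd.DataFrame) -> pd.DataFrame:
    """Validate a zone table and return it indexed by ``zone_id``.

    Required columns: zone_id, county_id, lat, lon, population, coastal.
    Rejects duplicate zone ids, negative populations and out-of-range
    coordinates.
    """
    missing = [c for c in ZONE_COLUMNS if c not in zones.columns]
    if missing:
        raise ValueError(f"zone table missing columns: {missing}")
    df = zones.copy()
    df["zone_id"] = df["zone_id"].astype(str)
    df["county_id"] = df["county_id"].astype(str)
    if df["zone_id"].duplicated().any():
        dupes = df.loc[df["zone_id"].duplicated(), "zone_id"].tolist()
        raise ValueError(f"duplicate zone ids: {dupes}")
    if (df["population"] < 0).any():
        bad = df.loc[df["population"] < 0, "zone_id"].tolist()
        raise ValueError(f"negative population for zones: {bad}")
    if ((df["lat"] < -90) | (df["lat"] > 90)).any() or ((df["lon"] < -180) | (df["lon"] > 180)).any():
        raise ValueError("zone centroid coordinates out of range")
    df["coastal"] = df["coastal"].astype(bool)
    return df.set_index("zone_id")


def validate_exposure_table(exposure: pd.DataFrame) -> pd.DataFrame:
    """Validate an exposure table (one row per sub-zone per SLR increment).

    Checks 0 <= affected_population <= population and that, for a fixed
    sub-zone, the affected population is nondecreasing in the SLR increment
    (flooding is nested: land under water at 0.3 m stays under water at 0.6 m).
    """
    missing = [c for c in EXPOSURE_COLUMNS if c not in exposure.columns]
    if missing:
        raise ValueError(f"exposure table missing columns: {missing}")
    df = exposure.copy()
    df["subzone_id"] = df["subzone_id"].astype(str)
    df["zone_id"] = df["zone_id"].astype(str)
    if (df["population"] < 0).any() or (df["affected_population"] < 0).any():
        raise ValueError("negative populations in exposure table")
    over = df["affected_population"] > df["population"] + 1e-9
    if over.any():
        bad = df.loc[over, ["subzone_id", "slr_m"]].to_records(index=False).tolist()
        raise ValueError(f"affected_population exceeds population for sub-zones: {bad}")
    ordered = df.sort_values(["subzone_id", "slr_m"])
    diffs = ordered.groupby("subzone_id")["affected_population"].diff()
    if (diffs < -1e-9).any():
        bad = ordered.loc[diffs < -1e-9, "subzone_id"].unique().tolist()
        raise ValueError(f"affected population not nested across increments for sub-zones: {bad}")
    return df


@dataclass(frozen=True)
class ScenarioTimeline:
    """A named schedule pairing SLR increments (metres) with calendar years.

    ``schedule`` is an ordered list of ``(slr_m, year)`` with both coordinates
    strictly increasing: once an increment is reached the sea does not recede.
    """

    name: str
    schedule: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        incs = [s for s, _ in self.schedule]
        years = [y for _, y in self.schedule]
        if any(b <= a for a, b in zip(incs, incs[1:])):
            raise ValueError("SLR increments must be strictly increasing")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")

    def increment_at(self, year: int) -> float:
        """Largest scheduled increment whose year is <= ``year`` (0 before the first)."""
        inc = 0.0
        for slr_m, y in self.schedule:
            if y <= year:
                inc = slr_m
        return inc


#: Medium scenario: 0.9 m by 2100 (0.3/0.6/0.9 m reached in 2055/2080/2100).
MEDIUM_TIMELINE = ScenarioTimeline("medium", ((0.3, 2055), (0.6, 2080), (0.9, 2100)))

#: High scenario: 1.8 m by 2100 (0.3–1.8 m reached 2042/2059/2071/2082/2091/2100).
HIGH_TIMELINE = ScenarioTimeline(
    "high",
    ((0.3, 2042), (0.6, 2059), (0.9, 2071), (1.2, 2082), (1.5, 2091), (1.8, 2100)),
)

BUILTIN_TIMELINES = {"medium": MEDIUM_TIMELINE, "high": HIGH_TIMELINE}


def get_timeline(name: str) -> ScenarioTimeline:
    try:
        return BUILTIN_TIMELINES[name]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; built-ins: {sorted(BUILTIN_TIMELINES)}") from None


def timeline_lookup(timeline: ScenarioTimeline | str, year: int) -> float:
    """SLR increment (metres) in force at ``year`` under the given scenario timeline."""
    if isinstance(timeline, str):
        timeline = get_timeline(timeline)
    return timeline.increment_at(year)


def partition_zones(
    zones: pd.DataFrame,
    exposure: pd.DataFrame | None,
    slr_m: float,
    *,
    populations: pd.Series | None = None,
) -> pd.DataFrame:
    """Split each zone into affected/unaffected halves at an SLR increment.

    Parameters
    ----------
    zones
        Validated zone table indexed by zone_id (see :func:`validate_zone_table`).
    exposure
        Validated exposure table, or None / empty for a no-flooding partition.
    slr_m
        SLR increment to evaluate.  0 (or no matching exposure rows) yields
        affected = 0 everywhere.
    populations
        Optional override of per-zone populations (e.g. populations updated by
        earlier migration steps).  Affected counts from the exposure table are
        capped at the overridden population.

    Returns
    -------
    DataFrame indexed by zone_id with columns ``county_id``, ``lat``, ``lon``,
    ``coastal``, ``affected``, ``unaffected``, ``fully_flooded``.  Both halves
    inherit the parent centroid.  ``affected + unaffected`` equals the zone
    population exactly.
    """
    if zones.index.name != "zone_id":
        zones = validate_zone_table(zones)
    pop = zones["population"].astype(float)
    if populations is not None:
        pop = populations.reindex(zones.index).astype(float)
        if pop.isna().any():
            raise ValueError("population override missing zones")

    if exposure is None or len(exposure) == 0:
        affected = pd.Series(0.0, index=zones.index)
    else:
        unknown = set(exposure["zone_id"].astype(str)) - set(zones.index)
        if unknown:
            raise ValueError(f"exposure references unknown zones: {sorted(unknown)}")
        have = np.unique(exposure["slr_m"].astype(float))
        if slr_m != 0 and not np.isclose(have, slr_m).any():
            raise ValueError(f"slr increment {slr_m} not present in exposure table (has {have.tolist()})")
        sel = exposure.loc[np.isclose(exposure["slr_m"].astype(float), slr_m)]
        affected = (
            sel.groupby("zone_id")["affected_population"].sum().reindex(zones.index).fillna(0.0).astype(float)
        )
    affected = np.minimum(affected, pop)
    out = zones[["county_id", "lat", "lon", "coastal"]].copy()
    out["affected"] = affected
    out["unaffected"] = pop - affected
    out["fully_flooded"] = (out["unaffected"] <= 0) & (pop > 0)
    return out
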