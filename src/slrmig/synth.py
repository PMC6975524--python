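"""Seeded synthetic regions, exposure profiles and flow tables.

The generator emulates the statistical shape of the real inputs the framework
consumes: a Census-style zone table (county-scale units with centroids and
log-normal populations), a NOAA-style exposure table (per sub-zone affected
populations, nested across SLR increments and decaying inland), and IRS-style
county-to-county flow tables, optionally with a hurricane-shock year whose
outflows are inflated and tilted toward nearby destinations.

Geometry is a rectangular coastal region with the coastline along its
southern edge; it makes no attempt at real US geography.  Every operation is
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from slrmig.features import build_feature_table, haversine_km
from slrmig.models import DistanceTiltedModel, ExtendedRadiationModel, MigrationModel, validate_flow_table
from slrmig.zones import STANDARD_INCREMENTS, validate_exposure_table, validate_zone_table

__all__ = ["SyntheticSpec", "generate_region", "generate_flows", "inject_shock"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic coastal region.

    Defaults: 200 county-scale zones, 30% of them coastal, log-normal
    populations (mu=9, sigma=1, i.e. a median of ~8,100 people), flood
    fractions growing with the SLR increment and decaying exponentially with
    distance from the coast.
    """

    n_zones: int = 200
    seed: int = 0
    pop_mu: float = 9.0
    pop_sigma: float = 1.0
    frac_coastal: float = 0.3
    increments: tuple[float, ...] = STANDARD_INCREMENTS
    # flood-fraction curve: f(x, dist) = max_flood_frac * (x / x_max)^flood_exponent
    #                                    * exp(-dist_km / flood_decay_km)
    max_flood_frac: float = 0.8
    flood_exponent: float = 1.5
    flood_decay_km: float = 30.0
    max_subzones: int = 4
    # bounding box (degrees); coastline = southern edge
    lat_range: tuple[float, float] = (25.0, 33.0)
    lon_range: tuple[float, float] = (-98.0, -88.0)

    def __post_init__(self) -> None:
        if self.n_zones < 3:
            raise ValueError("need at least 3 zones")
        if not 0 < self.frac_coastal <= 1:
            raise ValueError("frac_coastal must be in (0, 1]")
        if self.pop_sigma <= 0 or self.max_flood_frac <= 0 or self.max_flood_frac > 1:
            raise ValueError("invalid distribution parameters")


def default_bau_model() -> MigrationModel:
    """Generating model for business-as-usual flows (extended radiation, alpha=0.5)."""
    return ExtendedRadiationModel(alpha=0.5)


def default_climate_model() -> MigrationModel:
    """Generating model for climate-forced flows: distance-tilted extended radiation."""
    return DistanceTiltedModel(ExtendedRadiationModel(alpha=0.5), scale_km=200.0)


def generate_region(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a zone table and a nested exposure table.

    Returns ``(zones, exposure)``: zones indexed by zone_id with one county
    per zone; exposure with 1..max_subzones sub-zones per zone.  Coastal zones
    receive monotone-nested affected populations across increments; inland
    zones have zero exposure at every increment.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_zones
    lat = rng.uniform(*spec.lat_range, size=n)
    lon = rng.uniform(*spec.lon_range, size=n)
    pop = rng.lognormal(spec.pop_mu, spec.pop_sigma, size=n)
    coast_cut = np.quantile(lat, spec.frac_coastal)
    coastal = lat <= coast_cut
    zone_ids = [f"z{k:04d}" for k in range(n)]
    zones = pd.DataFrame(
        {
            "zone_id": zone_ids,
            "county_id": [f"c{k:04d}" for k in range(n)],
            "lat": lat,
            "lon": lon,
            "population": pop,
            "coastal": coastal,
        }
    )
    # distance inland from the coastline (southern edge), ~111 km per degree
    dist_km = (lat - spec.lat_range[0]) * 111.0

    records: list[dict] = []
    x_max = max(spec.increments)
    for k in range(n):
        n_sub = int(rng.integers(1, spec.max_subzones + 1))
        shares = rng.dirichlet(np.ones(n_sub))
        # per-sub-zone vulnerability multiplier, constant across increments so
        # nesting is preserved by construction
        vuln = rng.uniform(0.2, 1.0, size=n_sub) if coastal[k] else np.zeros(n_sub)
        for s_idx in range(n_sub):
            sub_pop = pop[k] * shares[s_idx]
            for x in spec.increments:
                frac = (
                    spec.max_flood_frac
                    * (x / x_max) ** spec.flood_exponent
                    * np.exp(-dist_km[k] / spec.flood_decay_km)
                    * vuln[s_idx]
                )
                records.append(
                    {
                        "subzone_id": f"{zone_ids[k]}_s{s_idx}",
                        "zone_id": zone_ids[k],
                        "slr_m": x,
                        "population": sub_pop,
                        "affected_population": min(frac, 1.0) * sub_pop,
                    }
                )
    exposure = pd.DataFrame.from_records(records)
    return validate_zone_table(zones), validate_exposure_table(exposure)


def region_features(zones: pd.DataFrame) -> pd.DataFrame:
    """Feature table over all ordered zone pairs (full populations, self excluded)."""
    pops = zones["population"].astype(float)
    return build_feature_table(pops, pops, zones[["lat", "lon"]], exclude_self=True)


def generate_flows(
    zones: pd.DataFrame,
    model: MigrationModel,
    rate: float,
    year: int,
    seed: int,
    *,
    feats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sample an IRS-style flow table from a migration model.

    Each origin emits ``round(rate * m_i)`` migrants drawn multinomially over
    the model's probability row.  Returns a validated flow table with columns
    origin, dest, migrants, year (zero cells dropped).
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if feats is None:
        feats = region_features(zones)
    p = model.predict_proba(feats)
    rng = np.random.default_rng(seed)
    pops = zones["population"].astype(float)
    out: list[pd.DataFrame] = []
    for oid, grp_idx in feats.groupby("origin", sort=True).groups.items():
        size = int(round(rate * float(pops.loc[oid])))
        if size == 0:
            continue
        probs = p.loc[grp_idx].to_numpy(float)
        draws = rng.multinomial(size, probs / probs.sum())
        sub = feats.loc[grp_idx, ["origin", "dest"]].copy()
        sub["migrants"] = draws
        out.append(sub[sub["migrants"] > 0])
    flows = pd.concat(out, ignore_index=True) if out else pd.DataFrame(columns=["origin", "dest", "migrants"])
    flows["year"] = year
    return validate_flow_table(flows)


def inject_shock(
    flows: pd.DataFrame,
    counties: list[str],
    multiplier: float,
    seed: int,
    *,
    zones: pd.DataFrame | None = None,
    tilt_km: float = 150.0,
) -> pd.DataFrame:
    """Inflate the outgoing flows of selected counties to emulate a hurricane year.

    Each listed county's outgoing total is scaled to ``multiplier`` times its
    current value; the extra migrants are drawn multinomially over a
    distance-tilted row (``m_j * exp(-d_ij / tilt_km)``) when ``zones`` is
    given, mimicking forced displacement toward nearby populated places.
    Without zone geometry the extra migrants follow the county's existing
    destination shares.
    """
    if multiplier <= 1:
        raise ValueError(f"shock multiplier must exceed 1, got {multiplier}")
    df = validate_flow_table(flows)
    known = set(df["origin"])
    unknown = {str(c) for c in counties} - known
    if unknown:
        raise ValueError(f"unknown shock counties: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    pieces = [df]
    for cty in sorted({str(c) for c in counties}):
        cur = df[df["origin"] == cty]
        total = float(cur["migrants"].sum())
        extra = int(round((multiplier - 1.0) * total))
        if extra == 0:
            continue
        if zones is not None:
            others = zones.drop(index=cty, errors="ignore")
            o = zones.loc[cty]
            d = haversine_km(
                float(o["lat"]), float(o["lon"]), others["lat"].to_numpy(float), others["lon"].to_numpy(float)
            )
            w = others["population"].to_numpy(float) * np.exp(-np.asarray(d) / tilt_km)
            dests = others.index.to_numpy()
        else:
            w = cur["migrants"].to_numpy(float)
            dests = cur["dest"].to_numpy()
        draws = rng.multinomial(extra, w / w.sum())
        add = pd.DataFrame({"origin": cty, "dest": dests, "migrants": draws})
        if "year" in df.columns:
            add["year"] = df["year"].iloc[0]
        pieces.append(add[add["migrants"] > 0])
    merged = pd.concat(pieces, ignore_index=True)
    keys = ["origin", "dest"] + (["year"] if "year" in merged.columns else [])
    merged = merged.groupby(keys, as_index=False)["migrants"].sum()
    return validate_flow_table(merged)
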