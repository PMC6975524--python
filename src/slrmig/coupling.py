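"""Assembling migration matrices and running multi-step SLR scenarios.

For each scheduled step of an SLR timeline the runner partitions zones into
affected/unaffected halves, routes the forced *climate* flows ``T'`` (affected
-> unaffected, whole affected population moves) and the *business-as-usual*
flows ``T''`` (unaffected -> unaffected, a fixed fraction moves), aggregates
``T = T' + T''``, and computes the matched baseline — the same system with no
flooding at all — whose incoming totals anchor the indirect-effect
classification.

Two orthogonal mode switches:

* population mode — ``exogenous`` (default) re-reads each step's populations
  from the input projections; ``compounded`` carries net migration forward so
  later steps see the redistributed population.
* model mode — ``dual`` uses the separately parameterised climate model for
  ``T'``; ``single`` (ablation) routes the climate flows through the
  business-as-usual model as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from slrmig.features import DEFAULT_INTRAZONE_KM, build_feature_table
from slrmig.models import (
    BAU_PRODUCTION,
    CLIMATE_PRODUCTION,
    MigrationMatrix,
    MigrationModel,
    ProductionFunction,
)
from slrmig.zones import ScenarioTimeline, partition_zones

__all__ = ["climate_flows", "bau_flows", "aggregate", "run_scenario", "StepResult", "ScenarioResult"]


def _dest_universe(partitions: pd.DataFrame) -> pd.Series:
    """theta_U populations of zones that still have habitable land (not fully flooded)."""
    ok = ~partitions["fully_flooded"]
    return partitions.loc[ok, "unaffected"]


def climate_flows(
    partitions: pd.DataFrame,
    model: MigrationModel,
    g: ProductionFunction = CLIMATE_PRODUCTION,
    *,
    intrazone_km: float = DEFAULT_INTRAZONE_KM,
    distance_matrix: pd.DataFrame | None = None,
    year: int | None = None,
) -> MigrationMatrix:
    """Forced flows T' from affected halves to unaffected halves.

    Row sums equal ``g(theta_A)`` per origin (the whole affected population
    under the default identity production).  The intra-zone pair — a county's
    affected half relocating to its own unaffected half — is allowed at the
    configured intra-zone distance.
    """
    origins = partitions.loc[partitions["affected"] > 0, "affected"]
    if origins.empty:
        return MigrationMatrix.empty(label="climate", year=year)
    dests = _dest_universe(partitions)
    if dests.empty:
        raise ValueError("no unaffected destinations remain for climate migrants")
    feats = build_feature_table(
        origins,
        dests,
        partitions[["lat", "lon"]],
        exclude_self=False,
        intrazone_km=intrazone_km,
        distance_matrix=distance_matrix,
    )
    p = model.predict_proba(feats)
    production = feats["origin"].map(lambda o: g(float(origins.loc[o])))
    flows = pd.Series(
        (p * production).to_numpy(float),
        index=pd.MultiIndex.from_frame(feats[["origin", "dest"]]),
    )
    return MigrationMatrix(flows[flows > 0], label="climate", year=year)


def bau_flows(
    partitions: pd.DataFrame,
    model: MigrationModel,
    g: ProductionFunction = BAU_PRODUCTION,
    *,
    distance_matrix: pd.DataFrame | None = None,
    year: int | None = None,
) -> MigrationMatrix:
    """Business-as-usual flows T'' between unaffected halves (self-pairs excluded)."""
    dests = _dest_universe(partitions)
    origins = dests[dests > 0]
    if g.rate == 0 or origins.empty:
        return MigrationMatrix.empty(label="bau", year=year)
    if len(dests) < 2:
        raise ValueError("business-as-usual flows need at least two unflooded zones")
    feats = build_feature_table(
        origins,
        dests,
        partitions[["lat", "lon"]],
        exclude_self=True,
        distance_matrix=distance_matrix,
    )
    p = model.predict_proba(feats)
    production = feats["origin"].map(lambda o: g(float(origins.loc[o])))
    flows = pd.Series(
        (p * production).to_numpy(float),
        index=pd.MultiIndex.from_frame(feats[["origin", "dest"]]),
    )
    return MigrationMatrix(flows[flows > 0], label="bau", year=year)


def aggregate(t_climate: MigrationMatrix, t_bau: MigrationMatrix) -> MigrationMatrix:
    """Entrywise aggregate T = T' + T''."""
    return t_climate.add(t_bau, label="total")


@dataclass
class StepResult:
    """One timeline step: partition, component matrices, and the matched baseline."""

    year: int
    slr_m: float
    partitions: pd.DataFrame
    t_climate: MigrationMatrix
    t_bau: MigrationMatrix
    t_total: MigrationMatrix
    t_baseline: MigrationMatrix
    populations: pd.Series  # per-zone population entering this step
    baseline_populations: pd.Series


@dataclass
class ScenarioResult:
    """All steps of a scenario run plus the configuration that produced them."""

    timeline: ScenarioTimeline
    population_mode: str
    model_mode: str
    steps: list[StepResult] = field(default_factory=list)

    def step_at(self, year: int) -> StepResult:
        for s in self.steps:
            if s.year == year:
                return s
        raise KeyError(f"no step for year {year}")


def run_scenario(
    zones: pd.DataFrame,
    exposure: pd.DataFrame | None,
    timeline: ScenarioTimeline,
    model_climate: MigrationModel,
    model_bau: MigrationModel,
    g_climate: ProductionFunction = CLIMATE_PRODUCTION,
    g_bau: ProductionFunction = BAU_PRODUCTION,
    *,
    population_mode: str = "exogenous",
    model_mode: str = "dual",
    intrazone_km: float = DEFAULT_INTRAZONE_KM,
    distance_matrix: pd.DataFrame | None = None,
) -> ScenarioResult:
    """Iterate the timeline's scheduled years and build all migration matrices.

    At every scheduled (increment, year): partition zones, compute ``T'``,
    ``T''`` and ``T = T' + T''``, and the baseline ``T`` for the same
    populations with zero flooding.  In ``compounded`` population mode each
    zone's population is updated by net migration before the next step and the
    affected population at step t is the increment over the previous step
    (people are not displaced twice); in ``exogenous`` mode every step re-reads
    the input projections and uses the total affected at its increment.
    """
    if population_mode not in ("exogenous", "compounded"):
        raise ValueError(f"unknown population mode {population_mode!r}")
    if model_mode not in ("dual", "single"):
        raise ValueError(f"unknown model mode {model_mode!r}")
    if not timeline.schedule:
        raise ValueError("timeline has no scheduled steps")
    if zones.index.name != "zone_id":
        from slrmig.zones import validate_zone_table

        zones = validate_zone_table(zones)

    mc = model_bau if model_mode == "single" else model_climate
    result = ScenarioResult(timeline=timeline, population_mode=population_mode, model_mode=model_mode)

    cur_pop = zones["population"].astype(float).copy()
    base_pop = cur_pop.copy()
    prev_affected = pd.Series(0.0, index=zones.index)

    for slr_m, year in timeline.schedule:
        if population_mode == "exogenous":
            parts = partition_zones(zones, exposure, slr_m)
            step_pop = zones["population"].astype(float)
            step_base_pop = step_pop
        else:
            total_aff = partition_zones(zones, exposure, slr_m)["affected"]
            newly = np.minimum(np.maximum(total_aff - prev_affected, 0.0), cur_pop)
            parts = partition_zones(zones, None, 0.0, populations=cur_pop)
            parts["affected"] = newly
            parts["unaffected"] = cur_pop - newly
            parts["fully_flooded"] = (parts["unaffected"] <= 0) & (cur_pop > 0)
            prev_affected = np.maximum(prev_affected, total_aff)
            step_pop = cur_pop.copy()
            step_base_pop = base_pop.copy()

        t_c = climate_flows(
            parts, mc, g_climate, intrazone_km=intrazone_km, distance_matrix=distance_matrix, year=year
        )
        t_b = bau_flows(parts, model_bau, g_bau, distance_matrix=distance_matrix, year=year)
        t_tot = aggregate(t_c, t_b)

        base_parts = partition_zones(zones, None, 0.0, populations=step_base_pop)
        t_base = bau_flows(base_parts, model_bau, g_bau, distance_matrix=distance_matrix, year=year)

        result.steps.append(
            StepResult(
                year=year,
                slr_m=slr_m,
                partitions=parts,
                t_climate=t_c,
                t_bau=t_b,
                t_total=t_tot,
                t_baseline=t_base,
                populations=step_pop,
                baseline_populations=step_base_pop,
            )
        )

        if population_mode == "compounded":
            outgoing_bau = t_b.row_sums().reindex(cur_pop.index).fillna(0.0)
            incoming = t_tot.col_sums().reindex(cur_pop.index).fillna(0.0)
            cur_pop = parts["unaffected"] - outgoing_bau + incoming
            base_out = t_base.row_sums().reindex(base_pop.index).fillna(0.0)
            base_in = t_base.col_sums().reindex(base_pop.index).fillna(0.0)
            base_pop = base_pop - base_out + base_in

    return result
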