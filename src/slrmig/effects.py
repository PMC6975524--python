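"""Direct and indirect population effects of an SLR-migration scenario.

*Direct effects* count the people living on land flooded at a given SLR
increment (the summed affected populations).  *Indirect effects* flag the
counties whose incoming migrants under the SLR scenario exceed the matched
no-flooding baseline by more than ``d`` percent of the county population —
places that never flood but absorb the redirected migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from slrmig.coupling import StepResult
from slrmig.models import MigrationMatrix

__all__ = [
    "DEFAULT_THRESHOLDS",
    "direct_effects",
    "incoming_by_county",
    "classify_indirect",
    "EffectsReport",
    "build_effects_report",
]

#: Indirect-effect thresholds d, in percent of county population.
DEFAULT_THRESHOLDS = (0.5, 1.0, 3.0, 6.0, 9.0)


def direct_effects(partitions: pd.DataFrame) -> float:
    """Total directly affected population: sum of theta_A over all zones."""
    return float(partitions["affected"].sum())


def incoming_by_county(
    matrix: MigrationMatrix,
    county_map: pd.Series,
    *,
    exclude_intra_county: bool = True,
) -> pd.Series:
    """Incoming migrants per county.

    By default flows whose origin and destination lie in the same county are
    excluded: a county's affected half relocating into its own unaffected half
    moves existing residents around, it does not bring new people in.  Set
    ``exclude_intra_county=False`` to count every arrival.
    """
    counties = pd.Index(sorted(county_map.astype(str).unique()))
    if matrix.data.empty:
        return pd.Series(0.0, index=counties)
    rolled = matrix.county_rollup(county_map.astype(str), exclude_intra=exclude_intra_county)
    incoming = rolled.groupby(level="dest_county").sum()
    return incoming.reindex(counties).fillna(0.0)


def classify_indirect(
    incoming_scenario: pd.Series,
    incoming_baseline: pd.Series,
    county_pops: pd.Series,
    d: float,
) -> pd.Series:
    """Boolean flag per county: extra migrants strictly exceed d% of population."""
    if d <= 0:
        raise ValueError("threshold d must be positive")
    idx = incoming_scenario.index.union(incoming_baseline.index)
    pops = county_pops.reindex(idx)
    if pops.isna().any():
        missing = idx[pops.isna()].tolist()
        raise ValueError(f"county population missing for: {missing}")
    extra = incoming_scenario.reindex(idx).fillna(0.0) - incoming_baseline.reindex(idx).fillna(0.0)
    return extra > (d / 100.0) * pops


@dataclass
class EffectsReport:
    """Per-increment effects summary: direct total plus per-county indirect flags."""

    slr_m: float
    year: int
    directly_affected: float
    counties: pd.DataFrame  # incoming_scenario, incoming_baseline, extra, flag_<d>...
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def indirectly_affected_population(self, d: float) -> float:
        """People living in counties flagged at threshold d."""
        col = _flag_col(d)
        if col not in self.counties.columns:
            raise KeyError(f"threshold {d} not in report (has {self.thresholds})")
        return float(self.counties.loc[self.counties[col], "population"].sum())

    def flagged(self, d: float) -> frozenset[str]:
        col = _flag_col(d)
        return frozenset(self.counties.index[self.counties[col]])

    def summary(self) -> dict:
        return {
            "slr_m": self.slr_m,
            "year": self.year,
            "directly_affected": self.directly_affected,
            "indirectly_affected_population": {
                str(d): self.indirectly_affected_population(d) for d in self.thresholds
            },
            "indirectly_affected_counties": {
                str(d): int(self.counties[_flag_col(d)].sum()) for d in self.thresholds
            },
        }


def _flag_col(d: float) -> str:
    return f"flag_{d:g}"


def build_effects_report(
    step: StepResult,
    county_map: pd.Series,
    *,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    exclude_intra_county: bool = True,
) -> EffectsReport:
    """Assemble the effects report for one scenario step.

    County populations are the step's projected zone populations summed to the
    county level (the population the d% threshold references).
    """
    county_map = county_map.astype(str)
    incoming_s = incoming_by_county(step.t_total, county_map, exclude_intra_county=exclude_intra_county)
    incoming_b = incoming_by_county(step.t_baseline, county_map, exclude_intra_county=exclude_intra_county)
    pops = step.populations.groupby(county_map.reindex(step.populations.index)).sum()
    idx = incoming_s.index.union(incoming_b.index).union(pops.index)
    df = pd.DataFrame(
        {
            "population": pops.reindex(idx).fillna(0.0),
            "incoming_scenario": incoming_s.reindex(idx).fillna(0.0),
            "incoming_baseline": incoming_b.reindex(idx).fillna(0.0),
        }
    )
    df["extra"] = df["incoming_scenario"] - df["incoming_baseline"]
    for d in thresholds:
        df[_flag_col(d)] = classify_indirect(
            df["incoming_scenario"], df["incoming_baseline"], df["population"], d
        )
    return EffectsReport(
        slr_m=step.slr_m,
        year=step.year,
        directly_affected=direct_effects(step.partitions),
        counties=df,
        thresholds=tuple(thresholds),
    )
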