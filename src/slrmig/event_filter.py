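"""Hurricane-shock detection in year-pair flow tables, and training-set splits.

Comparing two consecutive years of county-to-county migration, a coastal
county is flagged as shock-affected when its outgoing migration more than
doubled (over 100% increase) and its shock-year outgoing total exceeds 1,000
migrants.  Applied to US IRS data around 2005 this rule isolates the counties
devastated by Hurricanes Katrina and Rita; here it drives the split of flow
data into climate-model and business-as-usual training sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from slrmig.models import validate_flow_table

__all__ = ["ShockDetectionResult", "detect_shocked_origins", "split_training_data"]


@dataclass
class ShockDetectionResult:
    """Per-county shock statistics plus the flagged set."""

    stats: pd.DataFrame  # outgoing_prev, outgoing_curr, pct_increase, coastal, flagged
    flagged: frozenset[str]


def detect_shocked_origins(
    flows_prev: pd.DataFrame,
    flows_curr: pd.DataFrame,
    coastal: pd.Series,
    *,
    min_increase_pct: float = 100.0,
    min_outgoing: float = 1000.0,
    exclude: tuple[str, ...] = (),
) -> ShockDetectionResult:
    """Flag coastal counties whose outgoing migration spiked between two years.

    A county is flagged when it is coastal, its outgoing total rose by more
    than ``min_increase_pct`` percent, and its current-year outgoing total
    exceeds ``min_outgoing`` migrants.  A county with zero previous outflow
    but positive current outflow counts as an infinite increase (flagged if
    the other criteria hold, with a warning).  ``exclude`` lists counties
    removed after manual inspection (shocks with known non-climate causes).
    """
    prev = validate_flow_table(flows_prev)
    curr = validate_flow_table(flows_curr)
    if prev.empty or curr.empty:
        raise ValueError("both flow tables must be nonempty")
    out_prev = prev.groupby("origin")["migrants"].sum()
    out_curr = curr.groupby("origin")["migrants"].sum()
    idx = out_prev.index.union(out_curr.index)
    coastal = coastal.copy()
    coastal.index = coastal.index.astype(str)
    op = out_prev.reindex(idx).fillna(0.0)
    oc = out_curr.reindex(idx).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(op > 0, 100.0 * (oc - op) / op, np.where(oc > 0, np.inf, 0.0))
    if ((op == 0) & (oc > 0)).any():
        warnings.warn(
            "county with zero previous outflow treated as infinite increase", stacklevel=2
        )
    is_coastal = coastal.reindex(idx).fillna(False).astype(bool)
    flagged = (
        is_coastal.to_numpy()
        & (pct > min_increase_pct)
        & (oc.to_numpy() > min_outgoing)
        & ~idx.isin([str(e) for e in exclude])
    )
    stats = pd.DataFrame(
        {
            "outgoing_prev": op,
            "outgoing_curr": oc,
            "pct_increase": pct,
            "coastal": is_coastal,
            "flagged": flagged,
        },
        index=idx,
    )
    return ShockDetectionResult(stats=stats, flagged=frozenset(idx[flagged]))


def split_training_data(
    flows: pd.DataFrame, shocked: frozenset[str] | set[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a flow table into climate-model and business-as-usual training pairs.

    Climate pairs: shocked origin, unshocked destination (the forced outflows
    the climate model must learn).  Business-as-usual pairs: unshocked origin
    and unshocked destination.  Pairs with a shocked destination appear in
    neither set — arrivals into a disaster zone are neither normal migration
    nor forced displacement.
    """
    df = validate_flow_table(flows)
    shocked = {str(s) for s in shocked}
    unknown = shocked - set(df["origin"]).union(df["dest"])
    if unknown:
        raise ValueError(f"shocked counties absent from the flow table: {sorted(unknown)}")
    if not shocked:
        warnings.warn("empty shocked set: climate training set is empty", stacklevel=2)
    o_shocked = df["origin"].isin(shocked)
    d_shocked = df["dest"].isin(shocked)
    climate = df[o_shocked & ~d_shocked].reset_index(drop=True)
    bau = df[~o_shocked & ~d_shocked].reset_index(drop=True)
    return climate, bau
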