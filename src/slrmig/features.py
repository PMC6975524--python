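"""Migration-model features: populations, great-circle distances, intervening opportunities.

Every mobility model in this package scores an ordered origin–destination pair
from four quantities: origin population ``m_i``, destination population
``m_j``, great-circle distance ``d_ij`` between the zone centroids, and the
*intervening opportunities* ``s_ij`` — the total population living strictly
inside the circle centred at the origin with radius ``d_ij``, excluding both
endpoints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Distance assigned to the intra-zone pair (a zone's affected half moving to
#: its own unaffected half).  Strictly positive so distance-decay models stay
#: finite; the two halves share the parent centroid so no geometric distance
#: exists for them.
DEFAULT_INTRAZONE_KM = 1.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in kilometres (spherical Earth, radius 6371 km).

    Accepts scalars or broadcastable arrays of coordinates in degrees.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude out of [-90, 90]")
    for lon in (lon1, lon2):
        if np.any((lon < -180) | (lon > 180)):
            raise ValueError("longitude out of [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def pairwise_distances_km(zones: pd.DataFrame) -> pd.DataFrame:
    """Symmetric centroid distance matrix (km) for a zone table with lat/lon columns."""
    lat = zones["lat"].to_numpy(float)
    lon = zones["lon"].to_numpy(float)
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=zones.index, columns=zones.index)


def intervening_opportunities(
    zones: pd.DataFrame,
    origin_id: str,
    dest_id: str,
    *,
    populations: pd.Series | None = None,
    distance_matrix: pd.DataFrame | None = None,
) -> float:
    """Population strictly closer to the origin than the destination.

    Sums the populations of all zones ``k`` with ``d_ik < d_ij``, excluding the
    origin and the destination themselves.  Ties at exactly ``d_ij`` fall
    outside the circle interior and are excluded.
    """
    if origin_id == dest_id:
        raise ValueError("intervening opportunities undefined for origin == destination")
    pops = (populations if populations is not None else zones["population"]).astype(float)
    if distance_matrix is not None:
        d_row = distance_matrix.loc[origin_id]
    else:
        o = zones.loc[origin_id]
        d_row = pd.Series(
            haversine_km(o["lat"], o["lon"], zones["lat"].to_numpy(float), zones["lon"].to_numpy(float)),
            index=zones.index,
        )
    d_ij = float(d_row.loc[dest_id])
    inside = d_row.index[(d_row.to_numpy(float) < d_ij)]
    inside = inside.difference([origin_id, dest_id])
    return float(pops.reindex(inside).fillna(0.0).sum())


def build_feature_table(
    origin_pops: pd.Series,
    dest_pops: pd.Series,
    coords: pd.DataFrame,
    *,
    opportunity_pops: pd.Series | None = None,
    exclude_self: bool = True,
    intrazone_km: float = DEFAULT_INTRAZONE_KM,
    distance_matrix: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Feature rows for every ordered (origin, destination) pair.

    Parameters
    ----------
    origin_pops, dest_pops
        Populations of the origin and destination halves, indexed by parent
        zone id.  For climate-migrant features these are the affected (theta_A)
        and unaffected (theta_U) populations; for business-as-usual features
        both are theta_U.
    coords
        DataFrame with ``lat``/``lon`` columns covering every id appearing as
        origin or destination (parent-zone centroids).
    opportunity_pops
        Populations counted as intervening opportunities (third zones).
        Defaults to ``dest_pops`` — the habitable population between origin and
        destination; flooded portions do not count as opportunities.
    exclude_self
        Drop pairs whose origin and destination share a parent zone.  When
        False the intra-zone pair is kept with distance ``intrazone_km`` and
        ``s = 0``.
    distance_matrix
        Optional precomputed distances (km) indexed by zone id on both axes,
        overriding centroid haversine (supports planar toy geometries).

    Returns
    -------
    DataFrame with columns ``origin``, ``dest``, ``m_i``, ``m_j``, ``d_km``, ``s``.
    """
    if len(dest_pops) == 0:
        raise ValueError("empty destination universe (all destinations fully flooded?)")
    if len(origin_pops) == 0:
        raise ValueError("empty origin set")
    origin_ids = origin_pops.index.to_list()
    dest_ids = dest_pops.index.to_list()
    opp = (dest_pops if opportunity_pops is None else opportunity_pops).astype(float)

    all_ids = pd.Index(origin_ids).union(dest_ids).union(opp.index)
    if distance_matrix is not None:
        D = distance_matrix.reindex(index=all_ids, columns=all_ids).to_numpy(float)
        if np.isnan(D).any():
            raise ValueError("distance matrix does not cover all zone ids")
    else:
        sub = coords.reindex(all_ids)
        if sub[["lat", "lon"]].isna().any().any():
            missing = sub.index[sub["lat"].isna()].tolist()
            raise ValueError(f"coordinates missing for zones: {missing}")
        lat = sub["lat"].to_numpy(float)
        lon = sub["lon"].to_numpy(float)
        D = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        np.fill_diagonal(D, 0.0)
    pos = {z: k for k, z in enumerate(all_ids)}

    opp_idx = np.array([pos[z] for z in opp.index], dtype=int)
    opp_pop = opp.to_numpy(float)

    rows_origin: list[str] = []
    rows_dest: list[str] = []
    m_i_col: list[float] = []
    m_j_col: list[float] = []
    d_col: list[float] = []
    s_col: list[float] = []

    dest_positions = np.array([pos[z] for z in dest_ids], dtype=int)
    m_j_all = dest_pops.to_numpy(float)
    opp_by_id = dict(zip(opp.index, opp_pop))

    for oid in origin_ids:
        oi = pos[oid]
        d_to_opp = D[oi, opp_idx]
        order = np.argsort(d_to_opp, kind="stable")
        d_sorted = d_to_opp[order]
        pop_sorted = opp_pop[order]
        csum = np.concatenate([[0.0], np.cumsum(pop_sorted)])

        d_ij = D[oi, dest_positions]
        # population strictly inside the circle of radius d_ij
        k = np.searchsorted(d_sorted, d_ij, side="left")
        s = csum[k]
        # remove origin/destination if they were counted as opportunities
        own = opp_by_id.get(oid, 0.0)
        s = s - np.where(d_ij > 0, own, 0.0)
        for j, did in enumerate(dest_ids):
            if did == oid:
                if exclude_self:
                    continue
                rows_origin.append(oid)
                rows_dest.append(did)
                m_i_col.append(float(origin_pops.loc[oid]))
                m_j_col.append(float(m_j_all[j]))
                d_col.append(float(intrazone_km))
                s_col.append(0.0)
                continue
            # destination inside its own circle boundary only if d_jk < d_ij
            # (never: d to itself equals d_ij); nothing to subtract for dest.
            rows_origin.append(oid)
            rows_dest.append(did)
            m_i_col.append(float(origin_pops.loc[oid]))
            m_j_col.append(float(m_j_all[j]))
            d_col.append(float(d_ij[j]))
            s_col.append(float(max(s[j], 0.0)))

    feats = pd.DataFrame(
        {
            "origin": rows_origin,
            "dest": rows_dest,
            "m_i": m_i_col,
            "m_j": m_j_col,
            "d_km": d_col,
            "s": s_col,
        }
    )
    if feats.empty:
        raise ValueError("no origin-destination pairs after exclusions")
    return feats
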