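"""Comparable-zones control delineation.

A deliberately simpler scheme used to judge the effect of scale on
self-containment: starting from the same plurality-destination seed zones,
the zone with the smallest supply-side self-containment is repeatedly merged
into its contiguous neighbour with the smallest supply-side self-containment
until a requested number of zones remains.  Because merging only happens
along adjacency, the output zones are contiguous by construction.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .errors import NCHDError
from .flows import BipartiteFlows, ZoneSystem, initial_zones, merge_birthless_units, zone_flow_matrix
from .geography import UnitGeography
from .zoning import (
    MergeStep,
    MergeTrace,
    TTWADelineator,
    merge_zones,
    self_containment_table,
    supply_self_containment,
)

__all__ = ["comparable_zones", "ComparableZonesBaseline"]


def comparable_zones(
    flows: BipartiteFlows,
    geo: UnitGeography,
    target_count: int,
    seed_zones: Optional[ZoneSystem] = None,
) -> Tuple[ZoneSystem, MergeTrace]:
    """Merge down to ``target_count`` zones by the supply-side rule.

    Each iteration the zone with the smallest supply-side self-containment is
    merged into the rook-adjacent zone with the smallest supply-side
    self-containment (ties to the smallest zone id in both choices).
    """
    if target_count < 1:
        raise NCHDError("target_count must be >= 1")
    zones = (seed_zones or initial_zones(flows, geo)).copy()
    if target_count > zones.n_zones:
        raise NCHDError(
            f"target_count {target_count} exceeds the initial zone count {zones.n_zones}"
        )
    location = geo.facility_location
    trace = MergeTrace()
    iteration = 0
    while zones.n_zones > target_count:
        T = zone_flow_matrix(flows, zones, location)
        supply = {z: supply_self_containment(T, z) for z in T.zone_ids}
        candidate = min(sorted(supply), key=lambda z: supply[z])
        neighbours = zones.zone_neighbours(candidate)
        if not neighbours:
            raise NCHDError(f"zone {candidate} has no contiguous neighbour to merge into")
        partner = min(sorted(neighbours), key=lambda z: supply[z])
        zones = merge_zones(zones, candidate, partner)
        iteration += 1
        T_after = zone_flow_matrix(flows, zones, location)
        trace.steps.append(
            MergeStep(
                iteration=iteration,
                candidate=candidate,
                candidate_min_sc=supply[candidate],
                partner=partner,
                connectance=float("nan"),
                n_zones_after=zones.n_zones,
                internal_share_after=T_after.internal_share(),
            )
        )
    return zones, trace


class ComparableZonesBaseline(BaseEstimator):
    """Control delineation: supply-side-only merging to a target zone count.

    Parameters
    ----------
    n_zones:
        Number of output zones.  When None, the main delineation is run on
        the same inputs and its zone count is used, giving a like-for-like
        comparison at matched scale.
    threshold:
        Stopping threshold for the internal matched-count run (only used
        when ``n_zones`` is None).
    merge_birthless:
        As in :class:`~nchd.zoning.TTWADelineator`.

    Attributes
    ----------
    zones_, labels_, trace_, self_containment_, n_zones_, geography_
    """

    def __init__(
        self,
        n_zones: Optional[int] = None,
        threshold: float = 0.96,
        merge_birthless: bool = True,
    ):
        self.n_zones = n_zones
        self.threshold = threshold
        self.merge_birthless = merge_birthless

    def fit(self, X: BipartiteFlows, geography: UnitGeography):
        if not isinstance(X, BipartiteFlows):
            raise TypeError("X must be a BipartiteFlows")
        if self.merge_birthless:
            geo, merge_map = merge_birthless_units(geography, X)
            flows = X.relabel_origins(merge_map) if merge_map else X
        else:
            geo, merge_map, flows = geography, {}, X
        target = self.n_zones
        if target is None:
            main = TTWADelineator(
                threshold=self.threshold, merge_birthless=False
            ).fit(flows, geo)
            target = main.n_zones_
        zones, trace = comparable_zones(flows, geo, target)
        T = zone_flow_matrix(flows, zones, geo.facility_location)
        self.geography_ = geo
        self.merge_map_ = merge_map
        self.flows_ = flows
        self.zones_ = zones
        self.trace_ = trace
        self.self_containment_ = self_containment_table(T)
        self.n_zones_ = zones.n_zones
        self.labels_ = zones.labels(geo.unit_ids)
        return self

    def fit_predict(self, X: BipartiteFlows, geography: UnitGeography) -> np.ndarray:
        return self.fit(X, geography).labels_
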