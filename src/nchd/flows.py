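"""Origin-destination birth flows and the hospital-anchored starting zones.

Flows record how many women resident in each sub-district gave birth at each
hospital.  This module aggregates community-level records to sub-districts,
folds birthless units into a same-district neighbour, builds the initial
one-zone-per-hospital system by plurality destination, and tabulates the
square zone-by-zone flow matrix ``T`` that the merge loop operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateScenarioError, NCHDError, SchemaError, UnmappedCommunityError
from .geography import UnitGeography

__all__ = [
    "FlowRecord",
    "BipartiteFlows",
    "Zone",
    "ZoneSystem",
    "ZoneFlowMatrix",
    "aggregate_to_units",
    "merge_birthless_units",
    "initial_zones",
    "zone_flow_matrix",
]


@dataclass(frozen=True)
class FlowRecord:
    """One origin-destination stream: ``count`` women from ``origin_id``
    delivered at hospital ``dest_facility_id``."""

    origin_id: str
    dest_facility_id: str
    count: int

    def __post_init__(self):
        if self.count < 0:
            raise ValueError(f"negative flow count for {self.origin_id}->{self.dest_facility_id}")


class BipartiteFlows:
    """Origin-unit x destination-hospital flow counts.

    Duplicate (origin, destination) pairs are summed on ingest and zero-count
    records dropped, so the stored table has one strictly positive row per
    pair.  ``unit_ids`` / ``facility_ids`` fix the universe of origins and
    destinations; ids appearing in records but not in an explicitly supplied
    universe raise.
    """

    def __init__(
        self,
        records: Iterable[FlowRecord] | pd.DataFrame,
        unit_ids: Optional[Iterable[str]] = None,
        facility_ids: Optional[Iterable[str]] = None,
    ):
        if isinstance(records, pd.DataFrame):
            frame = records[["origin_id", "dest_facility_id", "count"]].copy()
        else:
            frame = pd.DataFrame(
                [(r.origin_id, r.dest_facility_id, r.count) for r in records],
                columns=["origin_id", "dest_facility_id", "count"],
            )
        if len(frame) and (frame["count"] < 0).any():
            raise SchemaError("negative flow counts")
        frame["count"] = frame["count"].astype(np.int64)
        frame = (
            frame.groupby(["origin_id", "dest_facility_id"], as_index=False)["count"]
            .sum()
            .query("count > 0")
            .sort_values(["origin_id", "dest_facility_id"])
            .reset_index(drop=True)
        )
        self.frame = frame

        seen_units = frame["origin_id"].unique().tolist()
        seen_fac = frame["dest_facility_id"].unique().tolist()
        if unit_ids is None:
            self.unit_ids = sorted(seen_units)
        else:
            self.unit_ids = list(unit_ids)
            unknown = set(seen_units) - set(self.unit_ids)
            if unknown:
                raise SchemaError(f"flow origins outside the unit universe: {sorted(unknown)}")
        if facility_ids is None:
            self.facility_ids = sorted(seen_fac)
        else:
            self.facility_ids = list(facility_ids)
            unknown = set(seen_fac) - set(self.facility_ids)
            if unknown:
                raise SchemaError(
                    f"flow destinations outside the facility universe: {sorted(unknown)}"
                )

    @property
    def total(self) -> int:
        return int(self.frame["count"].sum())

    def records(self) -> List[FlowRecord]:
        return [
            FlowRecord(o, d, int(c))
            for o, d, c in zip(
                self.frame["origin_id"], self.frame["dest_facility_id"], self.frame["count"]
            )
        ]

    def outgoing_totals(self) -> Dict[str, int]:
        """Total flow originating in each unit (0 for units never observed)."""
        totals = self.frame.groupby("origin_id")["count"].sum().to_dict()
        return {u: int(totals.get(u, 0)) for u in self.unit_ids}

    def incoming_totals(self) -> Dict[str, int]:
        totals = self.frame.groupby("dest_facility_id")["count"].sum().to_dict()
        return {f: int(totals.get(f, 0)) for f in self.facility_ids}

    def relabel_origins(self, mapping: Mapping[str, str]) -> "BipartiteFlows":
        """Apply a unit merge map (old id -> new id) to the origins."""
        frame = self.frame.copy()
        frame["origin_id"] = frame["origin_id"].map(lambda u: mapping.get(u, u))
        units = sorted({mapping.get(u, u) for u in self.unit_ids})
        return BipartiteFlows(frame, unit_ids=units, facility_ids=self.facility_ids)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, BipartiteFlows) and self.frame.equals(other.frame)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BipartiteFlows({len(self)} streams, {len(self.unit_ids)} units, "
            f"{len(self.facility_ids)} facilities, total={self.total})"
        )


# ---------------------------------------------------------------------------
# Zone system
# ---------------------------------------------------------------------------


@dataclass
class Zone:
    units: Set[str] = field(default_factory=set)
    anchors: Set[str] = field(default_factory=set)


@dataclass
class ZoneSystem:
    """A partition of units into hospital-anchored zones.

    ``assignment`` maps every unit to exactly one zone; ``zones`` holds the
    member units and anchor hospitals per zone.  ``adjacency`` is the
    unit-level neighbour relation inherited from the geography (symmetric,
    irreflexive), kept here so zone-level contiguity can be derived without
    re-touching geometry.
    """

    assignment: Dict[str, str]
    zones: Dict[str, Zone]
    adjacency: Optional[Dict[str, Set[str]]] = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        assigned = set(self.assignment)
        member_union: Set[str] = set()
        for zid, zone in self.zones.items():
            if not zone.units:
                raise NCHDError(f"zone {zid} has no member units")
            member_union |= zone.units
            for u in zone.units:
                if self.assignment.get(u) != zid:
                    raise NCHDError(f"unit {u} listed in zone {zid} but assigned elsewhere")
        if member_union != assigned:
            raise NCHDError("assignment and zone membership disagree")
        if self.adjacency is not None:
            for u, nbrs in self.adjacency.items():
                if u in nbrs:
                    raise NCHDError(f"adjacency is reflexive at {u}")
                for v in nbrs:
                    if u not in self.adjacency.get(v, set()):
                        raise NCHDError(f"adjacency not symmetric for ({u}, {v})")

    @property
    def n_zones(self) -> int:
        return len(self.zones)

    @property
    def zone_ids(self) -> List[str]:
        return sorted(self.zones)

    def labels(self, unit_order: Iterable[str]) -> np.ndarray:
        return np.asarray([self.assignment[u] for u in unit_order], dtype=object)

    def copy(self) -> "ZoneSystem":
        return ZoneSystem(
            assignment=dict(self.assignment),
            zones={z: Zone(set(v.units), set(v.anchors)) for z, v in self.zones.items()},
            adjacency=self.adjacency,
        )

    def zone_neighbours(self, zone_id: str) -> Set[str]:
        """Zones containing a unit rook/queen-adjacent to this zone."""
        if self.adjacency is None:
            raise NCHDError("zone system carries no adjacency")
        out: Set[str] = set()
        for u in self.zones[zone_id].units:
            for v in self.adjacency.get(u, ()):
                z = self.assignment[v]
                if z != zone_id:
                    out.add(z)
        return out


@dataclass
class ZoneFlowMatrix:
    """Square integer matrix ``T`` with ``T[i, j]`` = women resident in zone
    ``zone_ids[i]`` who delivered at a facility located in ``zone_ids[j]``."""

    zone_ids: List[str]
    T: np.ndarray

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=np.int64)
        if self.T.ndim != 2 or self.T.shape[0] != self.T.shape[1]:
            raise NCHDError("T must be square")
        if self.T.shape[0] != len(self.zone_ids):
            raise NCHDError("zone_ids length must match T")
        if (self.T < 0).any():
            raise NCHDError("negative entries in T")
        self._index = {z: k for k, z in enumerate(self.zone_ids)}

    def index(self, zone_id: str) -> int:
        return self._index[zone_id]

    @property
    def total(self) -> int:
        return int(self.T.sum())

    def internal_share(self) -> float:
        """Global share of flows that start and end in the same zone."""
        tot = self.total
        return 1.0 if tot == 0 else float(np.trace(self.T)) / tot


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def aggregate_to_units(
    community_flows: Iterable[FlowRecord] | pd.DataFrame,
    community_lookup: Mapping[str, str],
    facility_ids: Optional[Iterable[str]] = None,
) -> BipartiteFlows:
    """Aggregate community-resolution flows to sub-district units.

    Every origin community must appear in ``community_lookup``; unmapped
    communities raise :class:`UnmappedCommunityError` listing the offenders
    (no fuzzy place-name matching is attempted).  Total flow is conserved
    exactly.
    """
    if isinstance(community_flows, pd.DataFrame):
        frame = community_flows[["origin_id", "dest_facility_id", "count"]].copy()
    else:
        frame = pd.DataFrame(
            [(r.origin_id, r.dest_facility_id, r.count) for r in community_flows],
            columns=["origin_id", "dest_facility_id", "count"],
        )
    unmapped = set(frame["origin_id"]) - set(community_lookup)
    if unmapped:
        raise UnmappedCommunityError(unmapped)
    frame["origin_id"] = frame["origin_id"].map(community_lookup)
    return BipartiteFlows(frame, facility_ids=facility_ids)


def merge_birthless_units(
    geo: UnitGeography, flows: BipartiteFlows
) -> Tuple[UnitGeography, Dict[str, str]]:
    """Fold units with no reported births into a same-district neighbour.

    A unit is birthless when no flow originates from it and none of its
    facilities received any flow.  Each birthless unit is unioned into the
    same-district rook neighbour sharing the longest boundary; a birthless
    unit with no same-district neighbour goes to the nearest same-district
    unit by centroid distance.  Only non-birthless targets are accepted, so
    chains of birthless units resolve over repeated passes.  Returns the new
    geography and the old-to-new unit id map (identity entries omitted).
    """
    incoming = flows.incoming_totals()

    def is_birthless(g: UnitGeography, unit: str, outgoing: Mapping[str, int]) -> bool:
        if outgoing.get(unit, 0) > 0:
            return False
        return all(incoming.get(f, 0) == 0 for f in g.frame.at[unit, "facility_ids"])

    merge_map: Dict[str, str] = {}
    current = geo
    outgoing = flows.outgoing_totals()
    while True:
        out_now = {u: outgoing.get(u, 0) for u in current.unit_ids}
        birthless = sorted(u for u in current.unit_ids if is_birthless(current, u, out_now))
        if not birthless:
            break
        districts = current.district_of
        # whole-district degeneracy check
        for d in sorted(set(districts.values())):
            members = [u for u, dd in districts.items() if dd == d]
            if all(u in birthless for u in members):
                raise DegenerateScenarioError(
                    f"district {d} has no unit with reported births"
                )
        adj = current.adjacency("rook")
        shared = current.shared_boundary_lengths()
        centroids = current.centroids()
        progressed = False
        for u in birthless:
            if u not in current.district_of:  # merged away earlier this pass
                continue
            d = current.district_of[u]
            candidates = [
                v
                for v in adj.get(u, ())
                if current.district_of.get(v) == d
                and v not in birthless
                and v in current.district_of
            ]
            if candidates:
                # longest shared boundary; ties to the smallest unit id
                target = max(sorted(candidates), key=lambda v: shared[frozenset((u, v))])
            else:
                others = [
                    v
                    for v in current.unit_ids
                    if v != u and current.district_of[v] == d and v not in birthless
                ]
                if not others:
                    continue  # neighbourless within a birthless chain; next pass
                ux, uy = centroids[u]
                target = min(
                    others,
                    key=lambda v: ((centroids[v][0] - ux) ** 2 + (centroids[v][1] - uy) ** 2, v),
                )
            current = current.merge_unit_into(u, target)
            merge_map[u] = target
            progressed = True
            # recompute topology for subsequent merges in this pass
            adj = current.adjacency("rook")
            shared = current.shared_boundary_lengths()
            centroids = current.centroids()
        if not progressed:  # pragma: no cover - guarded by district check
            raise DegenerateScenarioError("birthless units could not be resolved")
    # collapse chains old -> ... -> final
    def resolve(u: str) -> str:
        while u in merge_map:
            u = merge_map[u]
        return u

    merge_map = {u: resolve(u) for u in merge_map}
    return current, merge_map


def initial_zones(flows: BipartiteFlows, geo: UnitGeography) -> ZoneSystem:
    """One candidate zone per hospital; each unit joins the zone of the
    hospital receiving the plurality of its flows.

    Ties go to the smallest facility identifier.  A hospital that wins no
    unit co-anchors the zone its own location unit was assigned to.  The
    underlying flow records are never rewritten: cross-zone flows stay
    visible to the merge loop.
    """
    location = geo.facility_location
    unknown = set(flows.facility_ids) - set(location)
    if unknown:
        raise NCHDError(f"flows reference facilities with no location: {sorted(unknown)}")

    by_unit = flows.frame.groupby("origin_id")
    assignment: Dict[str, str] = {}
    for u in geo.unit_ids:
        if u not in by_unit.groups:
            raise NCHDError(
                f"unit {u} has no outgoing flows; run merge_birthless_units first"
            )
        g = by_unit.get_group(u)
        best = g.sort_values(
            ["count", "dest_facility_id"], ascending=[False, True]
        ).iloc[0]["dest_facility_id"]
        assignment[u] = best

    zones: Dict[str, Zone] = {}
    for u, z in assignment.items():
        zones.setdefault(z, Zone()).units.add(u)
    for z in zones:
        zones[z].anchors.add(z)
    # hospitals that won no unit co-anchor their location unit's zone
    for f in flows.facility_ids:
        if f not in zones:
            host_zone = assignment[location[f]]
            zones[host_zone].anchors.add(f)
    return ZoneSystem(assignment=assignment, zones=zones, adjacency=geo.adjacency("rook"))


def zone_flow_matrix(
    flows: BipartiteFlows,
    zones: ZoneSystem,
    facility_location: Mapping[str, str],
) -> ZoneFlowMatrix:
    """Tabulate the zone-by-zone matrix ``T`` from unit-level flows.

    The grand total of ``T`` equals the total of ``flows`` exactly.
    """
    missing_units = set(flows.frame["origin_id"]) - set(zones.assignment)
    if missing_units:
        raise NCHDError(f"flow origins not covered by the zone system: {sorted(missing_units)}")
    missing_fac = set(flows.frame["dest_facility_id"]) - set(facility_location)
    if missing_fac:
        raise NCHDError(f"facilities without a location: {sorted(missing_fac)}")

    zone_ids = zones.zone_ids
    idx = {z: k for k, z in enumerate(zone_ids)}
    origin_zone = flows.frame["origin_id"].map(zones.assignment).map(idx)
    dest_zone = (
        flows.frame["dest_facility_id"].map(facility_location).map(zones.assignment).map(idx)
    )
    n = len(zone_ids)
    T = np.zeros((n, n), dtype=np.int64)
    np.add.at(T, (origin_zone.to_numpy(), dest_zone.to_numpy()), flows.frame["count"].to_numpy())
    out = ZoneFlowMatrix(zone_ids=zone_ids, T=T)
    assert out.total == flows.total, "flow conservation violated"
    return out
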