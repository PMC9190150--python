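"""The adapted travel-to-work-area (TTWA) engine.

Zones are merged iteratively: find the zone with the lowest
min(demand-side, supply-side) self-containment, find its best-connected
partner by the connectance flow function, merge them, and repeat until every
zone clears the self-containment threshold (default 96%).  Zones are only
ever merged, never dissolved.  A final automated pass repairs spatial
contiguity by reassigning detached fragments to the neighbouring zone with
the longest shared boundary.

Self-containment of zone *z*:

* demand-side  = internal flows / all flows **ending** in *z*  (column share)
* supply-side  = internal flows / all flows **starting** in *z*  (row share)

Connectance between zones *i* and *j* (range [0, 2], symmetric):

    C_ij = (T_ij / colsum_j) (T_ij / rowsum_i) + (T_ji / colsum_i) (T_ji / rowsum_j)

Any term with a zero denominator contributes 0; a zone generating or
attracting no trips is treated as vacuously self-contained (fraction 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import NCHDError
from .flows import (
    BipartiteFlows,
    Zone,
    ZoneFlowMatrix,
    ZoneSystem,
    initial_zones,
    merge_birthless_units,
    zone_flow_matrix,
)
from .geography import UnitGeography

__all__ = [
    "DelineationConfig",
    "SelfContainment",
    "MergeStep",
    "MergeTrace",
    "DelineationResult",
    "supply_self_containment",
    "demand_self_containment",
    "self_containment_table",
    "least_self_contained",
    "connectance",
    "best_connected_partner",
    "merge_zones",
    "delineate",
    "contiguity_repair",
    "zone_boundary_lengths",
    "TTWADelineator",
]


@dataclass(frozen=True)
class DelineationConfig:
    """Tunables of the merge loop.

    threshold:
        Minimum min(demand, supply) self-containment every output zone must
        reach, in (0, 1].  Default 0.96.
    contiguity:
        'rook' (shared edges) or 'queen' (edges or corners), used for the
        zero-connectance fallback and contiguity repair.
    """

    threshold: float = 0.96
    contiguity: str = "rook"

    def __post_init__(self):
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.contiguity not in ("rook", "queen"):
            raise ValueError(f"contiguity must be rook or queen, got {self.contiguity!r}")


@dataclass(frozen=True)
class SelfContainment:
    zone_id: str
    demand_side: float
    supply_side: float

    @property
    def minimum(self) -> float:
        return min(self.demand_side, self.supply_side)


@dataclass(frozen=True)
class MergeStep:
    iteration: int
    candidate: str
    candidate_min_sc: float
    partner: str
    connectance: float
    n_zones_after: int
    internal_share_after: float


@dataclass
class MergeTrace:
    steps: List[MergeStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(s) for s in self.steps],
            columns=[
                "iteration",
                "candidate",
                "candidate_min_sc",
                "partner",
                "connectance",
                "n_zones_after",
                "internal_share_after",
            ],
        )

    def __len__(self) -> int:
        return len(self.steps)


# ---------------------------------------------------------------------------
# Elementary quantities
# ---------------------------------------------------------------------------


def supply_self_containment(T: ZoneFlowMatrix, zone: str | int) -> float:
    """Internal flows as a share of all flows originating in the zone."""
    i = T.index(zone) if isinstance(zone, str) else zone
    row = T.T[i, :].sum()
    return 1.0 if row == 0 else float(T.T[i, i]) / float(row)


def demand_self_containment(T: ZoneFlowMatrix, zone: str | int) -> float:
    """Internal flows as a share of all flows ending in the zone."""
    j = T.index(zone) if isinstance(zone, str) else zone
    col = T.T[:, j].sum()
    return 1.0 if col == 0 else float(T.T[j, j]) / float(col)


def self_containment_table(T: ZoneFlowMatrix) -> List[SelfContainment]:
    return [
        SelfContainment(
            zone_id=z,
            demand_side=demand_self_containment(T, k),
            supply_side=supply_self_containment(T, k),
        )
        for k, z in enumerate(T.zone_ids)
    ]


def least_self_contained(T: ZoneFlowMatrix) -> Tuple[str, SelfContainment]:
    """The merge candidate: the zone minimising min(demand, supply) SC.

    Ties break to the smallest zone identifier.  Raises on a single-zone
    system — there is nothing left to merge.
    """
    if len(T.zone_ids) < 2:
        raise NCHDError("nothing to merge: the system has a single zone")
    table = self_containment_table(T)
    best = min(table, key=lambda sc: (sc.minimum, sc.zone_id))
    return best.zone_id, best


def connectance(T: ZoneFlowMatrix, i: str | int, j: str | int) -> float:
    """Symmetric connectance between two distinct zones, in [0, 2].

    Sums the products of the forward flow's origin- and destination-shares
    with the same for the reverse flow; zero-denominator terms contribute 0.
    """
    a = T.index(i) if isinstance(i, str) else i
    b = T.index(j) if isinstance(j, str) else j
    if a == b:
        raise NCHDError("connectance is defined between two distinct zones")
    M = T.T

    def term(x: int, colsum: int, rowsum: int) -> float:
        if colsum == 0 or rowsum == 0:
            return 0.0
        return (float(x) / colsum) * (float(x) / rowsum)

    fwd = term(int(M[a, b]), int(M[:, b].sum()), int(M[a, :].sum()))
    rev = term(int(M[b, a]), int(M[:, a].sum()), int(M[b, :].sum()))
    return fwd + rev


def zone_boundary_lengths(
    zones: ZoneSystem, geo: UnitGeography
) -> Dict[FrozenSet[str], float]:
    """Total shared boundary length for every pair of distinct zones."""
    out: Dict[FrozenSet[str], float] = {}
    for pair, length in geo.shared_boundary_lengths().items():
        u, v = tuple(pair)
        zu, zv = zones.assignment[u], zones.assignment[v]
        if zu != zv:
            key = frozenset((zu, zv))
            out[key] = out.get(key, 0.0) + length
    return out


def best_connected_partner(
    T: ZoneFlowMatrix,
    candidate: str,
    zones: Optional[ZoneSystem] = None,
    geo: Optional[UnitGeography] = None,
) -> str:
    """The zone with the highest connectance to the candidate.

    Ties break to the smallest zone id.  If every connectance is zero (an
    isolated zone exchanging no flows), fall back to the adjacent zone
    sharing the longest boundary, which requires ``zones`` and ``geo``.
    """
    others = [z for z in T.zone_ids if z != candidate]
    if not others:
        raise NCHDError("no partner available: single-zone system")
    values = {z: connectance(T, candidate, z) for z in others}
    best = max(sorted(values), key=lambda z: values[z])
    if values[best] > 0.0:
        return best
    if zones is None or geo is None:
        return best
    boundaries = zone_boundary_lengths(zones, geo)
    adjacent = {
        z: boundaries[frozenset((candidate, z))]
        for z in others
        if frozenset((candidate, z)) in boundaries
    }
    if not adjacent:
        return best
    return max(sorted(adjacent), key=lambda z: adjacent[z])


def merge_zones(zones: ZoneSystem, a: str, b: str) -> ZoneSystem:
    """Merge zone ``a`` into zone ``b``; the result keeps ``b``'s id.

    Member units are reassigned wholesale and anchor sets unioned.  Zones
    are never split by any later step.
    """
    if a == b:
        raise NCHDError("cannot merge a zone with itself")
    if a not in zones.zones or b not in zones.zones:
        raise NCHDError(f"unknown zone id in merge: {a!r} or {b!r}")
    out = zones.copy()
    za, zb = out.zones[a], out.zones[b]
    for u in za.units:
        out.assignment[u] = b
    zb.units |= za.units
    zb.anchors |= za.anchors
    del out.zones[a]
    out.validate()
    return out


def _collapse_matrix(T: ZoneFlowMatrix, a: str, b: str) -> ZoneFlowMatrix:
    """T after merging zone a into zone b (row/col a added into b, then dropped)."""
    ia, ib = T.index(a), T.index(b)
    M = T.T.copy()
    M[ib, :] += M[ia, :]
    M[:, ib] += M[:, ia]
    M = np.delete(np.delete(M, ia, axis=0), ia, axis=1)
    ids = [z for z in T.zone_ids if z != a]
    return ZoneFlowMatrix(zone_ids=ids, T=M)


# ---------------------------------------------------------------------------
# The merge loop and contiguity repair
# ---------------------------------------------------------------------------


@dataclass
class DelineationResult:
    """Everything the merge loop produced.

    ``zones_pre_repair`` satisfies the self-containment stopping rule;
    ``zones`` additionally satisfies spatial contiguity (the repair can
    perturb self-containment, so both systems and both SC tables are kept).
    """

    zones: ZoneSystem
    zones_pre_repair: ZoneSystem
    trace: MergeTrace
    sc_pre_repair: List[SelfContainment]
    sc_post_repair: List[SelfContainment]

    @property
    def min_sc_pre_repair(self) -> float:
        return min(sc.minimum for sc in self.sc_pre_repair)


def delineate(
    flows: BipartiteFlows,
    seed_zones: ZoneSystem,
    geo: UnitGeography,
    config: DelineationConfig = DelineationConfig(),
) -> DelineationResult:
    """Run the merge loop to completion, then repair contiguity.

    Repeats {least self-contained zone -> best-connected partner -> merge}
    until every zone's min(demand, supply) self-containment reaches the
    threshold, or a single zone remains.  Deterministic for fixed inputs.
    """
    location = geo.facility_location
    zones = seed_zones.copy()
    T = zone_flow_matrix(flows, zones, location)
    trace = MergeTrace()
    iteration = 0
    while zones.n_zones > 1:
        table = self_containment_table(T)
        if all(sc.minimum >= config.threshold for sc in table):
            break
        candidate, sc = least_self_contained(T)
        partner = best_connected_partner(T, candidate, zones=zones, geo=geo)
        cvalue = connectance(T, candidate, partner)
        zones = merge_zones(zones, candidate, partner)
        T = _collapse_matrix(T, candidate, partner)
        iteration += 1
        trace.steps.append(
            MergeStep(
                iteration=iteration,
                candidate=candidate,
                candidate_min_sc=sc.minimum,
                partner=partner,
                connectance=cvalue,
                n_zones_after=zones.n_zones,
                internal_share_after=T.internal_share(),
            )
        )
    sc_pre = self_containment_table(T)
    pre_repair = zones.copy()
    repaired = contiguity_repair(zones, geo, rule=config.contiguity)
    T_post = zone_flow_matrix(flows, repaired, location)
    return DelineationResult(
        zones=repaired,
        zones_pre_repair=pre_repair,
        trace=trace,
        sc_pre_repair=sc_pre,
        sc_post_repair=self_containment_table(T_post),
    )


def _zone_components(
    zones: ZoneSystem, adjacency: Mapping[str, Set[str]]
) -> Dict[str, List[Set[str]]]:
    out: Dict[str, List[Set[str]]] = {}
    for zid in zones.zone_ids:
        g = nx.Graph()
        members = zones.zones[zid].units
        g.add_nodes_from(members)
        for u in members:
            for v in adjacency.get(u, ()):
                if v in members:
                    g.add_edge(u, v)
        out[zid] = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return out


def contiguity_repair(
    zones: ZoneSystem, geo: UnitGeography, rule: str = "rook"
) -> ZoneSystem:
    """Reassign detached fragments until every zone is spatially connected.

    For each zone the component holding the anchor hospitals' units is
    retained (the largest component when anchors are split or absent); every
    other component moves wholesale to the adjacent zone with the longest
    total shared boundary.  Each reassignment welds a fragment onto a
    neighbouring component, so the pass count is finite.
    """
    adjacency = geo.adjacency(rule)
    shared = geo.shared_boundary_lengths()
    location = geo.facility_location
    out = zones.copy()
    while True:
        components = _zone_components(out, adjacency)
        broken = sorted(z for z, comps in components.items() if len(comps) > 1)
        if not broken:
            break
        zid = broken[0]
        comps = components[zid]
        anchor_units = {
            location[f] for f in out.zones[zid].anchors if f in location
        }
        keep = next(
            (c for c in comps if c & anchor_units), comps[0]
        )  # comps sorted largest-first
        for comp in comps:
            if comp is keep:
                continue
            lengths: Dict[str, float] = {}
            for u in comp:
                for v in adjacency.get(u, ()):
                    z = out.assignment[v]
                    if z == zid and v in comp:
                        continue
                    if z == zid:  # another fragment of the same zone; skip
                        continue
                    key = frozenset((u, v))
                    lengths[z] = lengths.get(z, 0.0) + shared.get(key, 0.0)
            if not lengths:
                raise NCHDError(
                    f"detached fragment {sorted(comp)} of zone {zid} has no "
                    "adjacent zone to join"
                )
            target = max(sorted(lengths), key=lambda z: lengths[z])
            for u in comp:
                out.assignment[u] = target
                out.zones[target].units.add(u)
                out.zones[zid].units.discard(u)
            # a zone emptied entirely by repair disappears; its anchors follow
            if not out.zones[zid].units:
                out.zones[target].anchors |= out.zones[zid].anchors
                del out.zones[zid]
                break
        out.validate()
    return out


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------


class TTWADelineator(BaseEstimator):
    """Hospital catchment delineation as a clustering-style estimator.

    Partitions sub-district units into self-contained, hospital-anchored
    zones from origin-destination birth flows, in the style of
    regionalisation estimators (``fit`` -> ``labels_``).

    Parameters
    ----------
    threshold:
        Minimum min(demand, supply) self-containment per zone, default 0.96.
    contiguity:
        'rook' or 'queen' adjacency for fallbacks and repair.
    merge_birthless:
        Fold units without reported births into a same-district neighbour
        before seeding zones (default True).

    Attributes
    ----------
    zones_ : ZoneSystem
        Final zones after contiguity repair.
    zones_pre_repair_ : ZoneSystem
        Zones when the stopping rule was met, before repair.
    labels_ : ndarray of zone ids aligned with ``geography_.unit_ids``.
    trace_ : MergeTrace
        One record per merge iteration.
    self_containment_ / self_containment_pre_repair_ : list of SelfContainment
    n_zones_ : int
    geography_ : UnitGeography
        Geography after birthless-unit merging.
    merge_map_ : dict
        Old-to-new unit ids from birthless-unit merging.
    """

    def __init__(
        self,
        threshold: float = 0.96,
        contiguity: str = "rook",
        merge_birthless: bool = True,
    ):
        self.threshold = threshold
        self.contiguity = contiguity
        self.merge_birthless = merge_birthless

    def fit(self, X: BipartiteFlows, geography: UnitGeography):
        """Delineate zones from unit-level flows and the unit tessellation."""
        if not isinstance(X, BipartiteFlows):
            raise TypeError("X must be a BipartiteFlows")
        config = DelineationConfig(threshold=self.threshold, contiguity=self.contiguity)
        if self.merge_birthless:
            geo, merge_map = merge_birthless_units(geography, X)
            flows = X.relabel_origins(merge_map) if merge_map else X
        else:
            geo, merge_map, flows = geography, {}, X
        seeds = initial_zones(flows, geo)
        result = delineate(flows, seeds, geo, config)
        self.geography_ = geo
        self.merge_map_ = merge_map
        self.flows_ = flows
        self.result_ = result
        self.zones_ = result.zones
        self.zones_pre_repair_ = result.zones_pre_repair
        self.trace_ = result.trace
        self.self_containment_ = result.sc_post_repair
        self.self_containment_pre_repair_ = result.sc_pre_repair
        self.n_zones_ = result.zones.n_zones
        self.labels_ = result.zones.labels(geo.unit_ids)
        return self

    def fit_predict(self, X: BipartiteFlows, geography: UnitGeography) -> np.ndarray:
        return self.fit(X, geography).labels_
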