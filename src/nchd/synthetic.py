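"""Synthetic study scenarios.

Generates complete worlds with the statistical structure the delineation
assumes: a lattice tessellation of ~250 sub-district units grouped into ~33
contiguous districts, ~27 hospitals, a gridded population surface, and
community-level birth flows.  Flows follow a gravity (Huff) destination
choice — probability proportional to hospital attractiveness times
distance^(-beta) — with a right-skewed births-per-community distribution
(lognormal, median 7) and a configurable bypass stream to one distant
high-attractiveness hospital, mimicking strong long-range referral/bypass
patterns such as a capital-city clientele at a border hospital.

A planted-partition mode produces flows concentrated within k contiguous
blocks of units with known labels, for partition-recovery experiments.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` children, so identical configs yield
byte-identical scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import DegenerateScenarioError, NCHDError
from .flows import BipartiteFlows, aggregate_to_units
from .geography import UnitGeography
from .indicators import SECTORS, SIGNAL_FUNCTIONS, PopulationSurface

__all__ = [
    "ScenarioConfig",
    "SyntheticScenario",
    "generate_geography",
    "generate_communities",
    "generate_flows",
    "planted_partition_flows",
    "generate_facility_assessments",
    "generate_population",
    "generate_scenario",
]

_STREAMS = ("geography", "communities", "facilities", "flows", "population", "planted")


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator settings; defaults emulate the Eastern-Region study setting.

    250 sub-districts in 33 districts with 27 hospitals; ~4 communities per
    sub-district (~1000 overall); births per community lognormal with median
    7 (right-skewed, mean ~25); gravity decay beta = 5 on network travel
    distance; ~8 travel basins whose boundaries (lake- and ridge-like
    barriers) multiply crossing cost by ``barrier_factor``; 5% of communities
    are bypass streams sending most births to the most attractive hospital.
    Set ``barrier_factor`` to 1 for a homogeneous, barrier-free surface.
    """

    seed: int
    n_units: int = 250
    n_cols: int = 25
    cell_km: float = 6.0
    n_districts: int = 33
    n_hospitals: int = 27
    max_hospitals_per_district: int = 2
    communities_per_unit: int = 4
    births_log_mu: float = math.log(7.0)
    births_log_sigma: float = 1.6
    attractiveness_range: Tuple[float, float] = (1.0, 10.0)
    beta: float = 5.0
    n_basins: int = 8
    barrier_factor: float = 8.0
    bypass_fraction: float = 0.05
    bypass_strength: float = 0.8
    total_population: float = 2_900_000.0
    pop_cell_km: float = 2.0
    cemonc_ready_fraction: float = 0.7
    midwives_mean: float = 20.0

    def __post_init__(self):
        if self.n_units < 1 or self.n_districts < 1 or self.n_hospitals < 1:
            raise ValueError("counts must be positive")
        if self.n_hospitals > self.n_units:
            raise DegenerateScenarioError("more hospitals than units")
        if self.n_districts > self.n_units:
            raise ValueError("more districts than units")
        if not 0.0 <= self.bypass_fraction < 1.0:
            raise ValueError("bypass_fraction must be in [0, 1)")

    def rng(self, stream: str) -> np.random.Generator:
        if stream not in _STREAMS:
            raise ValueError(f"unknown stream {stream!r}")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS.index(stream),))
        )


@dataclass
class SyntheticScenario:
    """A fully generated world, consumable by every other module."""

    config: ScenarioConfig
    geography: UnitGeography
    communities: pd.DataFrame  # community_id, unit_id, x, y, births
    facilities: pd.DataFrame  # facility_id, sector, midwives, 9 signal columns
    attractiveness: Dict[str, float]
    population: PopulationSurface
    community_flows: pd.DataFrame  # origin_id (community), dest_facility_id, count
    unit_flows: BipartiteFlows
    labels: Optional[Dict[str, str]] = None  # planted mode only


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


def _snake_order(n_units: int, n_cols: int) -> List[Tuple[int, int]]:
    """Boustrophedon walk over lattice cells: consecutive cells are rook
    neighbours, so contiguous runs form contiguous districts."""
    n_rows = math.ceil(n_units / n_cols)
    order = []
    for r in range(n_rows):
        cols = range(n_cols) if r % 2 == 0 else range(n_cols - 1, -1, -1)
        order.extend((r, c) for c in cols)
    # truncating keeps the walk contiguous: consecutive cells share an edge
    return order[:n_units]


def generate_geography(config: ScenarioConfig) -> UnitGeography:
    """Square-lattice tessellation with contiguous, balanced districts and
    randomly placed hospitals (capped per district)."""
    rng = config.rng("geography")
    cell = config.cell_km * 1000.0
    walk = _snake_order(config.n_units, config.n_cols)

    # balanced contiguous district runs along the walk
    base, rem = divmod(config.n_units, config.n_districts)
    sizes = [base + (1 if k < rem else 0) for k in range(config.n_districts)]
    district_of_pos: List[int] = []
    for k, s in enumerate(sizes):
        district_of_pos += [k] * s

    width = max(2, len(str(config.n_units)))
    dwidth = max(2, len(str(config.n_districts)))
    unit_ids = [f"U{k + 1:0{width}d}" for k in range(config.n_units)]
    district_ids = [f"D{district_of_pos[k] + 1:0{dwidth}d}" for k in range(config.n_units)]

    # hospitals: random distinct units, at most max_hospitals_per_district each
    perm = rng.permutation(config.n_units)
    per_district: Dict[int, int] = {}
    hospital_units: List[int] = []
    for pos in perm:
        d = district_of_pos[pos]
        if per_district.get(d, 0) >= config.max_hospitals_per_district:
            continue
        hospital_units.append(int(pos))
        per_district[d] = per_district.get(d, 0) + 1
        if len(hospital_units) == config.n_hospitals:
            break
    if len(hospital_units) < config.n_hospitals:
        raise DegenerateScenarioError(
            "cannot place hospitals under the per-district cap; raise "
            "max_hospitals_per_district"
        )
    hwidth = max(2, len(str(config.n_hospitals)))
    facility_of_pos: Dict[int, Tuple[str, ...]] = {p: () for p in range(config.n_units)}
    for h, pos in enumerate(sorted(hospital_units)):
        facility_of_pos[pos] = (f"H{h + 1:0{hwidth}d}",)

    units = []
    for k, (r, c) in enumerate(walk):
        geom = box(c * cell, r * cell, (c + 1) * cell, (r + 1) * cell)
        units.append((unit_ids[k], district_ids[k], geom, facility_of_pos[k]))
    return UnitGeography.from_units(units)


def generate_communities(geo: UnitGeography, config: ScenarioConfig) -> pd.DataFrame:
    """Residential communities: several random points per unit with
    right-skewed birth counts (lognormal, floored at one birth)."""
    rng = config.rng("communities")
    rows = []
    k = 0
    for u in geo.unit_ids:
        minx, miny, maxx, maxy = geo.geometry(u).bounds
        for _ in range(config.communities_per_unit):
            k += 1
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            births = max(
                1,
                int(round(rng.lognormal(config.births_log_mu, config.births_log_sigma))),
            )
            rows.append({"community_id": f"C{k:04d}", "unit_id": u, "x": x, "y": y, "births": births})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flows
# ---------------------------------------------------------------------------

_MIN_DISTANCE_M = 500.0  # gravity distance floor: avoids a singular kernel


def _hospital_points(geo: UnitGeography) -> Tuple[List[str], np.ndarray]:
    location = geo.facility_location
    fids = sorted(location)
    pts = np.array(
        [[geo.geometry(location[f]).centroid.x, geo.geometry(location[f]).centroid.y] for f in fids]
    )
    return fids, pts


def _grow_blocks(geo: UnitGeography, seed_units: List[str]) -> Dict[str, str]:
    """Contiguous blocks by multi-source breadth-first search; block ``Zk``
    grows from ``seed_units[k-1]``."""
    adjacency = geo.adjacency("rook")
    labels: Dict[str, str] = {}
    frontier: List[Tuple[str, str]] = [
        (u, f"Z{i + 1}") for i, u in enumerate(seed_units)
    ]
    for u, lab in frontier:
        labels[u] = lab
    while frontier:
        nxt: List[Tuple[str, str]] = []
        for u, lab in frontier:
            for v in sorted(adjacency.get(u, ())):
                if v not in labels:
                    labels[v] = lab
                    nxt.append((v, lab))
        frontier = nxt
    return labels


def _travel_distances(
    geo: UnitGeography, basin_of: Mapping[str, str], barrier_factor: float
) -> Tuple[Dict[str, int], np.ndarray]:
    """All-pairs network travel distance between unit centroids.

    Edges join rook-adjacent units at centroid Euclidean length; an edge
    crossing a basin boundary costs ``barrier_factor`` times more, the way a
    lake crossing or an unsurfaced mountain pass lengthens a journey.
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import shortest_path

    units = geo.unit_ids
    index = {u: k for k, u in enumerate(units)}
    centroids = geo.centroids()
    g = lil_matrix((len(units), len(units)))
    for u, nbrs in geo.adjacency("rook").items():
        for v in nbrs:
            if index[u] < index[v]:
                ux, uy = centroids[u]
                vx, vy = centroids[v]
                w = math.hypot(ux - vx, uy - vy)
                if basin_of[u] != basin_of[v]:
                    w *= barrier_factor
                g[index[u], index[v]] = w
                g[index[v], index[u]] = w
    D = shortest_path(g.tocsr(), method="D", directed=False)
    return index, D


def generate_flows(
    geo: UnitGeography,
    config: ScenarioConfig,
    communities: Optional[pd.DataFrame] = None,
    attractiveness: Optional[Dict[str, float]] = None,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Community-to-hospital birth flows from the gravity choice model.

    Each community's births are multinomial over hospitals with probability
    proportional to attractiveness x distance^(-beta).  A random
    ``bypass_fraction`` of communities additionally routes ``bypass_strength``
    of its choice mass to the single most attractive hospital regardless of
    distance — a few strong long-range bypass streams rather than uniform
    leakage, the way a distant metropolitan clientele concentrates on one
    border hospital.  Returns the community-level flow table (origin_id =
    community id, plus its unit for aggregation) and the attractiveness map.
    """
    if config.beta <= 0:
        raise ValueError("distance-decay exponent beta must be positive")
    if communities is None:
        communities = generate_communities(geo, config)
    rng = config.rng("flows")
    fids, pts = _hospital_points(geo)
    if attractiveness is None:
        lo, hi = config.attractiveness_range
        attr = dict(zip(fids, rng.uniform(lo, hi, size=len(fids))))
    else:
        attr = dict(attractiveness)
    attr_vec = np.array([attr[f] for f in fids])
    bypass_idx = int(np.argmax(attr_vec))

    # travel basins grown from hospital units, so each basin has a hospital
    units = geo.unit_ids
    location = geo.facility_location
    if config.barrier_factor > 1.0 and config.n_basins > 1:
        hospital_units = sorted(set(location.values()))
        n_basins = min(config.n_basins, len(hospital_units))
        seeds = sorted(rng.choice(hospital_units, size=n_basins, replace=False))
        basin_of = _grow_blocks(geo, list(seeds))
    else:
        basin_of = {u: "Z1" for u in units}
    index, D = _travel_distances(geo, basin_of, config.barrier_factor)
    hosp_idx = np.array([index[location[f]] for f in fids])
    centroids = geo.centroids()
    cunit_idx = communities["unit_id"].map(index).to_numpy()
    cxy = communities[["x", "y"]].to_numpy()
    cent = np.array([centroids[u] for u in units])
    # community -> own-unit centroid hop, then network distance between units
    hop = np.sqrt(((cxy - cent[cunit_idx]) ** 2).sum(axis=1))
    d = hop[:, None] + D[np.ix_(cunit_idx, hosp_idx)]
    d = np.maximum(d, _MIN_DISTANCE_M)
    weight = attr_vec[None, :] * d ** (-config.beta)
    probs = weight / weight.sum(axis=1, keepdims=True)
    # bypass streams cluster near the bypass hospital, the way a border
    # hospital draws a distant metropolitan clientele through the districts
    # adjoining it: being a bypasser decays with distance to that hospital
    n_comm = len(communities)
    d_bypass = d[:, bypass_idx]
    w_near = np.exp(-3.0 * d_bypass / max(d_bypass.max(), 1.0))
    p_bypass = np.minimum(1.0, config.bypass_fraction * n_comm * w_near / w_near.sum())
    bypassers = rng.random(n_comm) < p_bypass
    probs[bypassers] *= 1.0 - config.bypass_strength
    probs[bypassers, bypass_idx] += config.bypass_strength

    births = communities["births"].to_numpy()
    rows = []
    for i, (cid, uid) in enumerate(zip(communities["community_id"], communities["unit_id"])):
        counts = rng.multinomial(births[i], probs[i])
        for j in np.nonzero(counts)[0]:
            rows.append(
                {
                    "origin_id": cid,
                    "unit_id": uid,
                    "dest_facility_id": fids[j],
                    "count": int(counts[j]),
                }
            )
    return pd.DataFrame(rows), attr


def planted_partition_flows(
    geo: UnitGeography,
    k: int,
    within_prob: float,
    config: ScenarioConfig,
    communities: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Flows with a known k-block ground truth.

    Units are split into k contiguous blocks grown by multi-source
    breadth-first search from k hospital seed units, so every block contains
    at least one hospital.  Each birth delivers at a uniformly chosen
    hospital inside its own block with probability ``within_prob``,
    otherwise at a uniformly chosen outside hospital.  Returns the
    community-level flows and the unit -> block label map.
    """
    if not (0.5 < within_prob <= 1.0):
        raise ValueError("within_prob must be in (0.5, 1]")
    location = geo.facility_location
    if k > len(location):
        raise NCHDError(f"k={k} exceeds the number of hospitals ({len(location)})")
    rng = config.rng("planted")
    if communities is None:
        communities = generate_communities(geo, config)

    hospital_units = sorted({location[f] for f in location})
    seed_units = list(rng.choice(hospital_units, size=k, replace=False))
    labels = _grow_blocks(geo, seed_units)
    if set(labels) != set(geo.unit_ids):
        raise NCHDError("could not grow k contiguous blocks covering all units")

    block_of_hospital = {f: labels[location[f]] for f in location}
    blocks: Dict[str, List[str]] = {}
    for f, b in block_of_hospital.items():
        blocks.setdefault(b, []).append(f)
    for b in blocks:
        blocks[b].sort()
    all_f = sorted(location)

    rows = []
    for row in communities.itertuples():
        lab = labels[row.unit_id]
        inside = blocks[lab]
        outside = [f for f in all_f if f not in inside]
        n_in = rng.binomial(row.births, within_prob) if outside else row.births
        counts: Dict[str, int] = {}
        if n_in:
            picks = rng.integers(0, len(inside), size=n_in)
            for p in picks:
                counts[inside[p]] = counts.get(inside[p], 0) + 1
        n_out = row.births - n_in
        if n_out:
            picks = rng.integers(0, len(outside), size=n_out)
            for p in picks:
                counts[outside[p]] = counts.get(outside[p], 0) + 1
        for f, c in counts.items():
            rows.append(
                {
                    "origin_id": row.community_id,
                    "unit_id": row.unit_id,
                    "dest_facility_id": f,
                    "count": c,
                }
            )
    return pd.DataFrame(rows), labels


# ---------------------------------------------------------------------------
# Facilities & population
# ---------------------------------------------------------------------------


def generate_facility_assessments(geo: UnitGeography, config: ScenarioConfig) -> pd.DataFrame:
    """Randomised EmONC survey table: sector, midwife staffing (Poisson) and
    the nine signal functions, with a configurable CEmONC-ready share."""
    rng = config.rng("facilities")
    fids = sorted(geo.facility_location)
    rows = []
    for f in fids:
        ready = rng.random() < config.cemonc_ready_fraction
        signals = {s: True for s in SIGNAL_FUNCTIONS}
        if not ready:
            n_fail = 1 + int(rng.integers(0, 3))
            for s in rng.choice(SIGNAL_FUNCTIONS, size=n_fail, replace=False):
                signals[s] = False
        row = {
            "facility_id": f,
            "sector": SECTORS[int(rng.choice(len(SECTORS), p=[0.6, 0.25, 0.15]))],
            "midwives": int(rng.poisson(config.midwives_mean)),
        }
        row.update({s: int(signals[s]) for s in SIGNAL_FUNCTIONS})
        rows.append(row)
    return pd.DataFrame(rows)


def generate_population(geo: UnitGeography, config: ScenarioConfig) -> PopulationSurface:
    """Lognormal-noise population grid over the tessellation's bounding box,
    scaled to the configured regional total."""
    rng = config.rng("population")
    bounds = np.array([geo.geometry(u).bounds for u in geo.unit_ids])
    minx, miny = bounds[:, 0].min(), bounds[:, 1].min()
    maxx, maxy = bounds[:, 2].max(), bounds[:, 3].max()
    cell = config.pop_cell_km * 1000.0
    nc = int(math.ceil((maxx - minx) / cell))
    nr = int(math.ceil((maxy - miny) / cell))
    raw = rng.lognormal(0.0, 1.0, size=(nr, nc))
    values = raw * (config.total_population / raw.sum())
    return PopulationSurface(values=values, x0=float(minx), y0=float(miny), cell_size=cell)


# ---------------------------------------------------------------------------
# Full scenarios
# ---------------------------------------------------------------------------


def generate_scenario(
    config: ScenarioConfig,
    planted_k: Optional[int] = None,
    within_prob: float = 0.99,
) -> SyntheticScenario:
    """Generate a complete world; gravity mode by default, planted-partition
    mode when ``planted_k`` is given."""
    geo = generate_geography(config)
    communities = generate_communities(geo, config)
    facilities = generate_facility_assessments(geo, config)
    population = generate_population(geo, config)
    labels = None
    if planted_k is None:
        cflows, attr = generate_flows(geo, config, communities=communities)
    else:
        cflows, labels = planted_partition_flows(
            geo, planted_k, within_prob, config, communities=communities
        )
        attr = {f: 1.0 for f in sorted(geo.facility_location)}
    lookup = dict(zip(communities["community_id"], communities["unit_id"]))
    unit_flows = aggregate_to_units(
        cflows[["origin_id", "dest_facility_id", "count"]],
        lookup,
        facility_ids=sorted(geo.facility_location),
    )
    return SyntheticScenario(
        config=config,
        geography=geo,
        communities=communities,
        facilities=facilities,
        attractiveness=attr,
        population=population,
        community_flows=cflows,
        unit_flows=unit_flows,
        labels=labels,
    )
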