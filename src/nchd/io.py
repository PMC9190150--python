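"""Readers, writers and reporting helpers for the standard file formats.

Flows, facility assessments, population grids, merge traces and indicator
tables travel as plain CSV; unit tessellations and dissolved zone polygons
as GeoJSON FeatureCollections in a planar projected CRS.  All readers
validate schemas strictly and fail with the offending column or feature
named; write-then-read is the identity on the data model.
"""

from __future__ import annotations

import decimal
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .errors import NCHDError, SchemaError
from .flows import BipartiteFlows, ZoneSystem
from .geography import UnitGeography
from .indicators import SIGNAL_FUNCTIONS, PopulationSurface
from .zoning import MergeTrace, SelfContainment

__all__ = [
    "CompletenessReport",
    "completeness_report",
    "filter_flows_for_map",
    "read_flows_csv",
    "write_flows_csv",
    "read_units_geojson",
    "write_units_geojson",
    "read_facilities_csv",
    "write_facilities_csv",
    "read_population_csv",
    "write_population_csv",
    "write_zones_geojson",
    "write_assignment_csv",
    "read_assignment_csv",
    "write_trace_csv",
    "write_indicators_csv",
]


# ---------------------------------------------------------------------------
# Completeness reporting and map filtering
# ---------------------------------------------------------------------------


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal; 0.0 on an empty denominator."""
    if denominator == 0:
        return 0.0
    q = decimal.Decimal(numerator) * 100 / decimal.Decimal(denominator)
    return float(q.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class CompletenessReport:
    """Record-linkage completeness: aggregate counts vs individual records vs
    successfully geocoded records."""

    n_aggregate: int
    n_individual: int
    n_geocoded: int
    pct_individual_of_aggregate: float
    pct_geocoded_of_individual: float

    def to_dict(self) -> Dict[str, float]:
        return dict(vars(self))


def completeness_report(n_aggregate: int, n_individual: int, n_geocoded: int) -> CompletenessReport:
    """Build the data-completeness summary for the participant flow diagram."""
    for name, v in (("n_aggregate", n_aggregate), ("n_individual", n_individual), ("n_geocoded", n_geocoded)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    if n_geocoded > n_individual:
        raise ValueError("n_geocoded cannot exceed n_individual")
    if n_individual > n_aggregate:
        warnings.warn(
            "individual records exceed aggregate counts: possible double entry",
            stacklevel=2,
        )
    return CompletenessReport(
        n_aggregate=int(n_aggregate),
        n_individual=int(n_individual),
        n_geocoded=int(n_geocoded),
        pct_individual_of_aggregate=_pct(n_individual, n_aggregate),
        pct_geocoded_of_individual=_pct(n_geocoded, n_individual),
    )


def filter_flows_for_map(flows: BipartiteFlows, min_count: int = 6) -> BipartiteFlows:
    """Drop streams below ``min_count`` women (default 6) for legible flow
    maps; the input object is untouched."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    kept = flows.frame[flows.frame["count"] >= min_count].copy()
    return BipartiteFlows(kept, unit_ids=flows.unit_ids, facility_ids=flows.facility_ids)


# ---------------------------------------------------------------------------
# Flows CSV
# ---------------------------------------------------------------------------

_FLOW_COLUMNS = ["origin_id", "dest_facility_id", "count"]


def read_flows_csv(path: str | Path) -> BipartiteFlows:
    frame = pd.read_csv(path, dtype={"origin_id": str, "dest_facility_id": str})
    missing = [c for c in _FLOW_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: flow CSV missing column(s) {missing}")
    bad = frame[pd.to_numeric(frame["count"], errors="coerce").isna()]
    if len(bad):
        lines = (bad.index + 2).tolist()  # +1 header, +1 zero-base
        raise SchemaError(f"{path}: non-numeric count at line(s) {lines}")
    frame["count"] = frame["count"].astype(np.int64)
    if (frame["count"] < 0).any():
        lines = (frame.index[frame["count"] < 0] + 2).tolist()
        raise SchemaError(f"{path}: negative count at line(s) {lines}")
    return BipartiteFlows(frame[_FLOW_COLUMNS])


def write_flows_csv(flows: BipartiteFlows, path: str | Path) -> None:
    flows.frame[_FLOW_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Unit geography GeoJSON
# ---------------------------------------------------------------------------


def read_units_geojson(path: str | Path) -> UnitGeography:
    """Read a unit tessellation from a GeoJSON FeatureCollection.

    Features need ``unit_id`` and ``district_id`` properties (optionally
    ``facility_ids``, a list).  Coordinates must be planar/projected;
    longitude-latitude-looking coordinates are rejected.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    units = []
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        for key in ("unit_id", "district_id"):
            if key not in props:
                raise SchemaError(f"{path}: feature {k} missing property {key!r}")
        geom = shape(feat["geometry"])
        units.append(
            (str(props["unit_id"]), str(props["district_id"]), geom, tuple(props.get("facility_ids", ())))
        )
    return UnitGeography.from_units(units)


def write_units_geojson(geo: UnitGeography, path: str | Path) -> None:
    features = []
    for u in geo.unit_ids:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "unit_id": u,
                    "district_id": geo.district_of[u],
                    "facility_ids": list(geo.frame.at[u, "facility_ids"]),
                },
                "geometry": mapping(geo.geometry(u)),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_zones_geojson(
    zones: ZoneSystem,
    geo: UnitGeography,
    path: str | Path,
    self_containment: Optional[List[SelfContainment]] = None,
    baseline: bool = False,
) -> None:
    """Dissolve member units into one polygon per zone and write GeoJSON with
    membership, anchors and (optionally) demand/supply self-containment."""
    sc = {s.zone_id: s for s in self_containment or []}
    features = []
    for z in zones.zone_ids:
        members = sorted(zones.zones[z].units)
        geom = shapely.union_all([geo.geometry(u) for u in members])
        props = {
            "zone_id": z,
            "members": members,
            "anchors": sorted(zones.zones[z].anchors),
            "baseline": baseline,
        }
        if z in sc:
            props["demand_self_containment"] = sc[z].demand_side
            props["supply_self_containment"] = sc[z].supply_side
        features.append({"type": "Feature", "properties": props, "geometry": mapping(geom)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# Facilities CSV
# ---------------------------------------------------------------------------

_FACILITY_COLUMNS = ["facility_id", "sector", "midwives", *SIGNAL_FUNCTIONS]


def read_facilities_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"facility_id": str, "sector": str})
    missing = [c for c in _FACILITY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: facility CSV missing column(s) {missing}")
    if (frame["midwives"] < 0).any():
        raise SchemaError(f"{path}: negative midwife counts")
    for c in SIGNAL_FUNCTIONS:
        if not frame[c].isin([0, 1]).all():
            raise SchemaError(f"{path}: signal-function column {c!r} must be 0/1")
    return frame[_FACILITY_COLUMNS].copy()


def write_facilities_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame[_FACILITY_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Population grid CSV
# ---------------------------------------------------------------------------


def read_population_csv(path: str | Path) -> PopulationSurface:
    """Read a gridded population surface from an ``x,y,pop`` cell-centre CSV.

    The grid must be regular; spacing is inferred from the coordinates.
    """
    frame = pd.read_csv(path)
    for c in ("x", "y", "pop"):
        if c not in frame.columns:
            raise SchemaError(f"{path}: population grid missing column {c!r}")
    xs = np.sort(frame["x"].unique())
    ys = np.sort(frame["y"].unique())
    dx = np.diff(xs)
    dy = np.diff(ys)
    if len(dx) == 0 and len(dy) == 0:
        cell = 1.0
    else:
        steps = np.concatenate([dx, dy])
        cell = float(steps.min())
        if not np.allclose(np.concatenate([dx, dy]) % cell, 0, atol=1e-6):
            raise SchemaError(f"{path}: cell centres do not lie on a regular grid")
    values = np.zeros((len(ys), len(xs)))
    xi = {v: i for i, v in enumerate(xs)}
    yi = {v: i for i, v in enumerate(ys)}
    for row in frame.itertuples():
        if row.pop < 0:
            raise SchemaError(f"{path}: negative population cell at ({row.x}, {row.y})")
        values[yi[row.y], xi[row.x]] = row.pop
    return PopulationSurface(
        values=values, x0=float(xs[0] - cell / 2), y0=float(ys[0] - cell / 2), cell_size=cell
    )


def write_population_csv(surface: PopulationSurface, path: str | Path) -> None:
    xs, ys, pops = surface.cell_centres()
    pd.DataFrame({"x": xs, "y": ys, "pop": pops}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Assignments, traces, indicators
# ---------------------------------------------------------------------------


def write_assignment_csv(zones: ZoneSystem, path: str | Path) -> None:
    rows = [{"unit_id": u, "zone_id": z} for u, z in sorted(zones.assignment.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assignment_csv(path: str | Path) -> Dict[str, str]:
    frame = pd.read_csv(path, dtype=str)
    for c in ("unit_id", "zone_id"):
        if c not in frame.columns:
            raise SchemaError(f"{path}: assignment CSV missing column {c!r}")
    return dict(zip(frame["unit_id"], frame["zone_id"]))


def write_trace_csv(trace: MergeTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_indicators_csv(indicators: pd.DataFrame, path: str | Path) -> None:
    indicators.to_csv(path)
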