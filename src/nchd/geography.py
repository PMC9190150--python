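"""Planar tessellations of health sub-districts.

A :class:`UnitGeography` holds the polygon of every sub-district unit, its
administrative district, and the hospitals located inside it, all in a planar
projected coordinate system (metres).  It derives the rook/queen adjacency
structure and shared-boundary lengths that the zone-design and contiguity
repair steps consume.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Mapping, Set, Tuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .errors import GeometryError

__all__ = ["UnitGeography"]

# Overlap below this share of the smaller polygon's area is treated as
# floating-point slack from snapped boundaries, not a genuine overlap.
_OVERLAP_AREA_TOL = 1e-9


def _looks_geographic(geoms: Iterable[BaseGeometry]) -> bool:
    xs, ys = [], []
    for g in geoms:
        minx, miny, maxx, maxy = g.bounds
        xs += [minx, maxx]
        ys += [miny, maxy]
    return max(abs(v) for v in xs) <= 180.0 and max(abs(v) for v in ys) <= 90.0


class UnitGeography:
    """Tessellated sub-district polygons with district and facility metadata.

    Parameters
    ----------
    frame:
        DataFrame indexed by ``unit_id`` with columns ``district_id`` (str),
        ``geometry`` (shapely Polygon/MultiPolygon in a planar projected CRS)
        and ``facility_ids`` (tuple of hospital ids located in the unit,
        possibly empty).
    validate:
        Check polygon validity, pairwise interior-disjointness, unique
        facility locations and a heuristic planar-CRS test.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        required = {"district_id", "geometry", "facility_ids"}
        missing = required - set(frame.columns)
        if missing:
            raise GeometryError(f"unit frame missing columns: {sorted(missing)}")
        self.frame = frame.copy()
        self.frame["facility_ids"] = self.frame["facility_ids"].apply(tuple)
        self._adjacency: Dict[str, Dict[str, Set[str]]] = {}
        self._shared: Dict[FrozenSet[str], float] | None = None
        if validate:
            self._validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_units(
        cls,
        units: Iterable[Tuple[str, str, BaseGeometry, Iterable[str]]],
        validate: bool = True,
    ) -> "UnitGeography":
        rows = [
            {"unit_id": u, "district_id": d, "geometry": g, "facility_ids": tuple(f)}
            for u, d, g, f in units
        ]
        frame = pd.DataFrame(rows).set_index("unit_id")
        return cls(frame, validate=validate)

    def _validate(self) -> None:
        if self.frame.index.duplicated().any():
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise GeometryError(f"duplicate unit ids: {dupes}")
        invalid = [u for u, g in self.frame["geometry"].items() if not g.is_valid]
        if invalid:
            raise GeometryError(f"invalid (self-intersecting) polygons: {invalid}")
        if _looks_geographic(self.frame["geometry"]):
            raise GeometryError(
                "coordinates fall inside [-180, 180] x [-90, 90]; supply a planar "
                "projected CRS (metres), not geographic longitude/latitude"
            )
        seen: Dict[str, str] = {}
        for u, fids in self.frame["facility_ids"].items():
            for f in fids:
                if f in seen:
                    raise GeometryError(
                        f"facility {f} located in both {seen[f]} and {u}"
                    )
                seen[f] = u
        self._check_interior_disjoint()

    def _check_interior_disjoint(self) -> None:
        geoms = list(self.frame["geometry"])
        ids = list(self.frame.index)
        tree = STRtree(geoms)
        left, right = tree.query(geoms, predicate="intersects")
        offending = []
        for i, j in zip(left, right):
            if i >= j:
                continue
            inter = geoms[i].intersection(geoms[j])
            min_area = min(geoms[i].area, geoms[j].area)
            if inter.area > _OVERLAP_AREA_TOL * max(min_area, 1.0):
                offending.append((ids[i], ids[j]))
        if offending:
            raise GeometryError(f"overlapping unit polygons: {sorted(offending)}")

    # -- accessors ---------------------------------------------------------
    @property
    def unit_ids(self) -> list:
        return list(self.frame.index)

    @property
    def district_of(self) -> Mapping[str, str]:
        return self.frame["district_id"].to_dict()

    @property
    def facility_location(self) -> Dict[str, str]:
        """Map facility id -> unit id containing it."""
        out: Dict[str, str] = {}
        for u, fids in self.frame["facility_ids"].items():
            for f in fids:
                out[f] = u
        return out

    def geometry(self, unit_id: str) -> BaseGeometry:
        return self.frame.at[unit_id, "geometry"]

    def centroids(self) -> Dict[str, Tuple[float, float]]:
        return {
            u: (g.centroid.x, g.centroid.y) for u, g in self.frame["geometry"].items()
        }

    # -- topology ----------------------------------------------------------
    def adjacency(self, rule: str = "rook") -> Dict[str, Set[str]]:
        """Unit-level neighbour sets under rook or queen contiguity.

        Rook: boundaries share a segment of positive length.  Queen: any
        boundary contact, including single points.
        """
        if rule not in ("rook", "queen"):
            raise ValueError(f"contiguity rule must be 'rook' or 'queen', got {rule!r}")
        if rule in self._adjacency:
            return self._adjacency[rule]
        geoms = list(self.frame["geometry"])
        ids = list(self.frame.index)
        tree = STRtree(geoms)
        adj: Dict[str, Set[str]] = {u: set() for u in ids}
        left, right = tree.query(geoms, predicate="intersects")
        for i, j in zip(left, right):
            if i >= j:
                continue
            inter = geoms[i].intersection(geoms[j])
            touches = inter.length > 0 if rule == "rook" else not inter.is_empty
            if touches:
                adj[ids[i]].add(ids[j])
                adj[ids[j]].add(ids[i])
        self._adjacency[rule] = adj
        return adj

    def shared_boundary_lengths(self) -> Dict[FrozenSet[str], float]:
        """Length of the shared boundary for every rook-adjacent unit pair."""
        if self._shared is not None:
            return self._shared
        out: Dict[FrozenSet[str], float] = {}
        adj = self.adjacency("rook")
        for u, nbrs in adj.items():
            for v in nbrs:
                key = frozenset((u, v))
                if key not in out:
                    inter = self.geometry(u).intersection(self.geometry(v))
                    out[key] = inter.length
        self._shared = out
        return out

    # -- editing -----------------------------------------------------------
    def merge_unit_into(self, src: str, dst: str) -> "UnitGeography":
        """Union unit ``src`` into ``dst``; returns a new geography.

        The merged unit keeps ``dst``'s id and district; facility lists are
        concatenated.
        """
        if src == dst:
            raise ValueError("cannot merge a unit into itself")
        frame = self.frame.copy()
        merged_geom = shapely.union(frame.at[src, "geometry"], frame.at[dst, "geometry"])
        frame.at[dst, "geometry"] = merged_geom
        frame.at[dst, "facility_ids"] = tuple(frame.at[dst, "facility_ids"]) + tuple(
            frame.at[src, "facility_ids"]
        )
        frame = frame.drop(index=src)
        return UnitGeography(frame, validate=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover
        nd = self.frame["district_id"].nunique()
        nf = sum(len(f) for f in self.frame["facility_ids"])
        return f"UnitGeography({len(self)} units, {nd} districts, {nf} facilities)"
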