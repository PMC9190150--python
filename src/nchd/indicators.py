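"""Access-to-birthing-services indicators per areal unit.

For each zone (administrative district or delineated catchment district) the
module reports the resident population, the hospitals and CEmONC-ready
hospitals serving it, and the staffing/facility densities health planners
benchmark against WHO thresholds:

* 22.8 skilled health workers per 10,000 population (and the revised 33.45);
* five emergency obstetric care facilities per 500,000 population.

CEmONC (comprehensive emergency obstetric and newborn care) readiness is the
conjunction of nine signal functions performed in the last three months.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree

from .errors import NCHDError, SchemaError
from .flows import ZoneSystem
from .geography import UnitGeography

__all__ = [
    "SIGNAL_FUNCTIONS",
    "WHO_MIDWIVES_PER_10K",
    "WHO_MIDWIVES_PER_10K_REVISED",
    "WHO_EMOC_PER_500K",
    "FacilityAssessment",
    "PopulationSurface",
    "is_cemonc_ready",
    "cemonc_ready_series",
    "zonal_population",
    "compute_indicators",
]

#: The nine EmONC signal functions, in reporting order.
SIGNAL_FUNCTIONS = (
    "parenteral_antibiotics",
    "uterotonics",
    "parenteral_anticonvulsants",
    "manual_placenta_removal",
    "removal_retained_products",
    "assisted_vaginal_delivery",
    "neonatal_resuscitation",
    "caesarean_section",
    "blood_transfusion",
)

WHO_MIDWIVES_PER_10K = 22.8
WHO_MIDWIVES_PER_10K_REVISED = 33.45
WHO_EMOC_PER_500K = 5.0

SECTORS = ("government", "private", "faith-based")


@dataclass(frozen=True)
class FacilityAssessment:
    """Per-hospital staffing and EmONC signal-function survey record."""

    facility_id: str
    sector: str
    midwives: int
    signal_functions: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if self.midwives < 0:
            raise ValueError(f"negative midwife count for {self.facility_id}")
        if self.sector not in SECTORS:
            raise ValueError(f"unknown sector {self.sector!r} for {self.facility_id}")
        if set(self.signal_functions) != set(SIGNAL_FUNCTIONS):
            missing = set(SIGNAL_FUNCTIONS) - set(self.signal_functions)
            extra = set(self.signal_functions) - set(SIGNAL_FUNCTIONS)
            raise ValueError(
                f"facility {self.facility_id}: signal functions must be exactly the "
                f"nine EmONC functions (missing {sorted(missing)}, extra {sorted(extra)})"
            )


def is_cemonc_ready(a: FacilityAssessment) -> bool:
    """True iff all nine signal functions were performed (conjunction)."""
    return all(bool(a.signal_functions[s]) for s in SIGNAL_FUNCTIONS)


def cemonc_ready_series(facilities: pd.DataFrame) -> pd.Series:
    """Vectorised readiness over a facility table with the nine 0/1 columns."""
    missing = set(SIGNAL_FUNCTIONS) - set(facilities.columns)
    if missing:
        raise SchemaError(f"facility table missing signal-function columns: {sorted(missing)}")
    return facilities[list(SIGNAL_FUNCTIONS)].astype(bool).all(axis=1)


@dataclass
class PopulationSurface:
    """Regular grid of person counts on the units' planar CRS.

    ``values[r, c]`` is the population of the cell whose centre is
    ``(x0 + (c + 0.5) * cell_size, y0 + (r + 0.5) * cell_size)``; ``x0, y0``
    is the lower-left corner of the grid, ``cell_size`` in metres.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell_size: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("population grid must be 2-D")
        if (self.values < 0).any() or not np.isfinite(self.values).all():
            raise ValueError("population cells must be finite and non-negative")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def cell_centres(self):
        """(x, y, pop) arrays over all cells, row-major."""
        nr, nc = self.values.shape
        cx = self.x0 + (np.arange(nc) + 0.5) * self.cell_size
        cy = self.y0 + (np.arange(nr) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(cx, cy)
        return xx.ravel(), yy.ravel(), self.values.ravel()


def zonal_population(
    surface: PopulationSurface,
    zones: ZoneSystem,
    geo: UnitGeography,
) -> Dict[str, float]:
    """Population per zone by the cell-centre rule.

    Each grid cell's population goes to the zone whose polygon covers the
    cell centre (smallest unit id wins the measure-zero case of a centre on
    a shared boundary); cells outside every unit are ignored.
    """
    units = sorted(zones.assignment)
    missing = [u for u in units if u not in set(geo.unit_ids)]
    if missing:
        raise NCHDError(f"zone units missing from the geography: {missing}")
    geoms = [geo.geometry(u) for u in units]
    tree = STRtree(geoms)
    xs, ys, pops = surface.cell_centres()
    points = [Point(x, y) for x, y in zip(xs, ys)]
    cell_idx, unit_idx = tree.query(points, predicate="covered_by")
    # a centre on a shared edge matches two units: keep the smallest unit id
    order = np.lexsort((unit_idx, cell_idx))
    cell_idx, unit_idx = cell_idx[order], unit_idx[order]
    first = np.ones(len(cell_idx), dtype=bool)
    first[1:] = cell_idx[1:] != cell_idx[:-1]
    cell_idx, unit_idx = cell_idx[first], unit_idx[first]

    out = {z: 0.0 for z in zones.zone_ids}
    for ci, ui in zip(cell_idx, unit_idx):
        out[zones.assignment[units[ui]]] += pops[ci]
    return out


def compute_indicators(
    zones: ZoneSystem,
    facilities: Iterable[FacilityAssessment] | pd.DataFrame,
    facility_location: Mapping[str, str],
    population: Mapping[str, float],
    pregnancies: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Indicator table, one row per zone.

    Rates are count x scale / population; WHO benchmark flags are inclusive
    (a zone exactly at 22.8 midwives per 10,000 meets the threshold).  A
    zone with zero population is an error.  ``pregnancies`` optionally adds
    a CEmONC rate per 100,000 estimated pregnancies alongside the
    population-denominator rate.
    """
    if isinstance(facilities, pd.DataFrame):
        records = []
        for row in facilities.itertuples():
            records.append(
                FacilityAssessment(
                    facility_id=row.facility_id,
                    sector=row.sector,
                    midwives=int(row.midwives),
                    signal_functions={s: bool(getattr(row, s)) for s in SIGNAL_FUNCTIONS},
                )
            )
        facilities = records
    else:
        facilities = list(facilities)

    by_zone: Dict[str, list] = {z: [] for z in zones.zone_ids}
    for a in facilities:
        unit = facility_location.get(a.facility_id)
        if unit is None:
            raise NCHDError(f"facility {a.facility_id} has no location")
        zone = zones.assignment.get(unit)
        if zone is None:
            raise NCHDError(f"facility {a.facility_id} located in unassigned unit {unit}")
        by_zone[zone].append(a)

    rows = []
    for z in zones.zone_ids:
        pop = float(population.get(z, 0.0))
        if pop <= 0:
            raise NCHDError(f"zone {z} has zero population; rates are undefined")
        facs = by_zone[z]
        n_hosp = len(facs)
        n_cemonc = sum(is_cemonc_ready(a) for a in facs)
        midwives = sum(a.midwives for a in facs)
        mid_rate = 10_000.0 * midwives / pop
        row = {
            "zone_id": z,
            "population": pop,
            "n_hospitals": n_hosp,
            "n_cemonc": n_cemonc,
            "cemonc_per_100k": 100_000.0 * n_cemonc / pop,
            "midwives": midwives,
            "midwives_per_10k": mid_rate,
            "emoc_facilities_per_500k": 500_000.0 * n_hosp / pop,
            "meets_who_22_8": mid_rate >= WHO_MIDWIVES_PER_10K,
            "meets_who_33_45": mid_rate >= WHO_MIDWIVES_PER_10K_REVISED,
        }
        row["meets_emoc_5_per_500k"] = row["emoc_facilities_per_500k"] >= WHO_EMOC_PER_500K
        if pregnancies is not None:
            preg = float(pregnancies.get(z, 0.0))
            if preg <= 0:
                raise NCHDError(f"zone {z} has zero estimated pregnancies")
            row["cemonc_per_100k_pregnancies"] = 100_000.0 * n_cemonc / preg
        rows.append(row)
    return pd.DataFrame(rows).set_index("zone_id")
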