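import numpy as np
import pytest
from shapely.geometry import box

from nchd.flows import BipartiteFlows, FlowRecord
from nchd.geography import UnitGeography


def make_lattice(n_rows, n_cols, cell=1000.0, districts=None, facilities=None):
    """Box-lattice geography; ``districts`` maps cell index -> district id
    (default one district), ``facilities`` maps cell index -> facility ids."""
    units = []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            uid = f"U{k + 1:03d}"
            d = districts[k] if districts else "D01"
            f = facilities.get(k, ()) if facilities else ()
            units.append((uid, d, box(c * cell, r * cell, (c + 1) * cell, (r + 1) * cell), f))
            k += 1
    return UnitGeography.from_units(units)


def flows_from_dict(d):
    """{(origin, facility): count} -> BipartiteFlows."""
    return BipartiteFlows([FlowRecord(o, f, c) for (o, f), c in d.items()])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_zone_matrix():
    """The worked 2x2 example used across the self-containment and
    connectance tests: T = [[10, 5], [2, 20]]."""
    from nchd.flows import ZoneFlowMatrix

    return ZoneFlowMatrix(zone_ids=["Z1", "Z2"], T=np.array([[10, 5], [2, 20]]))
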