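# Methods

## Problem and approach

Administrative districts in Ghana (and many comparable settings) are not
drawn around hospitals: a district may contain no hospital at all, and the
population a hospital actually serves routinely crosses district lines.
Per-district health indicators computed on such boundaries divide the wrong
numerator by the wrong denominator. This package delineates *natural
catchment health districts* — zones in which most journeys to give birth
both start and end — directly from routine origin–destination birth flows,
by adapting the travel-to-work-area (TTWA) zone-design procedure used for
labour-market areas, and then computes emergency obstetric care access
indicators on the resulting zones.

## Data model

The unit of aggregation is the health *sub-district* (polygon, district
membership, contained hospitals). Flows are counts of women by
`(origin unit, destination hospital)`; community-level records are summed to
units, conserving totals exactly (integer arithmetic throughout the flow
pipeline). Sub-districts with no recorded births and no reporting facility
are first folded into a same-district rook neighbour — the one with the
longest shared boundary, or the nearest same-district unit by centroid
distance when no same-district neighbour exists; only units that do have
births are accepted as targets, so chains of birthless units resolve
deterministically.

Seed zones are one per hospital: every unit joins the zone of the hospital
receiving the plurality of its flows (ties to the smallest facility id). A
hospital that wins no unit co-anchors the zone its own host unit joined.
Crucially, assignment is *membership only*: observed flows are never
rewritten to the plurality destination, so cross-zone flows remain visible
to the merge loop. Rewriting them would make every seed zone perfectly
self-contained and the algorithm vacuous.

## The merge loop

Let `T` be the zone-by-zone matrix with `T[i, j]` the women resident in
zone *i* delivering in zone *j*. For zone *z*:

* supply-side self-containment `= T[z, z] / Σ_j T[z, j]` (share of
  journeys starting in *z* that stay);
* demand-side self-containment `= T[z, z] / Σ_i T[i, z]` (share of
  journeys ending in *z* that started there).

Each iteration: (1) find the zone minimising `min(demand, supply)`; (2) if
every zone clears the threshold (default **0.96**), stop; (3) otherwise
compute the connectance between the candidate *i* and every other zone *j*

```
C_ij = (T_ij / Σ_i T_ij)(T_ij / Σ_j T_ij) + (T_ji / Σ_i T_ji)(T_ji / Σ_j T_ji)
```

(symmetric, range [0, 2]); (4) merge the candidate into the argmax-`C`
partner. Zones are only ever merged, never dissolved. Termination is
guaranteed: the zone count falls by one per iteration and a single zone is
perfectly self-contained. The global internal-flow share is non-decreasing
along the trace, since a merge converts the merged pair's mutual flows into
internal flows and touches nothing else; the full audit trail (candidate,
its self-containment, partner, connectance, share after) is retained and
exportable.

### Numerical conventions

* A zone generating (or attracting) no trips has self-containment 1 —
  vacuously self-contained. Connectance terms with a zero denominator
  contribute 0. Both conventions avoid undefined arithmetic without
  privileging any merge.
* All ties — plurality destinations, least-self-contained candidates,
  best-connected partners, repair targets — break to the smallest
  identifier, making every run reproducible bit-for-bit.
* When every connectance from the candidate is zero (a zone exchanging no
  flows, like an isolated lakeside catchment), the partner falls back to
  the rook-adjacent zone with the longest shared boundary. An isolated zone
  already above threshold is simply never selected, so genuine isolation is
  preserved rather than force-merged.
* The matrix is collapsed incrementally on merge (add row/col); a test
  asserts equality with full re-tabulation from the raw flows.

### Contiguity repair

Plurality assignment can strand units: a sub-district whose women mostly
attend a distant hospital becomes an island inside another zone. After the
stopping rule is met, each zone is decomposed into connected components
under the configured adjacency (rook by default, queen optional). The
component holding the zone's anchor-hospital units is kept (largest
component if anchors are absent or split); every other component is
reassigned wholesale to the adjacent zone with the longest total shared
boundary, iterating until all zones are connected. Each reassignment welds
a fragment onto an existing component, so the procedure terminates. Repair
can perturb self-containment, so the package reports self-containment both
before and after repair and does not re-enter the merge loop; the stopping
guarantee applies to the pre-repair state.

## The comparable-zones control

To separate the effect of flow-guided merging from the mere effect of
scale, a deliberately simpler control starts from the same seed zones and
repeatedly merges the zone with the smallest *supply-side* self-containment
into its rook-adjacent neighbour with the smallest supply-side
self-containment, stopping at a target zone count (by default, the count
the main delineation produced on the same inputs). A suite test asserts the
tendency that at matched counts the main delineation attains at least the
control's mean global internal-flow share across 20 seeds; it is a
statistical tendency, not a per-seed guarantee.

## Access indicators

Per zone: population (gridded surface, each cell assigned to the zone
covering its centre — exactly testable against a brute-force
point-in-polygon loop; areal weighting is a possible later refinement),
hospitals, CEmONC-ready hospitals, CEmONC hospitals per 100,000 population,
midwives per 10,000 population, and EmOC facilities per 500,000. CEmONC
readiness is the conjunction of the nine EmONC signal functions performed
in the last three months. WHO benchmark flags use 22.8 and 33.45 skilled
workers per 10,000 and five EmOC facilities per 500,000; thresholds are
inclusive (a zone at exactly 22.8 meets the benchmark). Rates use total
population as the denominator; an estimated-pregnancies denominator is
exposed as an option since planning practice varies. Zero-population zones
are an error rather than an infinity.

## Synthetic scenarios

No birth-register data can ship with the package, so a generator produces
worlds with the statistical structure the method assumes, and every
end-to-end claim is demonstrated on them.

* **Geography**: a square lattice of 250 six-kilometre units walked in
  boustrophedon order and cut into 33 contiguous, balanced districts; 27
  hospitals in distinct units, at most two per district. Four communities
  per unit (~1,000 overall).
* **Births per community**: lognormal with `mu = ln 7`, `sigma = 1.6`,
  floored at one birth — median 7, interquartile range ≈ 2–21, mean ≈ 25,
  reproducing the right-skewed profile of routine birth registers where a
  few towns contribute hundreds of deliveries.
* **Destination choice**: a gravity (Huff) model — probability proportional
  to hospital attractiveness (uniform on 1–10) times travel
  distance^(−beta), beta = 5 — with multinomial draws per community.
* **Travel basins**: distances are shortest paths on the unit-adjacency
  graph, and edges crossing one of ~8 basin boundaries (grown from hospital
  units) cost 8× more. This emulates the lake- and ridge-type barriers that
  make real regions decompose into a handful of semi-isolated flow basins.
  Without it, a homogeneous gravity surface leaks between every adjacent
  catchment and the 96% rule merges everything into a single zone — a
  regime the real setting demonstrably does not occupy: the calibrated
  defaults give an initial internal-flow share of roughly 0.70–0.84 and
  delineations of about five to seven zones from 27 seed zones, matching
  the magnitudes reported for a real regional delineation (initial
  self-containment ≈ 70%, 27 hospitals merging to 11 zones). Setting
  `barrier_factor=1` recovers the homogeneous surface.
* **Bypass streams**: ~5% of communities route 80% of their births to the
  single most attractive hospital, with bypasser probability decaying with
  distance to it — a few strong long-range streams of the kind a border
  hospital draws from a neighbouring metropolis, rather than uniform
  leakage from everywhere (which would place a hard ceiling on every zone's
  self-containment).
* **Facilities**: midwife counts Poisson(20); ~70% of hospitals perform all
  nine signal functions, the rest fail one to three at random.
* **Population**: lognormal cell noise on a 2-km grid scaled to a regional
  total of 2.9 million.
* **Planted-partition mode**: units are split into *k* contiguous blocks by
  multi-source BFS from *k* hospital units; births deliver inside their
  block with probability `within_prob`, else at a uniform outside hospital.
  Ground-truth labels are returned for recovery experiments.

All randomness derives from one integer seed through named
`SeedSequence` spawns per stage, so identical configurations are
byte-identical end to end.

### What the generator does not emulate

Real road networks and travel times; the geocoding failure process
(unmatched place names are out of scope — unmapped communities are a hard
error); facility-level reporting gaps correlated with ownership sector;
seasonal variation; population gradients tied to settlement structure.
Passing tests therefore demonstrate the algorithm's correctness and its
behaviour under the assumed flow structure, not the fidelity of any
particular empirical delineation.

## Test and experiment sizes

Unit and property tests run on lattices up to 5×10 and matrices up to 10
zones with exhaustive brute-force oracles. End-to-end suites use the full
250-unit default world (stopping rule, monotonicity), 20 seeded replicates
for the planted-recovery experiment (3 blocks, `within_prob = 0.99`,
expecting exact recovery in at least 19 — small planted blocks can
legitimately fall just below the 96% criterion through stray-inflow noise,
the observed failure mode), 100 random matrices for merge-decision
equivalence, and 20 seeds for the scale-effect comparison. The whole suite
completes in well under a minute on a laptop-class core.

## Design choices

* **Estimator shape**: the delineators are scikit-learn-style estimators
  (`fit`, `labels_`, `get_params`) in the tradition of regionalisation
  libraries, with the algorithmic steps exposed as plain functions
  underneath.
* **Zone identity**: the absorbing zone keeps the partner's id; lineage is
  recoverable from the trace.
* **Adjacency**: rook by default (shared boundary of positive length),
  queen configurable.
* Whether a multi-hospital sub-district's women should be re-pointed at the
  plurality hospital inside `T` (not just for membership) is the main
  interpretive fork in the procedure; this implementation keeps observed
  flows intact, as re-pointing would erase the very cross-flows the
  self-containment criterion measures.

## Known limitations

* Contiguity repair is greedy and order-dependent (smallest zone id first);
  a global optimisation could trade boundary length against
  self-containment loss.
* The stopping rule guarantees zone-level self-containment only before
  repair; severely fragmented plurality assignments could in principle be
  degraded by repair (both values are reported).
* Zonal population uses the cell-centre rule; cells straddling zone
  borders are not split.
* The generator's lattice geometry cannot express coastline-type
  tessellation irregularities; adjacency-driven logic is unaffected, but
  boundary-length tie-break behaviour is less exercised than on real maps.
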