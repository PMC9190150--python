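# nchd — natural catchment health districts from birth flows

`nchd` delineates **health service areas** from routine origin–destination
birth-admission records: zones in which most journeys to give birth both
start and end. It adapts the travel-to-work-area (TTWA) zone-design
algorithm to patient flows between health sub-districts and hospitals, and
computes emergency obstetric care access indicators on the resulting zones.
It is written for health-systems researchers and health-GIS analysts
working with routine health-information-system data, where administrative
districts often contain no hospital and misstate the population a hospital
actually serves.

## The algorithm

Let `T[i, j]` be the number of women resident in zone *i* who delivered at
a hospital in zone *j*. For a zone *z*,

* supply-side self-containment = `T[z,z] / Σ_j T[z,j]`
* demand-side self-containment = `T[z,z] / Σ_i T[i,z]`

Starting from one zone per hospital (each sub-district joins the zone of
the hospital receiving the plurality of its flows), the algorithm
repeatedly finds the zone with the lowest `min(demand, supply)`
self-containment and merges it with its most strongly linked partner by the
connectance index

```
C_ij = (T_ij / Σ_i T_ij)(T_ij / Σ_j T_ij) + (T_ji / Σ_i T_ji)(T_ji / Σ_j T_ji)
```

until every zone reaches the 96% self-containment threshold. Zones are only
merged, never dissolved. A final automated pass repairs spatial contiguity
by reassigning detached fragments to the neighbouring zone with the longest
shared boundary. A simpler supply-side-only "comparable zones" control is
included to separate the effect of flow-guided merging from the effect of
scale. See `docs/methods.md` for the full model description.

Because real birth registers are restricted, the package ships a synthetic
scenario generator (gravity destination choice over travel basins, skewed
birth counts, bypass streams, gridded population, EmONC facility surveys)
that reproduces the statistical structure the method assumes; all examples
and tests run on it.

## Worked example

```python
from nchd import TTWADelineator, ScenarioConfig, generate_scenario
from nchd.flows import initial_zones, zone_flow_matrix

scenario = generate_scenario(ScenarioConfig(seed=42))  # 250 units, 27 hospitals
seeds = initial_zones(scenario.unit_flows, scenario.geography)
T0 = zone_flow_matrix(scenario.unit_flows, seeds, scenario.geography.facility_location)
print(seeds.n_zones, round(T0.internal_share(), 3))

model = TTWADelineator(threshold=0.96).fit(scenario.unit_flows, scenario.geography)
print(model.n_zones_, len(model.trace_))
print(round(min(s.minimum for s in model.self_containment_pre_repair_), 4))
```

prints

```
27 0.774
5 22
0.9615
```

27 hospital-seeded zones with an initial internal-flow share of 77.4% are
merged 22 times into 5 catchment districts; at the moment the loop stops,
the worst zone still keeps 96.15% of its journeys internal — the stopping
rule's guarantee. Indicators on the delineated zones:

```python
from nchd import compute_indicators, zonal_population

pop = zonal_population(scenario.population, model.zones_, model.geography_)
table = compute_indicators(model.zones_, scenario.facilities,
                           model.geography_.facility_location, pop)
print(table[["n_hospitals", "n_cemonc", "midwives_per_10k"]].round(2))
```

```
         n_hospitals  n_cemonc  midwives_per_10k
zone_id
H05                6         4              1.65
H06                9         3              1.70
H12                8         6              2.19
H19                3         2              2.66
H27                1         0              1.43
```

Every delineated zone contains at least one hospital by construction; here
one zone has no CEmONC-ready hospital and all fall far short of the WHO
benchmark of 22.8 midwives per 10,000 population (`meets_who_22_8` False).

The same pipeline is available from the shell:

```
nchd simulate --outdir sim --seed 42
nchd delineate --flows sim/flows.csv --units sim/units.geojson --outdir zones
nchd indicators --units sim/units.geojson --assignment zones/assignment.csv \
    --facilities sim/facilities.csv --population sim/population.csv --outdir ind
```

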