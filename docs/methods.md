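# Methods

## The travel-time cost model

Every edge of the transport network carries one traversal time per
applicable mode, `t = 60 · L / v(mode, road_type)` minutes, with `L` the
edge length in km on a planar projected grid and `v` a constant speed in
km/h. The default speeds are field-measured constants for the vehicles the
model covers:

| mode | paved | herringbone | unpaved | waterway |
|---|---|---|---|---|
| rickshaw / rickshaw-van | 8.05 | 8.55 | 7.10 | — |
| tempo | 12.64 | — | — | — |
| CNG | 20.40 | — | — | — |
| walk | 4.00 | 4.00 | 4.00 | — |
| boat | — | — | — | 8.00 |

Pairs not listed are undefined and raise rather than silently falling back.
Speeds are deterministic: congestion, boarding delays and dispatch waiting
are deliberately out of scope. A speed table can be overridden from a flat
`mode.road_type = kmh` config file.

Mode applicability per segment: waterways carry boats only; roads narrower
than 5 ft carry only pedestrians; wider roads carry rickshaws and
pedestrians plus any fixed-route vehicle service (tempo, CNG, nasiman)
running on that corridor. Point constraints modify the touched edge: a
single-pole bamboo bridge forces walking, a natural barrier blocks
vehicles.

The nasiman — an improvised motorised cart deemed unsafe for patient
transport — has no measured speed; the packaged catalog back-derives
12.63 km/h from the one catalogued nasiman corridor (8.34 km, 39.61 min).
Nasiman corridors receive travel times (so the catalog records them
honestly) but are never dispatched: they are catalogued inactive and their
villages reassigned.

Boat paths lengthen in the dry season when channels force indirect
crossings; no factor is quantified in the source material, so the model
exposes an optional per-waterway length multiplier with default 1.0 (i.e.
wet-season straight-line crossings) via the segment geometry itself.

## Network construction and routing

Road and waterway polylines are noded at shared endpoints and crossings
(`shapely.unary_union`, preceded by a welding pass that inserts T-junction
endpoints into their host polyline, since a projected junction point is off
the host line by float epsilon). Each noded piece inherits its parent
segment's attributes. Village centroids become vertices joined by walking
connectors to the nearest point of the network — splitting the host edge
when that point falls mid-edge — and a village farther than a configurable
maximum (default 5 km) is left unconnected with a warning.

Shortest paths minimise total minutes under a mode policy:

* `fastest_available` — fastest applicable mode per edge, unsafe modes
  excluded (used for village→pickup assignment);
* `rickshaw_only` — rickshaw on vehicle-passable roads, walking on sub-5-ft
  roads, boats on water (the zoning convention);
* a single mode.

Ties break on fewer edges, then the lexicographically smallest vertex-id
sequence, making every result bit-reproducible. Correctness is checked
against exhaustive simple-path enumeration on hundreds of random small
graphs.

Routing follows the fixed-route structure of the real service rather than
free-form per-village routing: each community-end hub anchors one route to
its globally nearest facility (so villages near a subdistrict border
naturally route to the neighbouring hospital), sub-hubs on the corridor
attach in travel order, and each village is assigned to the pick-up point
(hub or sub-hub of an active route) minimising travel time from the
village centre. "Proximity and physical accessibility" is operationalised
purely as minimum travel time; the villagers'-preference adjustments that
no algorithm can reproduce are exposed as a manual override table
(village → route) applied after automatic assignment. Villages known to
use an out-of-study hospital are consumed as an exclusion list before
assignment. Arrival estimates are additive: village→pickup time plus the
route's remaining corridor time.

## Zoning

Catchment zones band villages by rickshaw travel time to the nearest
facility: green ≤ 30 min, yellow 30–50 min (inclusive upper bounds), red
beyond 50. Rickshaws are the yardstick because they are the most common
and universally available vehicle.

Service polygons are realised as *network reach widened by off-network
walking*: every network point reachable in `t ≤ b` minutes contributes a
disc of radius `(b − t) × 4 km/h`, and each edge is truncated at the exact
distance coverable within the remaining budget (sampled every 0.15 km,
with a thin flat-capped ribbon preserving the exact on-road reach tip).
Because walking is the slowest mode, the polygon along a straight road
ends exactly at `v·b/60` km. Polygons for successive breaks are nested by
construction and multipart shapes arise naturally around islands.

Village labels are the contract, not polygon aesthetics: a village wholly
inside the 30-minute polygon is green, one not touching the 50-minute
polygon is red, and a village crossed by a boundary is assigned by area
share — the band covering ≥ 50% of the village wins; if no band reaches
50% the largest share wins, with exact ties going to the faster band (the
three-band straddle case is not specified by the source convention; the
largest-share rule is this package's choice). The zone summary reports
per-zone village counts, settlement areas, populations, and integer
percentages rounded half-up on the exact population share, so the percent
column sums to 100 ± 1.

## Referral analytics

The analytic atoms are referred calls with nested flags
(`used_transport ⇒ complied ⇒ referred`), a six-month semester derived
from the call date (Oct–Mar / Apr–Sep, matching the call centre's
operational window Oct 2013 – Sep 2015), and a zone inherited from the
caller's village. Calls whose village cannot be resolved are dropped
before tabulation with a logged count.

Conventions, fixed once:

* rates are percentages rounded half-up on the exact rational value — 1
  decimal generally, 0 decimals for the headline usage figure, 2 decimals
  for ratios;
* zone shares of compliance divide by the semester's total complied count
  *including* excluded-zone records;
* the red:yellow usage ratio divides raw usage counts;
* the usage trend compares per-semester usage rates as exact fractions.

Published compliance tables sometimes print marginal totals that disagree
with their own zone breakdown: in the packaged fixture the first
semester's zone rows sum to 121 transport uses against a printed semester
total of 123 (two records unattributable to any zone), and the zone
summary's printed grand total exceeds the sum of its own zone populations
by 306. A `ComplianceTable` therefore accepts explicit printed semester
margins: semester-level statistics use the margins (reproducing the
published 16.5% first-semester usage, the 2.27 last-vs-first usage ratio
and the 6.4-point first-to-second decline), zone-level statistics use the
zone counts (reproducing the published 6.56/3.83/4.27/6.57 red:yellow
ratios), and tables built from records always derive margins from the
data. Three published trend figures (a 3.70× and a 2.30× usage ratio and
two small zone-trend percentages) are not recoverable from the printed
counts under any denominator convention tried; the package reports the
values its own convention computes (3.69, 2.37, …) rather than forcing
the printed ones.

## The synthetic-data generator

`generate_scenario` emulates the *structure* of a two-subdistrict rural
study area, not any real geography: each subdistrict is a 14 × 14 km block
(~196 km², matching the order of real subdistrict areas) with one
hospital at its headquarters; villages are Voronoi cells around uniformly
drawn settlement seeds (a planar partition, so the 50%-coverage rule faces
genuine straddling geometry); village populations are lognormal with mean
1,300; fixed corridors radiate from the hospital to boundary markets
(70% paved with tempo/CNG service by default, one corridor nasiman-served
to exercise the exclusion rule); village access roads draw surface types
from a paved/herringbone/unpaved mix (45/25/30) with 15% narrower than
5 ft; and the first subdistrict has a river at one-third of its width
whose island villages connect to mainland ghats only by boat edges. The
default scale is a quarter of the real study (~84 villages) so the test
suite runs in seconds; `ScenarioConfig.paper_scale()` generates ~338
villages.

`generate_call_log` draws referral calls with zone-conditional Bernoulli
compliance and transport use. Defaults mirror the published table's
empirical rates: referral probability 0.565; compliance 0.77/0.72/0.69
for green/yellow/red; transport use 0.06 (yellow) and 0.30 (red), with
the green-zone probability structurally zero because the service did not
operate there; semester weights 0.39/0.28/0.25/0.08.

What passing tests on synthetic data do and do not show: they verify the
pipeline's invariants (population conservation, partition properties,
polygon containment, monotonicity in break values, parameter recovery
within 3 binomial standard errors) and the exact reproduction of the
published tables from their own printed counts. They do not validate the
speed constants against any new field data, nor the generator's geography
against real road networks — real inputs arrive through the same GeoJSON
readers and are subject to the same invariants.

## Numerical choices

* All geometry is planar in kilometres; lon/lat inputs are rejected, not
  silently projected, because the travel-time model's distances are ground
  distances. Any equal-distance projection is acceptable upstream.
* Endpoint snap tolerance 1e-6 km (1 mm); junction welding tolerance the
  same.
* Printed-table reproduction uses exact `Fraction` arithmetic up to the
  final half-up rounding, since binary floats misround half-way cases.
* Degenerate inputs raise typed errors (zero-area villages, empty
  reachable sets, undefined speed pairs, zero denominators) rather than
  returning sentinels.

## Known limitations

* No congestion, waiting or dispatch-delay modelling; travel times are
  lower bounds from constant speeds.
* Seasonal boat-path lengthening is representable but defaults to none.
* The zone label of a village that is unreachable by rickshaw/boat (a
  fully isolated island with no ghat) is red by construction, which
  conflates "far" with "unreachable".
* The largest-share tie rule for three-band straddles and the pick-up
  assignment of near-equal hub/sub-hub times are conventions; real
  deployments adjusted such cases by local consultation, which the manual
  override table represents but cannot predict.
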