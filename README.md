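# refnet

Travel-time modelling of rural emergency referral transport on multimodal
road/waterway networks: closest-facility routing from villages via transport
hubs, travel-time catchment zoning, and call-centre compliance analytics —
with seeded synthetic geography so the whole pipeline runs without any
external data.

## The problem

In many rural low-income settings, a patient with suspected sepsis reaches
the subdistrict hospital not by ambulance but by whatever local transport
exists: pedal rickshaws everywhere, shared tempo/CNG three-wheelers on fixed
paved corridors, wooden boats between river islands and landing ghats, and
walking on roads too narrow for vehicles. A referral call centre needs to
know, for every village, the nearest pick-up point, the route to the nearest
hospital, and how long the journey takes — and programme managers need to
know which villages are far enough away to warrant dispatched transport and
fare support.

`refnet` implements that analysis as a reusable library:

* **Travel-time cost model.** A speed table v(mode, road type) in km/h
  (rickshaw 8.05 / 8.55 / 7.10 on paved / herringbone / unpaved; tempo
  12.64 and CNG 20.40 on paved; walking 4.00 everywhere; boat 8.00 on
  water). A segment of length L km costs t = 60·L/v minutes; roads under
  5 ft wide are walk-only; a single-pole bamboo bridge forces walking and a
  natural barrier blocks vehicles.
* **Closest-facility routing.** Roads and waterways are noded into a
  weighted multimodal graph; every village centre gets a walking connector.
  Shortest paths minimise total minutes with a deterministic tie-break
  (fewer edges, then lexicographic vertex ids), so runs are bit-
  reproducible. Each community-end hub anchors one route to its nearest
  facility; villages are assigned to the quickest pick-up point of an
  active route; corridors served only by the patient-unsafe nasiman cart
  are catalogued but excluded from dispatch, with their villages reassigned.
* **Travel-time zoning.** Rickshaw-based service areas at 30- and
  50-minute breaks (green ≤ 30 < yellow ≤ 50 < red), realised as network
  reach widened by off-network walking discs. A village straddling a zone
  boundary goes to the band covering ≥ 50% of its area.
* **Referral analytics.** From a log of referral calls: compliance rate
  (complied/referred), dispatched-transport usage rate (used/complied),
  zone shares of compliance, red:yellow usage ratios, and the usage trend
  across six-month semesters — all rounded half-up on exact fractions.

## Worked example

Generate a synthetic two-subdistrict study area (one hospital each, fixed
tempo/CNG corridors radiating to boundary markets, a river isolating island
villages reachable only by boat) and run the geographic stages:

```
$ refnet simulate --seed 7 --out demo/geo
wrote scenario (84 villages) to demo/geo
$ refnet routes --geodata demo/geo --out demo/routes.csv
wrote 10 routes to demo/routes.csv
$ head -4 demo/routes.csv
route_id,route_name,mode,distance_km,time_min,catchment_population,active
01,Market 0-0 to Subdistrict 0 UHC,Tempo,4.33,20.53,6465,1
02,Market 0-1 to Subdistrict 0 UHC,CNG,6.50,19.13,13062,1
03,Market 0-2 to Subdistrict 0 UHC,Tempo,4.07,19.31,6015,1
```

Route 01 is a 4.33 km paved tempo corridor, hence 60·4.33/12.64 = 20.53
minutes, and 6,465 people live in the villages whose quickest pick-up point
lies on it. A nasiman-served corridor appears in the catalog with
`active=0` and an empty catchment — its villages are reassigned to nearby
routes, and total population is conserved across the catalog. Zoning the
same scenario:

```
$ refnet zones --geodata demo/geo --out demo/zones.csv --summary demo/table3.csv
$ cat demo/table3.csv
zone,n_villages,settlement_area_km2,population,population_pct
green,8,42.34,9406,8
yellow,28,112.68,37241,31
red,48,221.77,71917,61
total,84,376.79,118564,100
```

61% of this scenario's population lives beyond 50 rickshaw-minutes of a
hospital — the population the dispatched-transport service exists for.

The analytics layer ships the published call-centre compliance table as a
packaged fixture; running the statistics on it:

```python
>>> from refnet import table_fixtures, analyze
>>> stats = analyze(table_fixtures().compliance_table)
>>> stats["n_referred"], stats["compliance_pct"], stats["ipsi_usage_pct"]
(2731, 71.5, 16.0)
>>> stats["usage_ratio_red_yellow_S1"]
6.56
```

Of 2,731 referred calls, 71.5% complied with the referral advice and 16%
of compliant callers used the dispatched transport; in the first semester,
red-zone patients used it 6.56× as often as yellow-zone patients.

## Layout

* `refnet.geodata` — domain types (villages, road segments, hubs,
  facilities, constraints, call records) and GeoJSON/CSV I/O on a planar
  kilometre grid.
* `refnet.travel_time` — the speed table, the 5-ft accessibility rule, and
  segment/path times.
* `refnet.network_routing` — graph construction, deterministic shortest
  paths, route catalog, catchment assignment, arrival estimates.
* `refnet.zoning` — service-area polygons, the 50%-coverage rule, zone
  summaries.
* `refnet.referral_analytics` — compliance tabulation and derived rates.
* `refnet.synthetic_geography` — seeded scenario and call-log generators,
  plus the published-table fixtures.
* `refnet.pipeline` / `refnet.cli` — the end-to-end runner and the
  `refnet` command.

See `docs/methods.md` for the model's assumptions, parameter conventions
and known limitations.
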