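# Methods

## Problem and scope

`stationopt` places k health stations among n patient demand points so that
an aggregate accessibility objective is minimized.  All geometry is planar:
every layer (patients, stations, road network, bus stops, buildings) must
share one projected CRS in metres, chosen by the user; the package never
reprojects.  Capacity, specialization and staffing of stations are out of
scope — stations are interchangeable service points.

## Objectives

For a station set *HS*, each patient contributes the cost to the station
that minimizes that same cost, weighted by annual visits *w_p* (default 1,
i.e. per-visit optimization):

| kind               | per-pair cost            | units |
| ------------------ | ------------------------ | ----- |
| `euclidean`        | d_L2(p, h)               | m     |
| `squared_euclidean`| d_L2(p, h)²              | m²    |
| `travel_cost`      | rule-based visit cost    | EUR   |

The travel-cost model (defaults in `CostParams`):

* walk if the straight-line patient→station distance is under
  `walk_threshold` = 1000 m → 0 €;
* taxi if age ≥ `taxi_age` = 80 → `trips_per_visit × (5.90 € + 1.50 €/km)`;
* bus if the nearest bus stop is closer than `bus_stop_threshold` = 200 m →
  flat `trips_per_visit × 5.10 €` (no fare zones);
* car otherwise → `trips_per_visit × 0.25 €/km`.

Distance-proportional parts use the overhead-graph travel estimate; the
walk and bus-stop threshold tests use straight-line distances (the rules
describe residence geography, not routes).  `trips_per_visit` defaults to 2
so a "visit" is a round trip.  Rule precedence is configurable and defaults
to walk > taxi > bus > car; walking first keeps a near-station 80-year-old
at 0 €, which matches reading the walk rule as a statement about residence
distance only.  The patient's own time is deliberately not priced, and the
car/taxi tariffs are explicit configuration values in the Finnish range,
not claims about any particular published tariff table.

Because the bus fare is flat and walking is free, many stations tie exactly
under the travel-cost objective.  Assignment therefore breaks cost ties by
the smaller estimated travel distance, then by lowest station index.  A
pure lowest-index rule would pile all bus riders onto station 0 — a
degenerate artifact, not a modelling choice.  Under the two geometric
objectives exact ties are broken by lowest index.

## Road network and travel estimation

The road graph is undirected; each edge carries a length (validated to be
at least the straight-line chord between its endpoints) and an average
speed.  Exact travel distance is Dijkstra over edge lengths; travel time is
accumulated along the *length*-optimal path (distance is primary, time is
derived).  Off-network points snap to the nearest graph node with no
access-leg penalty, identically for patients and stations, so the omitted
leg cancels in comparisons.  One-way streets and rush-hour dynamics are out
of scope.

The overhead graph makes the optimizer tractable.  K anchor nodes are
chosen by clustering patient locations (squared-Euclidean random swap,
fixed seed, 500 trials) and snapping the centroids to road nodes — anchors
end up dense exactly where queries originate.  For every anchor pair the
*detour ratio* (network distance / straight-line distance; ≥ 1 by the
chord invariant) and the effective speed (path distance / path time, a
harmonic mean over segments) are precomputed with multi-source Dijkstra.
A query scans for each endpoint's nearest anchor (O(K), cached for the
static patients) and multiplies.  Defaults: K = 256; anchor pairs closer
than ε = 1 m get ratio 1 to avoid division blow-up; disconnected pairs are
flagged and surface as errors rather than silent infinities.  On a plain
grid the ratio approaches the Manhattan diagonal √2; removed "lake" cells
push it locally higher, which is the regime where one global detour factor
(the classic 1.4) fails.

## Optimizer

Random swap wraps k-means:

1. initialize with k distinct patient locations (seeded draw);
2. polish with two k-means iterations (assign → weighted-mean centroid);
3. for T = 5000 trials: replace one uniformly chosen station with a
   uniformly chosen patient location, run two k-means iterations, accept
   iff the objective strictly decreases (ties rejected, so the accepted
   cost sequence strictly decreases);
4. report the final stations, assignment and a from-scratch recomputed
   cost; everything is bit-reproducible from the seed.

Design choices where the design was genuinely open:

* **Swap target = a patient location.**  Guarantees trial stations land
  where demand exists; standard random-swap practice.
* **Arithmetic-mean centroids for every objective**, including travel cost,
  where the mean is not the cost-minimizing point.  A local search around
  the centroid could do better at a large runtime cost; instead stations
  can be snapped to the nearest existing building once, after optimization,
  which also keeps them off lakes.
* **Empty-cluster repair:** a station whose cluster empties is relocated to
  the patient currently farthest (most costly under the active metric)
  from its assigned station; without repair k silently shrinks.
* **Two k-means iterations per trial** — enough to let a swap settle while
  keeping trials cheap.

Cluster-level quality is the centroid index (CI): map each found station to
its nearest ground-truth hub and count orphaned hubs.  CI = 0 means every
hub was detected.  The mapping is one-directional (found → truth); with
duplicate truth centres a zero CI is unattainable by construction, so truth
sets are expected to be distinct points.

## Synthetic regions

The generator emulates the data regime the method targets, not any real
geography.  Defaults: 100 × 100 km; 15 hubs with one dominant "city"
holding 40% of the 9,333 patients, the rest spread equally (Gaussian scatter,
sd 2 km, hubs ≥ max(3 grid pitches, 5 sd) apart); ages truncated-normal
(mean 67, sd 12, min 18) topped up to ≥ 15% aged 80+ (drives the taxi
share); annual visits Gamma with mean 4.7 (the weight column); a 5 km grid
road lattice (441 nodes) with 12% of non-hub nodes removed as lakes and
re-linked bridges if the graph disconnects; major roads are the rows and
columns through hubs (80 km/h vs 50 km/h; edges meander up to 3% above the
chord); bus stops every 800 m along major roads plus one per hub; 40
buildings per hub plus rural scatter; and a 23-station "administrative"
baseline (one station per hub regardless of size, extras spread by
population) for before/after comparisons.

What the generator does *not* emulate: real road topology and density (a
regular lattice with a few hundred nodes is far simpler than an OSM
extract — many demand points snap onto anchor nodes, so estimator errors
here are optimistic), address-level geocoding noise, station capacities,
and municipal-border allocation constraints.  Passing tests therefore show
algorithmic correctness and qualitative behaviour, not calibrated regional
forecasts; absolute distances and euro totals scale with the synthetic
geography, which is more compact than a real province.

## Numerical choices

* Assignment argmin uses the expanded  −2·P·Sᵀ + |s|²  form (the |p|² term
  is constant per row); the cost of the *selected* pair is recomputed from
  coordinate differences so reported costs carry no cancellation error.
* `Solution.cost` always equals a from-scratch `total_cost` recomputation;
  a test guards this.
* Overhead matrices are symmetrized with an element-wise minimum before
  ratios are formed.
* Degenerate inputs fail loudly: duplicate ids, edges shorter than their
  chord, self-loops, k exceeding the number of distinct patient locations,
  empty building/bus-stop layers where a rule needs them.

## Problem sizes used in the checks

Unit and property tests run on hand-sized instances and small regions
(hundreds of patients, ≤ 100 road nodes).  The estimator-accuracy and
robustness checks run at the full default conditions (9,333 patients,
K ∈ {16, 64, 256}, 1,000 query pairs; 20 seeded optimizer runs at
T = 5000).  The end-to-end determinism check runs the four CLI stages twice
on a 400-patient region, which exercises every pipeline stage byte-for-byte.
`scripts/acceptance.py` runs the full default conditions (k = 23,
T = 5000, K = 256) for all three objectives in one pass.

## Known limitations

* Travel times inherit the length-optimal-path convention; a faster but
  longer route is never chosen.
* The flat bus fare makes bus riders' assignment distance-tie-broken rather
  than cost-driven; with zoned fares the objective would discriminate more.
* Anchor quality depends on the demand clustering; pathological demand
  (e.g. all patients on one spot) degenerates the anchor set.
* The building snap is a single post-processing projection; it can slightly
  worsen the objective and is not re-optimized.
* With k much larger than the number of demand hubs, surplus stations
  subdivide dense hubs; the objectives provide no incentive to keep them
  apart from one another.
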