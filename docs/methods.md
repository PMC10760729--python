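# Methods

## Problem setting

The package models urban hospital accessibility on a road network.  Demand is
a set of population districts, each reduced to a single weighted point snapped
to its nearest network node; supply is a set of hospital sites with bed
counts.  Impedance between a district and a hospital is the shortest-path
travel time in hours, with edge time = length_km / speed_kmh.  Two analyses
share this substrate: a raster overlay that scores how well locations are
served, and a discrete location-allocation optimisation that assigns
districts to hospitals under an impedance cut-off.

Representing a district by one point is a modelling choice: allocation
operates on whole districts, so polygon geometry adds nothing to the
mathematics.  Coordinates are planar kilometres; no projection handling is
attempted or needed at this scale.

## Density surfaces and the fuzzy overlay

Bed and population densities are planar kernel-density estimates with the
quartic (biweight) kernel, `K(d) = (3/πh²)(1 − (d/h)²)²` for `d < h` and 0
beyond.  The kernel integrates to one, so cell value × cell area sums to the
total weight whenever a point's support disc lies inside the grid; mass near
the boundary partially falls outside and no edge correction is applied — this
is documented behaviour, acceptable because conclusions are drawn from the
interior of the study area.

Parameters:

* **bandwidth h (km)** — the search radius.  Default: one sixth of the
  shorter grid extent, chosen so a ~40 km city gets visible smoothing
  (~6–7 km) while structure survives; always overridable because the right
  bandwidth is an analyst's judgement, not a statistic of the data here.
* **cell size (km)** — default 0.5, a desk-scale grid (~80×80 cells for a
  40 km city).  Mass-conservation accuracy is limited by cell size; at
  cell ≤ h/100 the discretisation error is below 0.5 %.

Both rasters are rescaled to fuzzy memberships with a clamped linear map.
Anchor defaults are the 5th/95th percentiles of each raster — robust to the
long upper tail a KDE surface has around isolated large hospitals.  The
overlay operators are the standard fuzzy family (cellwise min, max, product,
algebraic sum, and the gamma blend `SUM^γ·PRODUCT^(1−γ)`).  The
provider-to-population score is the **AND (minimum)** of the bed and
population memberships: a cell counts as well served only when both supply
and demand memberships are high.  We implement AND as the minimum — the only
reading consistent with "all inputs must be high for a high output", even
though the operator is sometimes loosely described as taking a value "from
all inputs".  One known ambiguity is inherited by design: cells with low
population and low bed density also score low, so the under-served mask
(default threshold 0.33 on a unit scale; the source analysis is qualitative,
and a lower-third cut is the natural reading of its red/green rendering)
should be read alongside population before siting anything there.

## Travel-time matrices

Shortest paths use Dijkstra's algorithm (non-negative edge weights) from each
facility's snapped node; with ~5 facilities and ~110 districts this is the
cheap direction.  Edges are undirected — no one-way streets, congestion or
time-of-day effects.  The walk from a point to its snapped node is treated as
zero cost, consistent with allocating whole districts via the network.
Disconnected pairs are UNREACHABLE (+inf).  A cut-off never alters finite
times; it only masks entries above it.  The default cut-off grid is
0.5–6.0 h in 0.5 h steps.  A 6 h in-city drive cut-off is generous to the
point of oddity, but it is the configured reporting convention this analysis
mirrors, and the package treats it as configuration, not physics.

## Location-allocation

**P-Median.**  Minimise `Σ w_i · min_{j∈S} d_ij` over `|S| = p`.  Demands
beyond the cut-off from every chosen site are UNALLOCATED and excluded from
the sum rather than infinitely penalised: that keeps them visible to the
second optimisation stage instead of distorting the objective.  Demand
weights default to district population; a unit-weight mode
(`--unit-demand-weights`) reproduces unweighted allocation where every
district counts equally.  Note the excluded-demand convention makes the
objective non-monotone in coverage; the exact solver therefore *defines* the
optimum by exhaustive enumeration over all `C(n, p)` site sets, guarded to
10⁶ subsets.  Above the guard, exact mode refuses with an explicit size
error rather than silently switching to a formulation (an ILP would need
closest-assignment constraints to preserve these semantics, machinery that
buys nothing at the scales this package targets); the Teitz–Bart
vertex-substitution heuristic with seeded multi-restarts serves large
instances and, on every instance small enough to enumerate, is validated to
match the enumeration optimum ≥95 % of the time and never to beat it.

**MCLP.**  Maximise covered weight `Σ w_i y_i`, `y_i = 1` iff some chosen
site is within the cut-off.  Exact mode enumerates below the same guard and
otherwise solves the standard ILP (binary open/covered variables,
`z_i ≤ Σ_{j: d_ij≤T} y_j`, `Σ y_j = p`) with HiGHS; the greedy heuristic adds
the site with maximal marginal covered weight and carries the classic
`1 − 1/e` guarantee, asserted in tests on every instance.

**MC-P-Median.**  Stage 1 runs the P-Median at the cut-off.  Stage 2 flags
demands that *no candidate site* can reach within the cut-off — the
"inaccessible or redundant" demand — and removes them.  Stage 3 re-solves
MCLP on the remainder and assigns every surviving demand to its nearest
chosen site.  An audit log records each removal, each assignment change
between stages, and any demand the chosen set still cannot cover (possible
only when p is smaller than the candidate count; with all sites open the
final allocation partitions exactly into allocated + inaccessible).
"Redundant" is implemented as cutoff-inaccessible: it is the only precise
reading available, and the audit trail preserves the raw facts for anyone who
wants a different one.

Tie-breaking is deterministic throughout: among equal-objective site sets the
lexicographically smallest facility-id set wins; assignments go to the
nearest site, lowest id on exact ties.

## Coverage reporting

For an allocation, the table counts, per facility and per cut-off, the
facility's allocated districts with assigned travel time within the cut-off
(cumulative, hence row-monotone, ending at the facility's allocated count).
Cumulative percentages and facility shares are rounded **half-up** to two
decimals, matching how such tables are conventionally rendered (20/94 →
21.28).  Only allocated districts enter the table; inaccessible ones are
reported separately in the run manifest, so the final column is exactly
100.0 whenever anything is allocated.  `table_from_count_rows` inverts a
printed table: it reconstructs the minimal allocation consistent with given
cumulative rows and recomputes all derived figures, which is how the
published five-hospital report is validated in the tests and acceptance
script.

## The synthetic-city generator

The generator emulates the structure, not the geography, of a large rapidly
urbanising city: ~110 districts summing to 3.4 million people, five hospitals
with 109–900 beds, a connected planar-ish road graph (Delaunay candidates,
shortest-first selection on top of an MST, target mean degree 3) in a 40 km
square.  Edge speeds default to 20–60 km/h, a realistic urban range that
spreads travel times across the lower cut-offs.  District locations mix a
Gaussian "downtown" blob (60 % of districts) with uniform scatter, giving the
centre-weighted density gradient real cities show; populations are Dirichlet
shares (concentration 5) of the total, floored to integers with the residual
assigned to the largest district so the total is conserved exactly.  The
`n_remote` option attaches a chain of nodes behind a single slow access edge
(default 8 h) and relocates that many districts there — a controlled stand-in
for an inaccessible periphery, used to exercise the inaccessible-demand path
of the optimiser with a known answer (e.g. 110 districts, 16 remote → 94
allocated).

What the generator does **not** emulate: real street topology (grids,
arterials), one-way systems, district polygon shapes, correlation between
population and bed placement, or any actual city's geography.  Passing tests
on synthetic cities therefore validate the algorithms and their invariants,
not any claim about a particular real city.

## Numerical choices and degenerate inputs

* Objective comparisons use a 1e-12 tolerance; "equal" site sets then
  tie-break lexicographically.
* A flat raster (all cells equal) makes percentile anchors degenerate; the
  membership map falls back to an all-or-nothing anchor rather than dividing
  by zero.
* Zero-weight points contribute nothing to densities and coverage but remain
  valid inputs; zero-bed facilities yield all-zero bed rasters.
* Networks of 2–3 nodes skip Delaunay (undefined) and use the complete graph.
* Populations are conserved exactly by integer residual assignment, so
  totals in reports are never off by rounding.

## Problem sizes

Default test and acceptance runs use cities of 150–200 network nodes, 60–110
districts and 5–8 candidate sites, solver batches of up to 1,000 random
instances with ≤8 candidates and ≤25 demands, and 50 seeded cities × 100
random site sets for the dominance check — sizes at which exhaustive
enumeration remains a trustworthy oracle while the full suite stays fast.

## Known limitations

* No capacity constraints: a hospital can be assigned any number of
  districts regardless of beds (bed counts inform the density overlay only).
* Only two of the classical location-allocation problem classes (minimise
  impedance, maximise coverage) are implemented.
* No boundary correction in the KDE; no adaptive bandwidths; no line-feature
  kernels.
* The fuzzy under-served mask conflates "under-served" with "unpopulated";
  filter by population before acting on it.
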