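# hospisite

Where should a growing city put its hospitals, and how well do the existing
ones cover its districts?  `hospisite` is a Python toolkit for answering both
questions on a road network:

* **Suitability mapping** — kernel-density surfaces of hospital beds (supply)
  and population (demand) are rescaled to fuzzy memberships and combined with
  a fuzzy-overlay operator; low provider-to-population scores flag
  under-served areas.
* **Location-allocation** — P-Median and maximal-covering (MCLP) solvers over
  a shortest-path travel-time matrix, plus a staged **MC-P-Median** optimiser
  that removes demand no site can reach within the impedance cut-off and
  re-solves coverage on the remainder.
* **Coverage reporting** — per-facility cumulative reachable-district counts
  across a grid of travel-time cut-offs, with facility shares and cumulative
  percentages.

A seeded synthetic-city generator (connected road graph, ~110 weighted demand
districts, a handful of hospitals with 109–900 beds) provides reproducible
inputs at the scale of a large metropolis, read and written as GeoJSON/CSV.

## The models

Given demand points `i` with weights `w_i`, candidate sites `j`, and
shortest-path travel times `d_ij` (hours) on the road network:

* **P-Median**: choose `S`, `|S| = p`, minimising
  `Σ_i w_i · min_{j∈S} d_ij`; demands with `min_{j∈S} d_ij > T` (the
  impedance cut-off) stay unallocated and are excluded from the sum.
* **MCLP**: choose `S`, `|S| = p`, maximising `Σ_i w_i · y_i` where
  `y_i = 1` iff some `j ∈ S` has `d_ij ≤ T`.
* **MC-P-Median**: P-Median at cut-off `T` → remove demands with
  `min_j d_ij > T` over *all* candidates ("inaccessible or redundant") →
  MCLP re-solve on the remainder, assigning each surviving demand to its
  nearest chosen site.  Every removal and reassignment is audit-logged.

Density surfaces use the quartic (biweight) kernel
`K(d) = (3/πh²)(1 − (d/h)²)²` for `d < h`, which integrates to one, so the
raster integral conserves total beds / population away from grid edges.
Fuzzy AND is the cellwise minimum: a location is well served only if bed
density **and** population density are both high there.

Exact solving is exhaustive enumeration under a subset-count guard
(enumeration doubles as the test oracle); the P-Median also ships a
Teitz–Bart vertex-substitution heuristic for large instances and the MCLP an
ILP path (HiGHS).  Solvers are scikit-learn-style estimators (`PMedian`,
`MaxCoveringLocation`, `MCPMedian`, `QuarticKernelDensity`) with functional
wrappers.

## Worked example

```python
import hospisite as hs

city = hs.generate_city(n_nodes=200, n_districts=110, n_facilities=5,
                        n_remote=16, seed=11)
od = hs.od_matrix(city.network, city.demands, city.facilities, cutoff_h=6.0)
weights = {d.demand_id: float(d.population) for d in city.demands}

result = hs.mc_p_median_optimize(od, weights, p=5, cutoff_h=6.0)
print("allocated:", result.final.allocated_count,
      "inaccessible:", len(result.inaccessible))

table = hs.coverage_table(result.final, od, hs.default_cutoffs())
print("shares:", dict(sorted(table.share_pct.items())))
print("cumulative %:", table.cumulative_pct)
```

prints

```
allocated: 94 inaccessible: 16
shares: {0: 1.06, 1: 26.6, 2: 24.47, 3: 5.32, 4: 42.55}
cumulative %: [56.38, 96.81, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0]
```

The city was generated with 16 districts attached behind a slow access road,
so the optimiser allocates the remaining 94 and flags exactly those 16 as
inaccessible at the 6 h cut-off.  The shares are each hospital's percentage
of the 94 allocated districts; the cumulative row says 56.38 % of allocated
districts are within 0.5 h of their assigned hospital and all of them within
1.5 h (this compact synthetic city is fully traversable much faster than the
6 h cut-off).

The same flow is available from the shell:

```bash
hospisite generate --n-districts 110 --n-remote 16 --seed 11 --out city/
hospisite allocate --city city/ --cutoff 6.0 --out alloc.csv
hospisite report --city city/ --allocation alloc.csv --out coverage.csv
hospisite run --config pipeline.yaml --out artifacts/   # full pipeline
```

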