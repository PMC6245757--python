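# Methods

## Model

`nichebox` implements a climate-envelope suitability model.  The fitted
object is an *envelope profile*: per-variable occurrence ranges in
native units, an allowed soil-class set, and a set of cluster *scopes*
in normalized units.

**Normalization.** Each environmental layer is mapped linearly onto
[0, 100] using the layer's own minimum and maximum over valid (non-
nodata) cells.  Layer statistics, not occurrence statistics, define the
mapping, so occurrence values can legitimately normalize outside
[0, 100]; they extrapolate linearly and are never clipped.  Constant
layers are rejected at fit time.

**Range-based clustering.** Occurrence climate vectors are partitioned
by an alternating scheme: each point is assigned to the cluster whose
scope (per-variable [min, max] rectangle) it is nearest to, then scopes
are recomputed from the new memberships.  The per-variable distance is
0 inside the range and the gap to the nearer edge outside; per-variable
components aggregate as the Euclidean norm (an L1 or max aggregate
would be a one-line swap).  The objective is the sum of squared member
distances to their own scope.  Because the update step recomputes each
scope as its members' min/max, every member lies inside its own scope
at convergence and the converged objective is identically zero for any
partition; the objective is still reported, recomputable by brute
force, and non-increasing across iterations (the `history` field of a
`ClusterSet` exposes the trace).  Empty clusters are re-seeded from the
point currently farthest from its assigned scope; assignment ties break
toward the lowest cluster index; `restarts` seeded initialisations
(default 10, seeds `seed..seed+9`) are run and the lowest final
objective kept.

The default is k = 1 — a single rectangular envelope, equivalent to the
classic BIOCLIM inclusion test, which is what per-species range tables
report.  Multi-cluster mode exists for species whose climate niche is
disjoint; k is a user choice, not estimated.

**Suitability surface.** Every valid cell's normalized climate vector
gets the minimum distance to any cluster scope.  The continuous
suitability is `s = 0.999·exp(−D/σ)` with σ the median positive
distance over valid cells (fallback 1 when every cell has distance 0).
The exponential shape is a presentational choice: the model's
substantive output — the binary suitable mask, which drives all area
accounting — depends only on `D = 0` and the soil rule, not on the
shape of the decay.  Cells whose soil class was not observed at any
occurrence get suitability 0 and are excluded from the mask.

**Area accounting.** Cell areas on the WGS84 sphere use
`A = R²·Δλ·(sin φ_N − sin φ_S)`, R = 6371.0088 km (IUGG mean radius),
exact per cell and summing to 4πR² over the globe.  All computation
stays in geographic lon/lat; no projection step is needed or wanted for
a global mosaic.  A suitable cell is attributed to the country polygon
containing its centre (half-open cell ownership: a point on a shared
edge belongs to the cell to its south-east); continents aggregate their
countries; centres in no region accumulate in an "unassigned" row.
Cell-centre attribution is exactly testable but carries boundary error
of order perimeter × cell size; halving the cell size moves smooth-
boundary region areas by well under 2%.

**Jackknife variable importance.** The occurrence set is split 75/25
(seeded shuffle, train size `round(0.75·n)`).  For each variable a
profile is fitted on the training rows with only that variable and with
all variables but that one, alongside the full model.  A model's score
is its *discrimination*: the fraction of test occurrences at envelope
distance 0 minus the fraction of background cells (valid grid cells,
optionally subsampled) at distance 0.  Test inclusion alone cannot rank
variables — removing a variable can only relax a rectangular envelope,
so inclusion never drops — whereas removing a constraining variable
admits much more background and lowers discrimination.  The
contribution of a variable is `max(0, score(all) − score(without))`,
floored at zero because sampling noise can produce small negative
drops, then normalized to sum to 100%.  Variables constant on the
training rows would create zero-width envelope slabs that zero every
model's background inclusion, so they are excluded from the fitted
models, warned about, and assigned contribution 0.

**Phylogenetics.** K2P distance
`d = −½·ln[(1 − 2P − Q)·√(1 − 2Q)]` with P and Q the transition and
transversion proportions over sites where both sequences carry plain
A/C/G/T (pairwise deletion; listwise deletion would discard more data
and is not offered).  Arguments ≤ 0 raise a saturation error rather
than returning NaN.  Neighbor-joining uses the Q-criterion with
Studier–Keppler updates; Q-ties break toward the lowest (i, j) pair in
current order; negative intermediate branch lengths are clamped to zero
with the deficit moved to the sister edge, preserving the pair's path
length.  The final three lineages join at a trifurcating root via the
three-point formulas, so the tree is unrooted.  Bootstrap supports
resample alignment columns with replacement, rebuild K2P + NJ per
replicate, and score each internal edge of the full-data tree by the
percentage of usable replicates containing the same bipartition
(bipartition identity, not node identity; replicates that hit
saturation are dropped and counted).  Concatenated multi-gene
alignments are analysed as one matrix.

## The synthetic generator

Scenes emulate the study system end to end.  Climate fields are linear
spatial gradients (per-variable direction and range; defaults bracket
the envelope ranges reported for temperate-to-subtropical tuber crops)
plus optional independent Gaussian noise per cell — linear gradients
make the true envelope's spatial footprint analytically locatable.  The
soil map is a seeded Voronoi mosaic (contiguous patches, like real soil
maps).  Regions are two rectangular "continents" of two "countries"
each.  Occurrences are placed at centres of cells drawn from the true
envelope's footprint by cycling random permutations of the suitable
cells: marginally uniform, and guaranteeing that a sample at least as
large as the footprint covers it completely, so a noise-free scene pins
the fitted envelope exactly.  Detection noise re-draws a fraction of
occurrences uniformly over the whole grid (a simple mis-georeferencing
model).  A truth whose footprint is empty on the generated grid raises
an error naming the most constraining factor.

What the generator does *not* emulate: spatially autocorrelated
sampling bias, climate physics (no covariance structure between
variables beyond shared gradients), fragmented coastlines, or realistic
soil-class frequencies.  Passing tests therefore demonstrate
correctness of the algorithms under known truth, not predictive skill
on real occurrence data.

Sequence simulation evolves a uniform random root sequence down a given
tree under the two-parameter substitution process with
transition/transversion rate ratio κ (= α/β, default 2), rates scaled
so one unit of branch length is one expected substitution per site;
the expected K2P estimate between two leaves then equals their path
length.  Branch lengths of zero are allowed (no change); negative
lengths are errors.

## Numerical choices and defaults

| Parameter | Default | Why |
|---|---|---|
| k (clusters per species) | 1 | reproduces single-range envelope tables; k>1 available for disjoint niches |
| restarts | 10 | cheap insurance against bad initial scopes |
| convergence tol on E | 1e-9 | E is exactly recomputable; tight tolerance is free |
| train fraction | 0.75 | standard 75/25 protocol |
| suitability decay σ | median positive distance | scale-free; endpoints 0.999 at D=0 and →0 fixed |
| Earth radius | 6371.0088 km | IUGG mean radius |
| grid co-registration tol | 1e-9 degrees | rasters must be pre-aligned; no resampling |
| scene grid / n | 40×40, 200 occurrences | small enough for exhaustive per-cell oracles, large enough to pin the envelope |
| bootstrap replicates | 1000 (CLI), 200 in checks | supports stabilise well below 1000 on the simulated trees used |

Degenerate inputs: a single occurrence yields a valid profile with
min = max ranges; nodata propagates through every surface; occurrence
rows outside the raster or on nodata cells are flagged, counted and
excluded from modelling; exact-duplicate (species, lon, lat) records
are dropped on read (cell-level thinning exists but is off by default,
since deduplication of exact replicates is the documented protocol).

## Known limitations

- The envelope model has no notion of occurrence density: one outlying
  record extends a range as much as a hundred records.  Real workflows
  should clean outliers before fitting.
- Cell-centre region attribution misassigns border cells; at coarse
  grids this can move small-country areas by a few percent.
- The jackknife discrimination score depends on the background extent;
  contributions are comparable within one study region, not across
  regions.
- NJ is a point estimate; only bootstrap supports quantify uncertainty,
  and saturated replicates are silently (but countedly) dropped.
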