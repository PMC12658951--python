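# Methods

This note documents the models implemented in `seaconn`, the conventions
chosen where the method leaves room, and what the synthetic test
scenarios do and do not establish.

## Connectivity model

Habitat for each species is a raster of suitability classes
s_i ∈ {0, 0.5, 1} on a shared grid (default 250 m cells). Every cell
with s_i > 0 is a node. The connectivity export from habitat cell *i*
to habitat cell *j* is a negative-exponential dispersal kernel of the
least-cost water distance d_ij:

    k_ij = s_i · exp( −d_ij / (α · d_max) )   for d_ij ≤ d_max
    k_ij = 0                                  for d_ij > d_max

* **α (kernel steepness), default 0.3** — dimensionless. At α = 0.3 the
  kernel falls to exp(−1/0.3) ≈ 3.6% of its origin value at d_max, a
  moderately steep decline matching fish that usually move short
  distances but occasionally travel far.
* **d_max (maximum dispersal distance), metres** — species-specific;
  the kernel is exactly zero beyond it, so pairs farther apart are not
  stored at all.
* Habitat quality scales *exports only* (rows of the matrix). With
  uniform quality the matrix is symmetric; with varying quality it is
  the uniform-quality matrix with row i multiplied by s_i.

The diagonal is zero: exports are flows to *other* habitat cells, and
no self-retention term is added before powering. This is a modelling
choice with consequences at g ≥ 2 (multi-generation paths cannot
"wait" in place; on a bare two-ended chain, walks between the ends have
fixed parity).

**Generational connectivity** over g dispersal events is the matrix
power K^g (default g = 3). Powers capture stepping-stone routes: cells
beyond d_max of each other gain positive entries when a chain of
intermediate habitats connects them. Per-cell **exports** are row sums
of K^g, **imports** are column sums.

## Least-cost water distances

Land is impassable. Water cells form an 8-connected graph; the edge
between neighbours u, v weighs

    step_length / mean(c_u, c_v)

with step_length = resolution for orthogonal moves and resolution·√2
for diagonal moves, and c the cell conductance. Diagonal edges are
dropped when both cells flanking the shared corner are land, so paths
cannot slip between two touching land cells. Distances are exact
Dijkstra shortest paths between cell centres, truncated at d_max
(`scipy.sparse.csgraph.dijkstra` with a limit); the undirected graph
makes the table symmetric, which is enforced exactly by taking the
elementwise minimum with the transpose (multi-source Dijkstra is
otherwise symmetric only to the last float ulp along tied paths).

The mean-conductance combination rule and 8-connectivity are
conventions of this package (the common raster least-cost usage);
4-connectivity would overestimate around-island paths.

## Vulnerability to isolation

Anthropogenic disturbance is an integer zone raster (0 = none, 5 =
strongest obstruction). Zones map to conductances

    zone:        0    1    2    3    4    5
    conductance: 1.0  0.5  0.4  0.3  0.2  0.1

(configurable; the values express relative obstruction, not real-world
passage probabilities). Two matrices per species: **Matrix A** from the
uniform-conductance graph and **Matrix B** from the disturbed graph,
both with the same d_max cutoff — so disturbance that stretches a
pair's path beyond d_max severs the connection entirely. Vulnerability
of a habitat cell is |colsums(A^g) − colsums(B^g)|, the absolute loss
of generational imports. Disturbance affects traversal only, never
habitat quality. Since lowering conductance can only lengthen paths,
imports under B are cell-wise ≤ imports under A (tested, not assumed);
the score is a relative spatial index.

## MPA-network assessment

Three features per species: habitat amounts, connectivity exports
(g = 3), and vulnerable imports. For each feature the protected
fraction is Σ amount over protected cells / Σ amount over all cells,
measured for the **full** network (any protection) and the **strict**
network (IUCN categories Ia, Ib, II only; polygons with any other or
missing category count as non-strict, and overlaps resolve to the
strictest designation). A cell is protected when its centre lies inside
a polygon. The random-allocation expectation is analytic: the network's
area fraction of the study area, defined here as all water cells. The
summary statistic is the unweighted mean of per-species fractions.

## Spatial prioritization

Planning units are all water cells with cost 1, so budgets are cell
counts (fractions are converted by rounding half up). Targets are 100%
of every feature's total; existing MPA cells (full network) are locked
in and consume budget. The objective is the minimum shortfall

    Σ_f max(0, target_f − held_f) / target_f.

The solver is a deterministic greedy heuristic: from the locked-in set,
repeatedly add the cell with the largest marginal shortfall decrease,
ties broken by cell index, stopping at the budget, at zero shortfall,
or when no cell helps. With 100% targets the objective is modular until
a feature's entire support is selected, so at small scale the greedy
solution equals the exhaustive optimum (verified against a brute-force
oracle in the tests); an exact integer-programming solver is
deliberately not a dependency. Priority ranks come from budgets grown
in 1% increments from 11% of the study area: greedy selections are
nested by construction, so rank r means "first selected at the r-th
increment", locked-in cells carry no rank, and the protection curve
(mean protected fraction across features, starting from the
locked-in-only baseline) is non-decreasing. If the locked-in area
already exceeds the starting budget (possible on small synthetic grids
where MPA polygons are coarse relative to the water area), the pipeline
starts at the first increment that can hold it.

## Synthetic archipelago generator

Every layer is a pure function of (seed, scenario parameters); per-layer
substreams are derived from the seed so layers are independent yet
reproducible. Spatial structure comes from white noise smoothed with a
Gaussian kernel of width `autocorrelation_length` (default 1000 m) and
thresholded at quantiles; coastal affinity is added as
exp(−distance_to_land/scale) before thresholding.

Defaults, chosen once as a plausible coastal-archipelago setting:

* grid 100×100 at 250 m, `land_fraction` 0.25 (drawn until the land
  fraction is within ±2 points and ≥80% of water is one connected
  body);
* 4 species, d_max uniform on 1–10 km, α = 0.3;
* habitat classes: top 5% of water cells (by field value) quality 1.0,
  next 10% quality 0.5; coastal decay scale 1500 m — a near-shore
  shallow-habitat analogue;
* disturbance on 15% of water cells, hugging the coast (decay scale
  750 m), zone shares 0.35/0.25/0.18/0.13/0.09 from zone 1 to 5 so
  stronger obstruction is rarer, with the strongest zones closest to
  shore;
* MPA blobs (unions of buffered points) covering 10.5% of the water, of
  which 27% strict — echoing a network with 2.8% strict inside 10.5%
  total — plus one deliberately overlapping strict/non-strict pair to
  exercise the strictest-designation rule.

What the generator does *not* emulate: bathymetry, salinity or
temperature gradients, real species-distribution models, or the spatial
congruence of real nursery habitats across species. The last point
matters for interpretation: independent random habitat fields overlap
much less across species than real coastal nursery maps do, so the
synthetic prioritization needs a larger budget (~50% of the study area)
to reach full protection of all features than a real, spatially
congruent case would. Passing tests establish the mechanics and the
mathematical laws of the method, not empirical protection levels.

## Numerical choices and edge cases

* Distances: exact Dijkstra, no approximation; d_ii = 0; pairs beyond
  d_max absent (kernel 0). Symmetry enforced exactly (see above).
* Matrix powers computed sparse × sparse without thresholding small
  values; the d_max cutoff bounds fill-in.
* Greedy tie-break: lowest cell index, making runs bit-reproducible.
* Rasters are ESRI ASCII grids written with full float precision
  (`repr`), so write → read round-trips are bit-exact; NODATA means
  land in the mask and 0 in value layers. MPA polygons are GeoJSON.
* Coordinates are planar metres (projected CRS assumed); no geodesic
  corrections. Cell membership for polygons is centre containment.
* Degenerate inputs: empty polygon sets give an all-unprotected layer;
  a single habitat cell gives a 1×1 zero matrix; zero-total features
  are rejected by the assessment and the planner with the species and
  feature named.

## Problem sizes in the tests

The default end-to-end scenario is 100×100 cells with 4 species
(~7,500 water cells, ~1,100 habitat cells per species); oracle checks
run on 10–15 cell grids where brute-force enumeration (Floyd–Warshall
all-pairs, exhaustive subset search) is exact. These sizes exercise
every code path of the method at full numerical fidelity.

## Known limitations

* The greedy planner is optimal only while no target saturates; past
  saturation it is a heuristic (checked to beat every single-cell swap).
* Vulnerability is a relative index; it cannot be read as recruitment
  loss or demographic rate.
* The zone→conductance mapping is an assumption; it is configurable but
  no sensitivity analysis is built in.
* Whether generational matrices should carry self-retention on the
  diagonal is genuinely open; this package fixes diagonal = 0.
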