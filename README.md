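# seaconn

Seascape connectivity, disturbance-driven vulnerability to isolation,
and protected-area network assessment and prioritization on raster
grids.

`seaconn` is aimed at marine spatial planners and landscape ecologists
working with species that disperse actively over water — for example
coastal fish whose juveniles and adults move between near-shore nursery
habitats through archipelagos. It answers four questions about a
seascape:

1. **Which habitat cells keep the network connected?** Per-species
   connectivity matrices are built from a negative-exponential dispersal
   kernel over least-cost water distances,

       k_ij = s_i · exp(−d_ij / (α·d_max)),   k_ij = 0 for d_ij > d_max,

   where s_i is the donor cell's habitat quality (0 / 0.5 / 1), d_ij the
   least-cost path distance through water (land is impassable), d_max
   the species' maximum dispersal distance and α the kernel steepness
   (default 0.3). Connectivity over g generations is the matrix power
   K^g (default g = 3, capturing stepping-stone routes); row sums are
   per-cell **exports**, column sums **imports**.

2. **Which habitats are vulnerable to isolation?** Anthropogenic
   disturbance zones (1–5) lower water conductance to 0.5…0.1, which
   lengthens least-cost paths. Vulnerability of a cell is the absolute
   loss of generational imports, |colsums(A^g) − colsums(B^g)|, between
   the undisturbed (A) and disturbed (B) models.

3. **How well does the MPA network protect these features?** For each
   species × feature (habitat, exports, vulnerable imports) the
   protected fraction is measured in the full network and in strict
   MPAs (IUCN Ia/Ib/II, strictest designation winning on overlaps) and
   compared with the analytic random-allocation expectation — the
   network's area fraction.

4. **Where should the network grow?** A budgeted minimum-shortfall
   selection (all cells cost 1, targets 100% of every feature, existing
   MPAs locked in) is re-solved at budgets growing in 1% increments
   from 11% of the study area; a cell's priority rank is the first
   increment that selects it.

A seeded synthetic-archipelago generator produces complete input
bundles (land mask, habitat classes, coastal disturbance, overlapping
MPA polygons), so the whole pipeline runs without any external data.

## Worked example

Two habitat cells 250 m apart (both quality 1, d_max = 1 km, α = 0.3);
the recipient cell sits in disturbance zone 1 (conductance 0.5):

```python
import numpy as np
import seaconn as sc

grid = sc.SeascapeGrid(1, 2, 250.0, (0.0, 250.0), np.ones((1, 2), bool))
habitat = sc.HabitatLayer(grid, np.array([[1.0, 1.0]]))
species = sc.SpeciesProfile("perch", habitat, d_max=1000.0)

baseline = sc.build_traversal_graph(grid, sc.uniform_conductance(grid))
zones = sc.DisturbanceLayer(grid, np.array([[0, 1]]))
disturbed = sc.build_traversal_graph(grid, sc.zones_to_conductance(zones))

dist = sc.least_cost_distances(baseline, habitat.habitat_cells, cutoff=1000.0)
K = sc.build_connectivity_matrix(species, dist)
print("K =", np.round(K.matrix.toarray(), 5))

vul = sc.vulnerability_scores(species, baseline, disturbed, g=1)
print("vulnerability (g=1):", np.round(vul.amount, 5))
```

prints

```
K = [[0.     0.4346]
 [0.4346 0.    ]]
vulnerability (g=1): [[0.10541 0.10541]]
```

Each cell exports exp(−250/300) ≈ 0.4346 to the other. Under
disturbance the connecting edge stretches from 250 m to
250/mean(1, 0.5) ≈ 333 m, the import drops to exp(−333.33/300) ≈
0.3292, and both cells lose 0.10541 of their imports — their
vulnerability score.

## Full pipeline

From a YAML config (synthetic scenario or paths to your own layers):

```bash
seaconn --config config.yaml --seed 7 run-all
# or stage by stage: simulate / connect / vulnerability / assess / prioritize
```

```yaml
# config.yaml
seed: 7
generations: 3
output_dir: out
scenario: {}          # default 100x100 archipelago, 4 species
```

The output bundle contains per-species export and vulnerability
rasters, the assessment table (`assessment.csv`, one row per species ×
feature × network plus mean rows), the priority-rank raster, the
protection curve (`protection_curve.csv`), and a JSON run manifest.

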