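"""Habitat vulnerability to connectivity decline and isolation.

For each species two generational connectivity matrices are compared:
Matrix A from the undisturbed water graph and Matrix B from the graph
with disturbance-derived conductances. The vulnerability of a habitat
cell is the absolute loss of generational connectivity imports,
|colsums(A^g) - colsums(B^g)|. Because disturbance only lengthens
least-cost paths, imports under B never exceed imports under A, so the
absolute value equals the plain difference — a property the test suite
checks rather than assumes. The score is a relative spatial index, not
a real-world probability or demographic rate.
"""

from __future__ import annotations

import numpy as np

from .connectivity import (ConnectivityMatrix, FeatureLayer, _onto_grid,
                           build_connectivity_matrix, generational_matrix,
                           imports)
from .core import SpeciesProfile
from .resistance import TraversalGraph, least_cost_distances

__all__ = ["vulnerability_from_matrices", "vulnerability_scores"]


def vulnerability_from_matrices(Ag: ConnectivityMatrix,
                                Bg: ConnectivityMatrix,
                                grid) -> FeatureLayer:
    """|imports(A^g) - imports(B^g)| mapped onto the grid."""
    if len(Ag.cells) != len(Bg.cells) or np.any(Ag.cells != Bg.cells):
        raise ValueError(
            f"{Ag.species}: baseline and disturbed matrices index "
            "different habitat cells"
        )
    if Ag.generations != Bg.generations:
        raise ValueError("matrices must be powered to the same generation")
    diff = np.abs(imports(Ag) - imports(Bg))
    return FeatureLayer(grid, Ag.species, "vulnerable_imports",
                        _onto_grid(grid, Ag.cells, diff))


def vulnerability_scores(species: SpeciesProfile,
                         baseline_graph: TraversalGraph,
                         disturbed_graph: TraversalGraph,
                         g: int = 3) -> FeatureLayer:
    """Compute a species' vulnerability layer from the two water graphs.

    Both graphs must share the grid; the same d_max cutoff is applied to
    both, so disturbance that pushes a pair beyond d_max severs the
    connection entirely.
    """
    grid = baseline_graph.grid
    if not disturbed_graph.grid.same_geometry(grid):
        raise ValueError("baseline and disturbed graphs are on different grids")
    cells = species.habitat.habitat_cells
    dA = least_cost_distances(baseline_graph, cells, cutoff=species.d_max)
    dB = least_cost_distances(disturbed_graph, cells, cutoff=species.d_max)
    A = build_connectivity_matrix(species, dA, disturbed=False)
    B = build_connectivity_matrix(species, dB, disturbed=True)
    return vulnerability_from_matrices(generational_matrix(A, g),
                                       generational_matrix(B, g), grid)
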