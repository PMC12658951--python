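"""Water-traversal graph and least-cost distances between habitat cells.

Dispersal happens through water only: land is an obstacle that cannot be
travelled through. Water cells form an 8-connected graph whose edge
weights are metres of travel divided by the mean conductance of the two
cells, so a disturbed cell (conductance < 1) stretches every path that
crosses it. Least-cost distances are exact Dijkstra shortest paths,
truncated at a species' maximum dispersal distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .core import DisturbanceLayer, SeascapeGrid

__all__ = [
    "ZONE_CONDUCTANCE",
    "ConductanceField",
    "TraversalGraph",
    "DistanceTable",
    "zones_to_conductance",
    "uniform_conductance",
    "build_traversal_graph",
    "least_cost_distances",
]

#: Disturbance zone -> probability of successful passage (conductance,
#: the inverse of traversal cost). Zone 0 is undisturbed water.
ZONE_CONDUCTANCE: dict[int, float] = {
    0: 1.0, 1: 0.5, 2: 0.4, 3: 0.3, 4: 0.2, 5: 0.1,
}


@dataclass
class ConductanceField:
    """Per-water-cell conductance in (0, 1]; land cells carry none (0)."""

    grid: SeascapeGrid
    conductance: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.conductance, dtype=float)
        if c.shape != self.grid.shape:
            raise ValueError("conductance shape does not match grid")
        w = self.grid.water_mask
        if np.any((c[w] <= 0) | (c[w] > 1)):
            raise ValueError("water-cell conductance must lie in (0, 1]")
        c = np.where(w, c, 0.0)
        self.conductance = c


def uniform_conductance(grid: SeascapeGrid) -> ConductanceField:
    """Baseline field: conductance 1 on every water cell (no disturbance)."""
    return ConductanceField(grid, np.ones(grid.shape))


def zones_to_conductance(zones: DisturbanceLayer,
                         mapping: dict[int, float] | None = None
                         ) -> ConductanceField:
    """Map disturbance zones to conductances (default 0->1.0 ... 5->0.1)."""
    mapping = dict(ZONE_CONDUCTANCE if mapping is None else mapping)
    lut = np.empty(6)
    for z in range(6):
        if z not in mapping:
            raise ValueError(f"no conductance given for zone {z}")
        lut[z] = mapping[z]
    cond = lut[zones.zone]
    return ConductanceField(zones.grid, np.where(zones.grid.water_mask, cond, 0.0))


@dataclass
class TraversalGraph:
    """Sparse weighted graph over water cells.

    ``node_of`` maps a flat cell id to its node index (-1 on land);
    ``cells`` lists the flat cell id of each node; ``weights`` is the
    symmetric CSR adjacency matrix in metres of effective travel.
    """

    grid: SeascapeGrid
    cells: np.ndarray
    node_of: np.ndarray = field(repr=False)
    weights: sparse.csr_matrix = field(repr=False)


def build_traversal_graph(grid: SeascapeGrid,
                          conductance: ConductanceField) -> TraversalGraph:
    """Build the 8-connected water graph.

    Edge weight between water neighbours u, v is
    ``step_length / mean(c_u, c_v)`` with ``step_length = resolution``
    for orthogonal moves and ``resolution * sqrt(2)`` for diagonal moves.
    A diagonal edge is omitted when both orthogonal cells flanking the
    shared corner are land, so paths cannot cut through the meeting
    point of two land cells.
    """
    if conductance.grid is not grid and not conductance.grid.same_geometry(grid):
        raise ValueError("conductance field is on a different grid")
    water = grid.water_mask
    cond = conductance.conductance
    res = grid.resolution

    cells = np.flatnonzero(water.ravel())
    node_of = np.full(grid.n_cells, -1, dtype=np.int64)
    node_of[cells] = np.arange(cells.size)

    n_rows, n_cols = grid.shape
    rows_idx, cols_idx, wts = [], [], []

    def add_edges(dr: int, dc: int, step: float,
                  corner_ok: np.ndarray | None) -> None:
        r_src = slice(max(0, -dr), n_rows - max(0, dr))
        c_src = slice(max(0, -dc), n_cols - max(0, dc))
        r_dst = slice(max(0, dr), n_rows - max(0, -dr))
        c_dst = slice(max(0, dc), n_cols - max(0, -dc))
        ok = water[r_src, c_src] & water[r_dst, c_dst]
        if corner_ok is not None:
            ok &= corner_ok
        rr, cc = np.nonzero(ok)
        rr = rr + max(0, -dr)
        cc = cc + max(0, -dc)
        src = node_of[rr * n_cols + cc]
        dst = node_of[(rr + dr) * n_cols + (cc + dc)]
        mean_c = 0.5 * (cond[rr, cc] + cond[rr + dr, cc + dc])
        rows_idx.append(src)
        cols_idx.append(dst)
        wts.append(step / mean_c)

    add_edges(0, 1, res, None)
    add_edges(1, 0, res, None)
    diag = res * np.sqrt(2.0)
    # diagonal (r,c)-(r+1,c+1): flanking cells are (r+1,c) and (r,c+1)
    ok_se = water[1:, :-1] | water[:-1, 1:]
    add_edges(1, 1, diag, ok_se)
    # anti-diagonal (r,c)-(r+1,c-1): flanking cells are (r+1,c) and (r,c-1)
    ok_sw = water[1:, 1:] | water[:-1, :-1]
    add_edges(1, -1, diag, ok_sw)

    if rows_idx:
        src = np.concatenate(rows_idx)
        dst = np.concatenate(cols_idx)
        w = np.concatenate(wts)
        adj = sparse.coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([src, dst]), np.concatenate([dst, src]))),
            shape=(cells.size, cells.size),
        ).tocsr()
    else:
        adj = sparse.csr_matrix((cells.size, cells.size))
    return TraversalGraph(grid, cells, node_of, adj)


@dataclass
class DistanceTable:
    """Pairwise least-cost distances between habitat cells.

    ``dist[i, j]`` is the least-cost distance in metres between source
    cells i and j; pairs farther apart than ``cutoff`` hold ``inf``
    (absent: their kernel value is zero). The diagonal is zero and the
    table is symmetric (the traversal graph is undirected).
    """

    cells: np.ndarray
    dist: np.ndarray = field(repr=False)
    cutoff: float = np.inf

    def to_frame(self) -> pd.DataFrame:
        """Sparse 3-column diagnostic table (source, target, distance_m)."""
        i, j = np.nonzero(np.isfinite(self.dist) & ~np.eye(len(self.cells), dtype=bool))
        return pd.DataFrame({
            "source_cell": self.cells[i],
            "target_cell": self.cells[j],
            "distance_m": self.dist[i, j],
        })


def least_cost_distances(graph: TraversalGraph, sources: np.ndarray,
                         cutoff: float = np.inf) -> DistanceTable:
    """Exact multi-source Dijkstra distances between the given cells.

    ``sources`` are flat cell ids (habitat cells); every one must be a
    water cell. Distances greater than ``cutoff`` are reported as
    ``inf``, which downstream means "no connection".
    """
    sources = np.asarray(sources, dtype=np.int64)
    nodes = graph.node_of[sources]
    if np.any(nodes < 0):
        offending = sources[nodes < 0]
        raise ValueError(f"source cells on land: {offending.tolist()}")
    if sources.size == 0:
        return DistanceTable(sources, np.zeros((0, 0)), cutoff)
    dmat = dijkstra(graph.weights, directed=False, indices=nodes, limit=cutoff)
    table = dmat[:, nodes]
    # the graph is undirected, so the table is symmetric up to float
    # summation order along tied paths; enforce exact symmetry
    table = np.minimum(table, table.T)
    return DistanceTable(sources, table, cutoff)
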