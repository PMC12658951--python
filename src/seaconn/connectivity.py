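"""Dispersal kernel, per-species connectivity matrices, and export/import
feature layers.

The connectivity export k from habitat cell i to habitat cell j is a
negative-exponential function of the least-cost distance between them:

    k_ij = s_i * exp(-d_ij / (alpha * d_max))   if d_ij <= d_max
    k_ij = 0                                    if d_ij >  d_max

where s_i is the donor cell's habitat quality, d_max the species'
maximum dispersal distance, and alpha the kernel steepness. Habitat
quality scales exports only, so with uniform quality the matrix is
symmetric and with varying quality it is row-scaled and asymmetric.
Connectivity over g generations (g successive dispersal events,
capturing stepping-stone routes) is the g-th matrix power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .core import SeascapeGrid, SpeciesProfile
from .resistance import DistanceTable

__all__ = [
    "ConnectivityMatrix",
    "FeatureLayer",
    "dispersal_kernel",
    "build_connectivity_matrix",
    "generational_matrix",
    "exports",
    "imports",
]


@dataclass
class ConnectivityMatrix:
    """Sparse habitat-cell x habitat-cell matrix of kernel values.

    Rows are donors (exports), columns recipients (imports). ``cells``
    gives the flat grid cell id of each row/column. ``generations`` is
    the number of dispersal events the matrix accumulates; ``disturbed``
    flags whether the underlying least-cost paths included
    disturbance-derived resistance (Matrix B) or not (Matrix A).
    """

    species: str
    cells: np.ndarray
    matrix: sparse.csr_matrix = field(repr=False)
    generations: int = 1
    disturbed: bool = False

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class FeatureLayer:
    """Per-cell nonnegative amounts of one biodiversity feature.

    ``kind`` is one of ``habitat``, ``exports`` or ``vulnerable_imports``;
    amounts are zero outside the species' habitat cells.
    """

    grid: SeascapeGrid
    species: str
    kind: str
    amount: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.amount, dtype=float)
        if a.shape != self.grid.shape:
            raise ValueError("feature amount shape does not match grid")
        if np.any(a < 0):
            raise ValueError(f"{self.species}/{self.kind}: negative amounts")
        self.amount = a

    @property
    def total(self) -> float:
        return float(self.amount.sum())


def dispersal_kernel(d, alpha: float, d_max: float, s=1.0):
    """Evaluate the negative-exponential dispersal kernel.

    Vectorized over ``d`` (metres) and ``s`` (donor habitat quality).
    Returns ``s * exp(-d / (alpha * d_max))`` with a hard zero beyond
    ``d_max``; non-finite distances (unreachable pairs) also give zero.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    if not d_max > 0:
        raise ValueError("d_max must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d[np.isfinite(d)] < 0):
        raise ValueError("distances must be nonnegative")
    with np.errstate(over="ignore"):
        k = np.asarray(s, dtype=float) * np.exp(-d / (alpha * d_max))
    return np.where(np.isfinite(d) & (d <= d_max), k, 0.0)


def build_connectivity_matrix(species: SpeciesProfile,
                              distances: DistanceTable,
                              disturbed: bool = False) -> ConnectivityMatrix:
    """Assemble the one-generation connectivity matrix for one species.

    Entry (i, j) = kernel(d_ij) scaled by the donor quality s_i for
    i != j with d_ij within the cutoff; the diagonal is zero (exports go
    to *other* habitat cells; no self-retention).
    """
    if distances.cutoff != species.d_max:
        raise ValueError(
            f"{species.name}: distance table cutoff {distances.cutoff} "
            f"differs from species d_max {species.d_max}"
        )
    cells = distances.cells
    q = species.habitat.quality.ravel()[cells]
    n = len(cells)
    d = distances.dist
    present = np.isfinite(d) & (d <= species.d_max)
    np.fill_diagonal(present, False)
    i, j = np.nonzero(present)
    vals = q[i] * np.exp(-d[i, j] / (species.alpha * species.d_max))
    mat = sparse.coo_matrix((vals, (i, j)), shape=(n, n)).tocsr()
    return ConnectivityMatrix(species.name, cells, mat, generations=1,
                              disturbed=disturbed)


def generational_matrix(K: ConnectivityMatrix, g: int) -> ConnectivityMatrix:
    """Raise a one-generation matrix to the g-th matrix power (K^g)."""
    if K.generations != 1:
        raise ValueError("generational_matrix expects a one-generation matrix")
    if g < 1:
        raise ValueError("generations must be >= 1")
    if g == 1:
        return ConnectivityMatrix(K.species, K.cells, K.matrix.copy(), 1,
                                  K.disturbed)
    out = K.matrix
    for _ in range(g - 1):
        out = out @ K.matrix
    return ConnectivityMatrix(K.species, K.cells, out.tocsr(), g, K.disturbed)


def _onto_grid(grid: SeascapeGrid, cells: np.ndarray,
               values: np.ndarray) -> np.ndarray:
    full = np.zeros(grid.n_cells)
    full[cells] = values
    return full.reshape(grid.shape)


def exports(Kg: ConnectivityMatrix, grid: SeascapeGrid) -> FeatureLayer:
    """Row sums of the generational matrix as a per-cell feature layer.

    Exports measure each habitat cell's contribution to network
    connectivity: the kernel-weighted outflow to all reachable habitat.
    """
    row_sums = np.asarray(Kg.matrix.sum(axis=1)).ravel()
    return FeatureLayer(grid, Kg.species, "exports",
                        _onto_grid(grid, Kg.cells, row_sums))


def imports(Kg: ConnectivityMatrix) -> np.ndarray:
    """Column sums of the generational matrix, aligned with ``Kg.cells``.

    Imports measure kernel-weighted inflow — the external recruitment a
    habitat cell can draw on; the vulnerability index is built from the
    loss of imports under disturbance.
    """
    return np.asarray(Kg.matrix.sum(axis=0)).ravel()
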