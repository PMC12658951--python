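"""Shared fixtures: small grids, a default synthetic bundle, and
independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np
import pytest

import seaconn as sc

SQRT2 = float(np.sqrt(2.0))


def make_grid(water: np.ndarray, resolution: float = 250.0) -> sc.SeascapeGrid:
    water = np.asarray(water, dtype=bool)
    n_rows, n_cols = water.shape
    return sc.SeascapeGrid(n_rows, n_cols, resolution,
                           (0.0, n_rows * resolution), water)


def naive_edge_list(water: np.ndarray, cond: np.ndarray,
                    resolution: float) -> dict[tuple[int, int], float]:
    """Brute-force enumeration of traversal edges, written independently
    of the package's vectorized graph builder: loop over every cell and
    every 8-neighbour offset, apply the mean-conductance weight and the
    no-corner-cutting rule."""
    n_rows, n_cols = water.shape
    edges: dict[tuple[int, int], float] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            if not water[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < n_rows and 0 <= c2 < n_cols):
                        continue
                    if not water[r2, c2]:
                        continue
                    if dr != 0 and dc != 0:
                        # both flanking cells land -> corner is sealed
                        if not water[r + dr, c] and not water[r, c + dc]:
                            continue
                        step = resolution * SQRT2
                    else:
                        step = resolution
                    w = step / (0.5 * (cond[r, c] + cond[r2, c2]))
                    a = r * n_cols + c
                    b = r2 * n_cols + c2
                    edges[(a, b)] = w
    return edges


def oracle_all_pairs(water: np.ndarray, cond: np.ndarray,
                     resolution: float) -> np.ndarray:
    """All-pairs least-cost distances over water cells via Floyd-Warshall
    on a dense matrix assembled from the naive edge list. Returns a
    (n_cells, n_cells) array indexed by flat cell id (inf = unreachable,
    including any land cell)."""
    from scipy.sparse.csgraph import floyd_warshall

    n = water.size
    dense = np.full((n, n), np.inf)
    np.fill_diagonal(dense, 0.0)
    dense[~water.ravel(), :] = np.inf
    dense[:, ~water.ravel()] = np.inf
    for (a, b), w in naive_edge_list(water, cond, resolution).items():
        dense[a, b] = min(dense[a, b], w)
    land = ~water.ravel()
    dist = floyd_warshall(dense)
    dist[land, :] = np.inf
    dist[:, land] = np.inf
    np.fill_diagonal(dist, np.where(land, np.inf, 0.0))
    return dist


@pytest.fixture(scope="session")
def default_scenario() -> sc.SeascapeScenario:
    return sc.SeascapeScenario(seed=7)


@pytest.fixture(scope="session")
def default_bundle(default_scenario) -> sc.ScenarioBundle:
    """The default 100x100, 4-species archipelago used across tests."""
    return sc.generate_bundle(default_scenario)


@pytest.fixture(scope="session")
def small_bundle() -> sc.ScenarioBundle:
    """A 50x50, 2-species archipelago for cheaper end-to-end checks."""
    return sc.generate_bundle(
        sc.SeascapeScenario(seed=11, n_rows=50, n_cols=50, n_species=2,
                            d_max_range=(1000.0, 5000.0)))


def random_seascape(rng: np.random.Generator, n: int = 15,
                    p_land: float = 0.25, disturb: bool = False):
    """A random small water mask + conductance field for oracle tests."""
    water = rng.random((n, n)) > p_land
    cond = np.ones((n, n))
    if disturb:
        zones = rng.integers(0, 6, size=(n, n))
        lut = np.array([1.0, 0.5, 0.4, 0.3, 0.2, 0.1])
        cond = lut[zones]
    cond = np.where(water, cond, 0.0)
    return water, cond
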