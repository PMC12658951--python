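"""Dispersal kernel, connectivity matrices, generational powers,
exports and imports."""

import numpy as np
import pytest
from scipy import sparse

import seaconn as sc

from conftest import make_grid

K250 = float(np.exp(-250.0 / 300.0))  # kernel at 250 m, alpha 0.3, d_max 1000


def two_cell_species(s1=1.0, s2=1.0, d_max=1000.0):
    """Two adjacent habitat cells 250 m apart on a 1x2 water strip."""
    grid = make_grid(np.ones((1, 2), bool))
    habitat = sc.HabitatLayer(grid, np.array([[s1, s2]]))
    species = sc.SpeciesProfile("sp", habitat, d_max)
    g = sc.build_traversal_graph(grid, sc.uniform_conductance(grid))
    dist = sc.least_cost_distances(g, habitat.habitat_cells, cutoff=d_max)
    return grid, species, dist


class TestDispersalKernel:
    def test_closed_form_values(self):
        assert sc.dispersal_kernel(0.0, 0.3, 1000.0, 1.0) == 1.0
        assert sc.dispersal_kernel(1000.0, 0.3, 1000.0, 0.5) == pytest.approx(
            0.5 * np.exp(-1 / 0.3), abs=1e-9)
        assert float(sc.dispersal_kernel(1000.0, 0.3, 1000.0, 0.5)
                     ) == pytest.approx(0.017837, abs=1e-6)

    def test_hard_zero_beyond_dmax(self):
        assert sc.dispersal_kernel(1500.0, 0.3, 1000.0, 1.0) == 0.0
        assert sc.dispersal_kernel(1000.0 + 1e-9, 0.3, 1000.0, 1.0) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            sc.dispersal_kernel(-1.0, 0.3, 1000.0)

    def test_vectorized_matches_scalar(self):
        d = np.array([0.0, 100.0, 999.0, 1001.0, np.inf])
        k = sc.dispersal_kernel(d, 0.3, 1000.0, 0.5)
        expected = [sc.dispersal_kernel(float(x), 0.3, 1000.0, 0.5)
                    if np.isfinite(x) else 0.0 for x in d]
        np.testing.assert_allclose(k, expected)
        assert k[-1] == 0.0


class TestConnectivityMatrix:
    def test_two_cell_uniform_quality(self):
        _, species, dist = two_cell_species()
        K = sc.build_connectivity_matrix(species, dist)
        M = K.matrix.toarray()
        assert M[0, 1] == pytest.approx(0.43460, abs=1e-5)
        assert M[1, 0] == pytest.approx(0.43460, abs=1e-5)
        assert M[0, 0] == M[1, 1] == 0.0

    def test_quality_scales_rows_only(self):
        _, species, dist = two_cell_species(s1=0.5, s2=1.0)
        M = sc.build_connectivity_matrix(species, dist).matrix.toarray()
        assert M[0, 1] == pytest.approx(0.21730, abs=1e-5)
        assert M[1, 0] == pytest.approx(0.43460, abs=1e-5)

    def test_single_habitat_cell_zero_matrix(self):
        grid = make_grid(np.ones((1, 3), bool))
        habitat = sc.HabitatLayer(grid, np.array([[1.0, 0.0, 0.0]]))
        species = sc.SpeciesProfile("sp", habitat, 1000.0)
        g = sc.build_traversal_graph(grid, sc.uniform_conductance(grid))
        dist = sc.least_cost_distances(g, habitat.habitat_cells, cutoff=1000.0)
        K = sc.build_connectivity_matrix(species, dist)
        assert K.matrix.shape == (1, 1) and K.matrix.nnz == 0

    def test_cutoff_mismatch_is_an_error(self):
        _, species, dist = two_cell_species()
        species.d_max = 2000.0
        with pytest.raises(ValueError, match="cutoff"):
            sc.build_connectivity_matrix(species, dist)

    def test_uniform_quality_symmetric_at_all_generations(self, small_bundle):
        sp = small_bundle.species[0]
        # force uniform quality on the species' habitat cells
        uniform = np.where(sp.habitat.quality > 0, 1.0, 0.0)
        species = sc.SpeciesProfile(sp.name,
                                    sc.HabitatLayer(small_bundle.grid, uniform),
                                    sp.d_max)
        g = sc.build_traversal_graph(small_bundle.grid,
                                     sc.uniform_conductance(small_bundle.grid))
        dist = sc.least_cost_distances(g, species.habitat.habitat_cells,
                                       cutoff=species.d_max)
        K = sc.build_connectivity_matrix(species, dist)
        assert (K.matrix != K.matrix.T).nnz == 0
        K3 = sc.generational_matrix(K, 3)
        diff = np.abs((K3.matrix - K3.matrix.T)).max()
        assert diff < 1e-12


class TestGenerationalMatrix:
    def test_hand_example_antidiagonal_cubed(self):
        K = sc.ConnectivityMatrix(
            "sp", np.array([0, 1]),
            sparse.csr_matrix(np.array([[0.0, 0.5], [0.5, 0.0]])))
        K3 = sc.generational_matrix(K, 3)
        np.testing.assert_allclose(K3.matrix.toarray(),
                                   [[0.0, 0.125], [0.125, 0.0]])

    def test_g1_is_identity_operation(self):
        K = sc.ConnectivityMatrix(
            "sp", np.array([0, 1]),
            sparse.csr_matrix(np.array([[0.0, 0.3], [0.2, 0.0]])))
        np.testing.assert_array_equal(
            sc.generational_matrix(K, 1).matrix.toarray(), K.matrix.toarray())

    def test_invalid_generation_count(self):
        K = sc.ConnectivityMatrix("sp", np.array([0]),
                                  sparse.csr_matrix((1, 1)))
        with pytest.raises(ValueError):
            sc.generational_matrix(K, 0)

    def test_sparse_power_matches_dense_triple_product(self):
        rng = np.random.default_rng(0)
        dense = rng.random((10, 10)) * (rng.random((10, 10)) < 0.3)
        np.fill_diagonal(dense, 0.0)
        K = sc.ConnectivityMatrix("sp", np.arange(10),
                                  sparse.csr_matrix(dense))
        K3 = sc.generational_matrix(K, 3).matrix.toarray()
        np.testing.assert_allclose(K3, dense @ dense @ dense, atol=1e-12)

    def test_stepping_stone_capture_beyond_dmax(self):
        # chain of 4 habitat cells 750 m apart; d_max 1000 m connects
        # only neighbours, yet 3 dispersal events link the chain ends
        grid = make_grid(np.ones((1, 10), bool))
        quality = np.zeros((1, 10))
        quality[0, [0, 3, 6, 9]] = 1.0
        habitat = sc.HabitatLayer(grid, quality)
        species = sc.SpeciesProfile("sp", habitat, 1000.0)
        g = sc.build_traversal_graph(grid, sc.uniform_conductance(grid))
        dist = sc.least_cost_distances(g, habitat.habitat_cells, cutoff=1000.0)
        K = sc.build_connectivity_matrix(species, dist)
        assert K.matrix[0, 3] == 0.0  # ends not directly connected
        K3 = sc.generational_matrix(K, 3)
        assert K3.matrix[0, 3] > 0.0


class TestExportsImports:
    def test_row_and_column_sums(self):
        _, species, dist = two_cell_species(s1=0.5, s2=1.0)
        grid = species.habitat.grid
        K = sc.build_connectivity_matrix(species, dist)
        exp = sc.exports(K, grid)
        np.testing.assert_allclose(exp.amount[0], [0.21730, 0.43460],
                                   atol=1e-5)
        np.testing.assert_allclose(sc.imports(K), [0.43460, 0.21730],
                                   atol=1e-5)

    def test_symmetric_matrix_exports_equal_imports(self):
        _, species, dist = two_cell_species()
        grid = species.habitat.grid
        K = sc.build_connectivity_matrix(species, dist)
        exp = sc.exports(K, grid).amount.ravel()[K.cells]
        np.testing.assert_allclose(exp, sc.imports(K), rtol=1e-12)

    def test_totals_match_grand_sum(self):
        rng = np.random.default_rng(1)
        dense = rng.random((8, 8))
        np.fill_diagonal(dense, 0.0)
        grid = make_grid(np.ones((1, 8), bool))
        K = sc.ConnectivityMatrix("sp", np.arange(8),
                                  sparse.csr_matrix(dense))
        exp = sc.exports(K, grid)
        assert exp.total == pytest.approx(dense.sum())
        assert sc.imports(K).sum() == pytest.approx(dense.sum())

    def test_entries_shrink_when_a_distance_grows(self):
        _, species, dist = two_cell_species()
        K1 = sc.build_connectivity_matrix(species, dist).matrix.toarray()
        dist.dist[0, 1] = dist.dist[1, 0] = 700.0
        K2 = sc.build_connectivity_matrix(species, dist).matrix.toarray()
        assert K2[0, 1] < K1[0, 1] and K2[1, 0] < K1[1, 0]
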