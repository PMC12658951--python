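"""Minimum-shortfall selection: objective, greedy solver, ranking."""

import itertools

import numpy as np
import pytest

import seaconn as sc

from conftest import make_grid


def toy_problem(amounts, locked=None, n_cols=None):
    """Problem over a 1xN all-water strip from an (F, N) amount array."""
    amounts = np.asarray(amounts, dtype=float)
    n = amounts.shape[1] if n_cols is None else n_cols
    grid = make_grid(np.ones((1, n), bool))
    features = [
        sc.FeatureLayer(grid, f"sp{f}", "habitat",
                        amounts[f][None, :]) for f in range(amounts.shape[0])
    ]
    locked_mask = None
    if locked is not None:
        locked_mask = np.zeros((1, n), bool)
        locked_mask[0, list(locked)] = True
    return sc.PlanningProblem.from_features(features, locked_mask)


def exhaustive_optimum(problem, budget):
    """Brute-force minimum shortfall over all selections of exactly
    `budget` units containing the locked-in set."""
    locked = np.flatnonzero(problem.locked_in)
    free = np.flatnonzero(~problem.locked_in)
    k = budget - locked.size
    best = np.inf
    for combo in itertools.combinations(free, k):
        sel = np.zeros(problem.n_units, bool)
        sel[locked] = True
        sel[list(combo)] = True
        best = min(best, sc.shortfall_objective(sel, problem))
    return best


class TestShortfallObjective:
    def test_all_cells_selected_gives_zero(self):
        p = toy_problem([[1.0, 2.0], [3.0, 4.0]])
        assert sc.shortfall_objective(np.ones(2, bool), p) == 0.0

    def test_empty_selection_gives_feature_count(self):
        p = toy_problem([[1.0, 2.0], [3.0, 4.0]])
        assert sc.shortfall_objective(np.zeros(2, bool), p) == 2.0

    def test_partial_holdings(self):
        p = toy_problem([[10.0, 0.0, 0.0, 6.0], [0.0, 10.0, 0.0, 6.0]])
        sel = np.array([False, False, False, True])
        assert sc.shortfall_objective(sel, p) == pytest.approx(1.25)


class TestGreedySolver:
    def test_picks_cell_covering_both_features(self):
        p = toy_problem([[10.0, 0.0, 0.0, 6.0], [0.0, 10.0, 0.0, 6.0]])
        sel = sc.solve_min_shortfall(p, budget=1)
        assert sel.tolist() == [False, False, False, True]
        assert sc.shortfall_objective(sel, p) == pytest.approx(1.25)
        assert exhaustive_optimum(p, 1) == pytest.approx(1.25)

    def test_full_budget_reaches_zero_shortfall(self):
        rng = np.random.default_rng(0)
        p = toy_problem(rng.random((3, 12)))
        sel = sc.solve_min_shortfall(p, budget=12)
        assert sc.shortfall_objective(sel, p) == 0.0

    def test_budget_below_locked_in_rejected(self):
        p = toy_problem([[1.0, 1.0, 1.0]], locked=[0, 1])
        with pytest.raises(ValueError, match="locked"):
            sc.solve_min_shortfall(p, budget=1)

    def test_selection_always_contains_locked_in(self):
        rng = np.random.default_rng(1)
        p = toy_problem(rng.random((2, 10)), locked=[3, 7])
        sel = sc.solve_min_shortfall(p, budget=4)
        assert sel[3] and sel[7]
        assert sel.sum() <= 4

    def test_matches_exhaustive_oracle_on_random_problems(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(6, 12))
            amounts = rng.random((3, n)) * (rng.random((3, n)) < 0.7)
            amounts[:, 0] += 0.01  # keep every total positive
            p = toy_problem(amounts)
            budget = int(rng.integers(1, 5))
            sel = sc.solve_min_shortfall(p, budget)
            greedy = sc.shortfall_objective(sel, p)
            assert greedy <= exhaustive_optimum(p, budget) + 1e-9

    def test_incremental_objective_matches_recomputation(self):
        rng = np.random.default_rng(9)
        p = toy_problem(rng.random((4, 15)))
        prev = sc.shortfall_objective(p.locked_in, p)
        for budget in range(1, 10):
            sel = sc.solve_min_shortfall(p, budget)
            score = sc.shortfall_objective(sel, p)
            assert score <= prev + 1e-9
            prev = score


class TestIncrementalRanking:
    def test_locked_in_cells_carry_no_rank(self):
        p = toy_problem([[1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]],
                        locked=[0])
        ranking = sc.incremental_ranking(p, start_fraction=0.2, step=0.1)
        assert ranking.rank[0, 0] == 0

    def test_already_satisfied_targets_give_flat_curve(self):
        amounts = np.zeros((1, 10))
        amounts[0, :3] = 1.0
        p = toy_problem(amounts, locked=[0, 1, 2])
        ranking = sc.incremental_ranking(p, start_fraction=0.3, step=0.1)
        assert np.all(ranking.rank == 0)
        assert np.allclose(ranking.curve.mean_protection, 1.0)

    def test_rank_sets_are_nested_and_contiguous(self):
        rng = np.random.default_rng(3)
        p = toy_problem(rng.random((3, 40)), locked=[0, 1])
        ranking = sc.incremental_ranking(p, start_fraction=0.1, step=0.05)
        ranks = ranking.rank.ravel()[p.unit_cells]
        present = sorted(set(ranks[ranks > 0]))
        assert present == list(range(1, len(present) + 1))
        # cells ranked r are inside the selection at every later budget
        for r, frac in enumerate(ranking.schedule, start=1):
            budget = int(np.floor(frac * p.n_units + 0.5))
            sel = sc.solve_min_shortfall(p, budget)
            assert np.all(sel[(ranks > 0) & (ranks <= r)])

    def test_curve_monotone_and_complete(self):
        rng = np.random.default_rng(4)
        p = toy_problem(rng.random((3, 40)) * (rng.random((3, 40)) < 0.6)
                        + 0.001, locked=[0, 1])
        ranking = sc.incremental_ranking(p, start_fraction=0.1, step=0.05)
        curve = ranking.curve.mean_protection.to_numpy()
        assert np.all(np.diff(curve) >= -1e-12)
        assert curve[-1] == pytest.approx(1.0)

    def test_start_budget_below_locked_area_rejected(self):
        p = toy_problem([[1.0] * 10], locked=range(5))
        with pytest.raises(ValueError):
            sc.incremental_ranking(p, start_fraction=0.1, step=0.1)

    def test_no_improving_single_swap_when_unsaturated(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = toy_problem(rng.random((3, 12)) + 0.05)
            budget = 4
            sel = sc.solve_min_shortfall(p, budget)
            base = sc.shortfall_objective(sel, p)
            for out_cell in np.flatnonzero(sel):
                for in_cell in np.flatnonzero(~sel):
                    alt = sel.copy()
                    alt[out_cell], alt[in_cell] = False, True
                    assert sc.shortfall_objective(alt, p) >= base - 1e-9
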