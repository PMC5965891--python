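"""Annealing schedules, proposal sampler, inner loop and full runs."""

import math

import numpy as np
import pytest
import scipy.optimize
import scipy.sparse as sp

from rdao.annealing import (
    SAConfig,
    SAState,
    acceptance_probability,
    initial_plan,
    inner_loop,
    optimize,
    perturbation_width,
    propose,
)
from rdao.annealing import _Evaluator
from rdao.dosemodel import (
    Aperture,
    AperturePlan,
    BixelGrid,
    DoseInfluenceMatrix,
    LeafRow,
    aperture_dose,
    plan_dose,
)
from rdao.objective import Structure, StructureSet, check_feasible, evaluate_cost

from conftest import two_bixel_toy


class TestSchedules:
    def test_width_starts_at_L0(self):
        cfg = SAConfig(L0=7.5)
        assert perturbation_width(0, cfg) == 7.5

    def test_width_closed_form(self):
        cfg = SAConfig(L0=5.0, alpha_cool=2.0)
        # 1 + 4*exp(-ln4 / 2) = 1 + 4/2 = 3
        assert perturbation_width(3, cfg) == pytest.approx(3.0, rel=1e-12)

    def test_width_monotone_to_one(self):
        cfg = SAConfig(L0=4.0, alpha_cool=3.0)
        widths = [perturbation_width(k, cfg) for k in range(10_001)]
        assert all(a > b for a, b in zip(widths, widths[1:]))
        assert widths[-1] > 1.0
        assert perturbation_width(10**9, cfg) == pytest.approx(1.0, abs=1e-2)

    def test_acceptance_improving_is_one(self):
        cfg = SAConfig()
        for k in [0, 5, 1000]:
            assert acceptance_probability(-0.5, k, cfg) == 1.0

    def test_acceptance_at_zero_is_P0(self):
        cfg = SAConfig(P0=0.37)
        assert acceptance_probability(1.0, 0, cfg) == pytest.approx(0.37, rel=1e-15)

    def test_acceptance_closed_form(self):
        cfg = SAConfig(P0=0.5, beta_cool=1.0)
        # 2*0.5 / (1 + e^{ln 4}) = 1/5
        assert acceptance_probability(0.1, 3, cfg) == pytest.approx(0.2, rel=1e-12)

    def test_acceptance_monotone_bounded(self):
        cfg = SAConfig(P0=0.4, beta_cool=2.0)
        probs = [acceptance_probability(1.0, k, cfg) for k in range(10_001)]
        assert all(a > b for a, b in zip(probs, probs[1:]))
        assert all(0 < p <= 0.4 for p in probs)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError, match="L0"):
            SAConfig(L0=1.0)
        with pytest.raises(ValueError, match="P0"):
            SAConfig(P0=0.6)
        with pytest.raises(ValueError, match="T_min"):
            SAConfig(T_min=2.0, T_star=1.0, T_init=1.0)
        with pytest.raises(ValueError, match="cool_factor"):
            SAConfig(cool_factor=1.0)
        with pytest.raises(ValueError, match="reheat"):
            SAConfig(reheat_factor=0.9)


def _wide_state(weight=100.0):
    """A single-aperture state far from every constraint boundary."""
    grid = BixelGrid("b", 2, 1000)
    dim = DoseInfluenceMatrix(grid, sp.csc_matrix((1, grid.n_bixels)))
    plan = AperturePlan(
        [Aperture("b", weight, [LeafRow(400.0, 600.0), LeafRow(400.0, 600.0)])],
        {"b": dim},
    )
    return SAState(
        current=plan, current_cost=0.0, best=plan, best_cost=0.0, temperature=1.0
    )


class TestPropose:
    def test_deterministic_for_fixed_seed(self):
        cfg = SAConfig(seed=3)
        state = _wide_state()
        p1 = propose(state, cfg, np.random.default_rng(9))
        p2 = propose(state, cfg, np.random.default_rng(9))
        assert p1.apertures[0].weight == p2.apertures[0].weight
        for r1, r2 in zip(p1.apertures[0].rows, p2.apertures[0].rows):
            assert (r1.x, r1.y) == (r2.x, r2.y)

    def test_always_feasible_even_near_boundary(self):
        grid = BixelGrid("b", 1, 4)
        dim = DoseInfluenceMatrix(grid, sp.csc_matrix((1, 4)))
        plan = AperturePlan([Aperture("b", 0.01, [LeafRow(0.0, 0.2)])], {"b": dim})
        state = SAState(plan, 0.0, plan, 0.0, 1.0)
        cfg = SAConfig(L0=8.0)
        rng = np.random.default_rng(0)
        for _ in range(300):
            cand = propose(state, cfg, rng)
            assert check_feasible(cand) == []

    def test_empirical_move_sd_matches_sigma(self):
        """Unconstrained variables move with s.d. within 5% of the schedule width.

        Weight moves are scaled by the plan's mean weight (here 100), since
        weights have no natural grid unit.
        """
        cfg = SAConfig(L0=3.0, weight_move_scale=0.01, move_scope="aperture")
        state = _wide_state(weight=100.0)
        sigma = perturbation_width(state.k_succ, cfg)
        rng = np.random.default_rng(7)
        leaf_moves, weight_moves = [], []
        for _ in range(10_000):
            cand = propose(state, cfg, rng)
            ap = cand.apertures[0]
            leaf_moves.append(ap.rows[0].x - 400.0)
            weight_moves.append(ap.weight - 100.0)
        assert np.std(leaf_moves) == pytest.approx(sigma, rel=0.05)
        assert np.std(weight_moves) == pytest.approx(sigma * 0.01 * 100.0, rel=0.05)


class TestInnerLoop:
    def test_zero_threshold_exits_untouched(self):
        _, _, structs, plan0 = two_bixel_toy()
        cfg = SAConfig(k_succ_max=0)
        state = SAState(plan0, np.inf, plan0, np.inf, cfg.T_init)
        out = inner_loop(state, structs, cfg, np.random.default_rng(0))
        assert out.i == 0
        assert [ap.weight for ap in out.current.apertures] == [0.5, 0.5]
        assert out.trace == []

    def test_flat_surface_acceptance_matches_schedule(self):
        """With a constant cost every move is 'worsening'; empirical acceptance
        binned by k_succ must match the analytic probability."""
        grid = BixelGrid("b", 1, 6)
        dim = DoseInfluenceMatrix(grid, sp.csc_matrix((4, 6)))  # zero dose always
        structs = StructureSet([Structure("s", np.arange(4), 1.0, 0.0)], 4)
        plan = AperturePlan([Aperture("b", 1.0, [LeafRow(2.0, 4.0)])], {"b": dim})
        cfg = SAConfig(
            P0=0.5, beta_cool=3.0, k_succ_max=10**9, i_max=20_000,
            T_init=1.0, T_star=1.0, T_min=1.0, max_reheats=0,
            k_succ_mode="cumulative", seed=11,
        )
        result = optimize(plan, structs, cfg)
        ks = np.cumsum([0] + [t[4] for t in result.trace])[:-1]
        accepted = np.array([t[4] for t in result.trace], dtype=bool)
        for lo, hi in [(0, 3), (3, 10), (10, 50), (50, 500)]:
            sel = (ks >= lo) & (ks < hi)
            if sel.sum() < 30:
                continue
            expect = np.mean(
                [acceptance_probability(1.0, int(k), cfg) for k in ks[sel]]
            )
            n = sel.sum()
            rate = accepted[sel].mean()
            assert abs(rate - expect) < 4 * math.sqrt(expect * (1 - expect) / n) + 1e-9

    def test_convex_toy_reaches_analytic_optimum(self):
        """Single voxel/bixel: optimum weight d*D/D^2, zero residual cost."""
        grid = BixelGrid("b", 1, 1)
        dim = DoseInfluenceMatrix(grid, sp.csc_matrix(np.array([[2.0]])))
        structs = StructureSet([Structure("s", np.array([0]), 1.0, 1.0)], 1)
        plan = AperturePlan([Aperture("b", 1.0, [LeafRow(0.0, 1.0)])], {"b": dim})
        state = SAState(plan, np.inf, plan, np.inf, 1.0)
        cfg = SAConfig(k_succ_max=10**6, i_max=5000, seed=5, k_succ_mode="cumulative")
        out = inner_loop(state, structs, cfg, np.random.default_rng(5))
        assert out.best_cost < 1e-2


class TestOptimize:
    def test_same_seed_identical_run(self, small_case):
        structs = small_case.structs
        plan0 = initial_plan(small_case.dims, 2, structs, mode="conformal")
        cfg = SAConfig(seed=42, i_max=200, k_succ_max=20)
        r1 = optimize(plan0, structs, cfg)
        r2 = optimize(plan0, structs, cfg)
        assert r1.best_cost == r2.best_cost
        assert r1.trace == r2.trace
        for a1, a2 in zip(r1.best_plan.apertures, r2.best_plan.apertures):
            assert a1.weight == a2.weight
            assert [(r.x, r.y) for r in a1.rows] == [(r.x, r.y) for r in a2.rows]

    def test_best_cost_monotone_and_below_current(self, small_case):
        plan0 = initial_plan(small_case.dims, 2, small_case.structs, mode="open")
        cfg = SAConfig(seed=7, i_max=300, k_succ_max=30)
        res = optimize(plan0, small_case.structs, cfg)
        best = [t[3] for t in res.trace]
        cur = [t[2] for t in res.trace]
        assert all(a >= b for a, b in zip(best, best[1:]))
        assert all(b <= c + 1e-12 for b, c in zip(best, cur))

    def test_returned_plans_feasible(self, small_case):
        plan0 = initial_plan(small_case.dims, 2, small_case.structs, mode="conformal")
        res = optimize(plan0, small_case.structs, SAConfig(seed=1, i_max=200, k_succ_max=20))
        assert check_feasible(res.best_plan) == []
        assert check_feasible(res.state.current) == []

    def test_best_cost_agrees_with_reference_evaluation(self, small_case):
        """The fast subset evaluator must match the full-grid cost."""
        plan0 = initial_plan(small_case.dims, 2, small_case.structs, mode="conformal")
        res = optimize(plan0, small_case.structs, SAConfig(seed=2, i_max=200, k_succ_max=20))
        full, _ = evaluate_cost(plan_dose(res.best_plan), small_case.structs)
        assert full == pytest.approx(res.best_cost, rel=1e-10)

    def test_recovers_nnls_optimum_on_toy(self):
        D, _, structs, plan0 = two_bixel_toy()
        u, _ = scipy.optimize.nnls(D, np.ones(2))
        opt = 0.5 * np.sum((D @ u - 1.0) ** 2)
        hits = 0
        for seed in range(6):
            res = optimize(plan0, structs, SAConfig(seed=seed, i_max=1000, k_succ_max=100))
            if res.best_cost <= 1.05 * opt:
                hits += 1
        assert hits >= 5

    def test_reheats_counted_and_bounded(self, small_case):
        plan0 = initial_plan(small_case.dims, 1, small_case.structs, mode="open")
        cfg = SAConfig(seed=0, i_max=50, k_succ_max=5, max_reheats=2)
        res = optimize(plan0, small_case.structs, cfg)
        assert res.state.n_reheats == 2
        assert res.state.temperature < cfg.T_min

    def test_infeasible_start_rejected(self, dim_factory):
        dim = dim_factory()
        plan = AperturePlan(
            [Aperture("b", -1.0, [LeafRow(0.0, 1.0)] * dim.grid.n_rows)], {"b": dim}
        )
        structs = StructureSet([Structure("s", np.arange(5), 1.0, 1.0)], dim.n_voxels)
        with pytest.raises(ValueError, match="infeasible"):
            optimize(plan, structs, SAConfig())


class TestEvaluatorParity:
    def test_subset_evaluator_matches_dosemodel(self, dim_factory, rng):
        """Prefix-sum unit dose equals the sparse reference on scored voxels."""
        dim = dim_factory(n_voxels=60, n_rows=4, n_cols=8)
        structs = StructureSet(
            [
                Structure("a", np.arange(0, 20), 0.7, 1.0),
                Structure("b", np.arange(30, 50), 0.3, 0.0),
            ],
            60,
        )
        ev = _Evaluator({"b": dim}, structs)
        for _ in range(25):
            leaves = np.sort(rng.uniform(0, 8, size=(4, 2)), axis=1)
            ap = Aperture("b", 1.0, [LeafRow(x, y) for x, y in leaves])
            want = aperture_dose(ap, dim)[ev.vox]
            got = ev.aperture_unit_dose("b", leaves)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-14)


class TestInitialPlan:
    def test_open_mode_full_rows(self, small_case):
        plan = initial_plan(small_case.dims, 2, small_case.structs, mode="open")
        ap = plan.apertures[0]
        g = small_case.dims[ap.beam_id].grid
        assert all((r.x, r.y) == (0.0, float(g.n_cols)) for r in ap.rows)
        assert check_feasible(plan) == []

    def test_conformal_mode_targets_mean_dose(self, small_case):
        plan = initial_plan(small_case.dims, 3, small_case.structs, mode="conformal")
        ptv = small_case.structs["ptv"]
        mean_ptv = plan_dose(plan)[ptv.voxel_ids].mean()
        assert mean_ptv == pytest.approx(1.0, rel=1e-6)
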