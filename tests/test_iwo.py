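"""IWO: closed forms, operator contracts, feasibility, vanilla-WOA reduction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retikan.iwo import (Dimension, IWOConfig, SearchSpace, cauchy_mutate,
                         chaotic_initialize, convergence_factor,
                         feedback_update, inertia_weight, optimize,
                         tent_map_step, update_position)
from woa_reference import vanilla_woa


def box(d: int = 5, lo: float = -5.0, hi: float = 5.0) -> SearchSpace:
    return SearchSpace([Dimension(f"x{i}", lo, hi) for i in range(d)])


class FakeRng:
    """Deterministic stand-in delivering a scripted stream of draws."""

    def __init__(self, scalars, vectors):
        self.scalars = list(scalars)
        self.vectors = list(vectors)

    def random(self, size=None):
        if size is None:
            return self.scalars.pop(0)
        return np.asarray(self.vectors.pop(0), dtype=float)

    def uniform(self, lo, hi, size=None):
        value = self.scalars.pop(0)
        return lo + (hi - lo) * value


class TestTentMap:
    @pytest.mark.parametrize("x,expected", [(0.35, 0.5), (0.7, 1.0),
                                            (0.0, 0.0)])
    def test_hand_computed_values(self, x, expected):
        assert tent_map_step(x) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tent_map_step(1.2)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.0, 1.0))
    def test_stays_in_unit_interval(self, x):
        assert 0.0 <= tent_map_step(x) <= 1.0

    def test_trajectory_is_non_degenerate(self):
        x = 0.37
        seen = set()
        for _ in range(10_000):
            x = tent_map_step(x)
            seen.add(round(x, 12))
        assert len(seen) >= 100


class TestChaoticInit:
    def test_positions_inside_bounds(self, rng):
        space = box(7, -3.0, 4.0)
        pop = chaotic_initialize(space, 30, rng)
        for whale in pop:
            assert (whale.position >= space.lb).all()
            assert (whale.position <= space.ub).all()

    def test_degenerate_dimension_pins_to_lower_bound(self, rng):
        space = SearchSpace([Dimension("x", 0.0, 1.0),
                             Dimension("fixed", 2.0, 2.0)])
        with pytest.warns(UserWarning, match="zero-width"):
            pop = chaotic_initialize(space, 5, rng)
        for whale in pop:
            assert whale.position[1] == pytest.approx(2.0)


class TestSchedules:
    def test_convergence_factor_endpoints(self):
        assert convergence_factor(0, 50, 1.0) == pytest.approx(2.0)
        assert convergence_factor(50, 50, 1.0) == pytest.approx(0.0)

    def test_convergence_factor_midpoint_closed_form(self):
        # 2 - 2 (e^0.5 - 1)/(e - 1), evaluated independently
        expected = 2.0 - 2.0 * (math.exp(0.5) - 1.0) / (math.e - 1.0)
        assert convergence_factor(25, 50, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(1.24492, abs=1e-5)

    @pytest.mark.parametrize("m", [0.5, 1.0, 2.0])
    def test_strictly_decreasing(self, m):
        values = [convergence_factor(t, 50, m) for t in range(51)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_zero_tmax_rejected(self):
        with pytest.raises(ValueError):
            convergence_factor(0, 0, 1.0)

    def test_inertia_weight_endpoints(self):
        assert inertia_weight(0, 50, 1.0) == pytest.approx(1.0)
        assert inertia_weight(25, 50, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert inertia_weight(50, 50, 1.0) == pytest.approx(1.0)


class TestCauchyMutate:
    def test_zero_crossover_mutates_exactly_forced_index(self, rng):
        space = box(8)
        cfg = IWOConfig(crossover_rate=0.0)
        best = np.zeros(8)
        current = np.full(8, 2.0)
        mutant = cauchy_mutate(best, current, space, cfg, rng)
        assert (mutant != current).sum() == 1

    def test_full_crossover_ignores_current(self, rng):
        space = box(8)
        cfg = IWOConfig(crossover_rate=1.0)
        best = np.zeros(8)
        current = np.full(8, 2.0)
        mutant = cauchy_mutate(best, current, space, cfg, rng)
        assert not np.any(mutant == current)

    def test_heavy_tail_fraction_matches_cauchy_probability(self):
        """P(|Cauchy| > 3) = 1 - 2 arctan(3)/pi ~ 0.2048."""
        space = SearchSpace([Dimension("x", 0.0, 1.0)])
        cfg = IWOConfig(crossover_rate=1.0, cauchy_scale=0.1)
        rng = np.random.default_rng(0)
        n = 100_000
        draws = cfg.cauchy_scale * (space.ub - space.lb) * \
            rng.standard_cauchy(n)
        frac = np.mean(np.abs(draws) > 3 * cfg.cauchy_scale
                       * (space.ub - space.lb))
        expected = 1.0 - 2.0 * math.atan(3.0) / math.pi
        assert expected == pytest.approx(0.2048, abs=1e-4)
        assert frac == pytest.approx(expected, abs=0.01)


class TestUpdatePosition:
    def test_zero_distance_spiral_returns_weighted_best(self):
        space = box(3, -5, 5)
        cfg = IWOConfig(tmax=10)
        best = np.array([1.0, -2.0, 0.5])
        # script: p=0.9 (spiral), r1, r2 vectors, s=0 -> e^0 cos0 = 1
        fake = FakeRng(scalars=[0.9, 0.5], vectors=[[0.1] * 3, [0.2] * 3])
        t = 4
        from retikan.iwo import inertia_weight
        wt = inertia_weight(t, cfg.tmax, cfg.l_cycle)
        new = update_position(best.copy(), best, best, best, t, space, cfg,
                              fake)
        np.testing.assert_allclose(new, np.clip(wt * best, -5, 5))

    def test_reproducible_given_seed(self):
        space = box(4)
        cfg = IWOConfig()
        w = np.array([1.0, 2.0, -1.0, 0.0])
        b = np.zeros(4)
        r = np.full(4, 0.5)
        a = update_position(w, b, r, b, 3, space, cfg,
                            np.random.default_rng(9))
        b2 = update_position(w, b, r, b, 3, space, cfg,
                             np.random.default_rng(9))
        np.testing.assert_array_equal(a, b2)

    def test_thousand_updates_stay_feasible(self):
        space = box(6, -2.0, 3.0)
        cfg = IWOConfig(tmax=20)
        rng = np.random.default_rng(1)
        for i in range(1000):
            w = rng.uniform(space.lb, space.ub)
            b = rng.uniform(space.lb, space.ub)
            r = rng.uniform(space.lb, space.ub)
            mut = cauchy_mutate(b, w, space, cfg, rng)
            new = update_position(w, b, r, mut, 1 + i % 20, space, cfg, rng)
            assert (new >= space.lb).all() and (new <= space.ub).all()


class TestFeedback:
    def test_below_threshold_returns_rand_whale(self):
        space = box(3)
        cfg = IWOConfig(feedback_threshold=0.5)
        fake = FakeRng(scalars=[0.7, 0.2, 0.5], vectors=[])  # pl=0.2 <= 0.5
        r = np.array([1.0, 2.0, 3.0])
        out = feedback_update(r, np.zeros(3), space, cfg, fake)
        np.testing.assert_array_equal(out, r)

    def test_equal_vectors_are_fixed_point(self):
        space = box(3)
        cfg = IWOConfig(feedback_threshold=0.0)
        r = np.array([1.0, -1.0, 0.0])
        for seed in range(5):
            out = feedback_update(r, r.copy(), space, cfg,
                                  np.random.default_rng(seed))
            np.testing.assert_allclose(out, r)


class TestOptimize:
    def test_constant_objective(self):
        space = box(3)
        res = optimize(lambda x: 7.5, space, IWOConfig(population=5, tmax=5))
        assert res.best_fitness == 7.5

    def test_exact_evaluation_count_and_monotone_history(self):
        space = box(4)
        calls = []
        res = optimize(lambda x: float((x ** 2).sum()), space,
                       IWOConfig(population=8, tmax=12, seed=3),
                       callback=lambda t, p, f: calls.append(t))
        assert res.n_evaluations == 8 * 13
        h = np.array(res.history)
        assert len(h) == 13
        assert (np.diff(h) <= 0).all()
        assert calls == list(range(1, 13))

    def test_nan_objective_becomes_inf_with_warning(self):
        space = box(2)

        def bad(x):
            return float("nan")

        with pytest.warns(UserWarning, match="NaN"):
            res = optimize(bad, space, IWOConfig(population=3, tmax=2))
        assert res.best_fitness == math.inf

    def test_reduces_to_vanilla_woa_on_shared_stream(self):
        """Mutation off + constant inertia + no feedback == textbook WOA."""
        space = box(5)
        cfg = IWOConfig(population=6, tmax=10, seed=42, mutation=False,
                        inertia="constant", feedback_fraction=0.0)
        mine = []
        res = optimize(lambda x: (mine.append(x.copy()), float((x**2).sum()))[1],
                       space, cfg)
        a_schedule = lambda t: convergence_factor(t, cfg.tmax, cfg.m)
        theirs, ref_history = vanilla_woa(
            lambda x: float((x ** 2).sum()), space, 6, 10, a_schedule,
            cfg.b, seed=42)
        assert len(mine) == len(theirs)
        for p1, p2 in zip(mine, theirs):
            np.testing.assert_allclose(p1, p2, atol=1e-12)
        np.testing.assert_allclose(res.history, ref_history, atol=1e-12)

    def test_rastrigin_not_worse_than_vanilla_within_slack(self):
        """Both variants solve 2-D Rastrigin to ~1e-2 at this budget.

        Soft comparison: medians over 10 seeds must agree within a small
        absolute slack (both are near the global optimum of 0).
        """
        space = SearchSpace([Dimension("x", -5.12, 5.12),
                             Dimension("y", -5.12, 5.12)])

        def rastrigin(x):
            return float(20 + (x ** 2 - 10 * np.cos(2 * np.pi * x)).sum())

        iwo = [optimize(rastrigin, space,
                        IWOConfig(population=20, tmax=50, seed=s)).best_fitness
               for s in range(10)]
        woa = [optimize(rastrigin, space,
                        IWOConfig(population=20, tmax=50, seed=s,
                                  mutation=False, inertia="constant",
                                  feedback_fraction=0.0)).best_fitness
               for s in range(10)]
        med_iwo, med_woa = np.median(iwo), np.median(woa)
        print(f"rastrigin medians: IWO {med_iwo:.3g}, vanilla {med_woa:.3g}")
        assert med_iwo <= med_woa + 0.05


class TestSearchSpace:
    def test_categorical_decoding_floors_into_menu(self):
        dim = Dimension("k", kind="categorical", menu=(3, 5))
        assert dim.decode(0.2) == 3
        assert dim.decode(1.7) == 5
        assert dim.decode(2.0) == 5  # boundary clips to the last item

    def test_log_dimension_round_trip(self):
        dim = Dimension("lr", 1e-5, 1e-2, kind="log")
        lo, hi = dim.internal_bounds
        assert dim.decode(lo) == pytest.approx(1e-5)
        assert dim.decode(hi) == pytest.approx(1e-2)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            Dimension("x", 1.0, 0.0)
        with pytest.raises(ValueError):
            Dimension("x", kind="categorical", menu=())
        with pytest.raises(ValueError):
            Dimension("x", -1.0, 1.0, kind="log")
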