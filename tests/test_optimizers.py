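import numpy as np
import pytest

from swarmbalance import SwarmConfig, brute_force_grid, optimize
from swarmbalance.optimizers import AgentState, ba_step, decode, pso_step


class ConstRng:
    """Degenerate generator returning a fixed fraction of each range."""

    def __init__(self, frac: float):
        self.frac = frac

    def uniform(self, low=0.0, high=1.0, size=None):
        val = low + self.frac * (high - low)
        if size is None:
            return val
        return np.full(size, val)


def agent(pos, vel, pbest, **kw):
    return AgentState(
        position=np.array(pos, dtype=float),
        velocity=np.array(vel, dtype=float),
        personal_best_position=np.array(pbest, dtype=float),
        personal_best_fitness=0.0,
        **kw,
    )


WIDE = ((0, 100), (0, 100))


class TestPsoStep:
    def test_hand_derived_update(self):
        # v' = 0.5*1 + 1.5*1*(2-0) + 1.5*1*(4-0) = 9.5 ; x' = 9.5
        a = agent([0, 0], [1, 1], [2, 2])
        cfg = SwarmConfig(inertia=0.5, c1=1.5, c2=1.5)
        pso_step([a], np.array([4.0, 4.0]), cfg, WIDE, ConstRng(1.0))
        np.testing.assert_allclose(a.velocity, [9.5, 9.5])
        np.testing.assert_allclose(a.position, [9.5, 9.5])

    def test_no_attraction_no_motion(self):
        a = agent([5, 5], [0, 0], [7, 7])
        cfg = SwarmConfig(c1=0.0, c2=0.0, inertia=0.9)
        pso_step([a], np.array([9.0, 9.0]), cfg, WIDE, ConstRng(0.5))
        np.testing.assert_allclose(a.position, [5, 5])

    def test_at_both_bests_velocity_scales_by_inertia(self):
        a = agent([5, 5], [2, 2], [5, 5])
        cfg = SwarmConfig(inertia=0.5)
        pso_step([a], np.array([5.0, 5.0]), cfg, WIDE, ConstRng(1.0))
        np.testing.assert_allclose(a.velocity, [1, 1])

    def test_position_clamped_to_bounds(self):
        a = agent([99, 99], [40, 40], [99, 99])
        pso_step([a], np.array([99.0, 99.0]), SwarmConfig(inertia=1.0),
                 WIDE, ConstRng(1.0))
        assert (a.position <= 100).all()


class TestBaStep:
    def test_zero_beta_keeps_velocity(self):
        a = agent([10, 10], [1, 1], [10, 10], loudness=0.5, pulse_rate=1.0)
        cfg = SwarmConfig(Q_min=0.0, Q_max=2.0)
        ba_step([a], np.array([3.0, 3.0]), cfg, WIDE, ConstRng(0.0), t=1)
        np.testing.assert_allclose(a.velocity, [1, 1])

    def test_at_global_best_velocity_unchanged(self):
        a = agent([7, 7], [2, 2], [7, 7], loudness=0.5, pulse_rate=1.0)
        cfg = SwarmConfig()
        ba_step([a], np.array([7.0, 7.0]), cfg, WIDE, ConstRng(0.7), t=1)
        np.testing.assert_allclose(a.velocity, [2, 2])

    def test_unit_pulse_rate_disables_local_walk(self):
        # rand in [0, 1) can never exceed pulse_rate = 1, so the candidate
        # is always the flown position
        rng = np.random.default_rng(0)
        a = agent([50, 50], [0, 0], [50, 50], loudness=0.5, pulse_rate=1.0)
        cands = ba_step([a], np.array([10.0, 10.0]), SwarmConfig(), WIDE, rng, t=1)
        np.testing.assert_allclose(cands[0], a.position)

    def test_low_pulse_rate_walks_around_global_best(self):
        a = agent([50, 50], [0, 0], [50, 50], loudness=0.5, pulse_rate=0.0)
        cands = ba_step([a], np.array([10.0, 10.0]), SwarmConfig(), WIDE,
                        ConstRng(0.6), t=1)
        # walk = gbest + eps * mean loudness with eps = 0.2, loudness 0.5
        np.testing.assert_allclose(cands[0], [10.1, 10.1])


def maximize(best, cand):
    return cand > best


class TestOptimize:
    def test_pso_recovers_known_optimum(self):
        target = (7, 3)
        obj = lambda S, K: -((S - target[0]) ** 2 + (K - target[1]) ** 2)
        cfg = SwarmConfig(population=20, iterations=50, seed=4)
        best, fit, trace = optimize(obj, ((0, 10), (0, 10)), "pso", cfg,
                                    maximize)
        assert best == target
        assert fit == 0

    def test_ba_returns_comparator_best_visited_point(self):
        # with the default unit pulse rate the bat local-walk branch is dead,
        # so BA's guarantee is exactness over *visited* points, not global
        # recovery
        target = (7, 3)
        obj = lambda S, K: -((S - target[0]) ** 2 + (K - target[1]) ** 2)
        for seed in range(5):
            cfg = SwarmConfig(population=20, iterations=50, seed=seed)
            best, fit, trace = optimize(obj, ((0, 10), (0, 10)), "ba", cfg,
                                        maximize)
            best_visited = max(trace, key=lambda e: e.fitness)
            assert fit == best_visited.fitness
            assert obj(*best) == fit

    def test_single_point_bounds(self):
        calls = []
        obj = lambda S, K: calls.append((S, K)) or 1.0
        cfg = SwarmConfig(population=2, iterations=1, seed=0)
        best, _, _ = optimize(obj, ((5, 5), (9, 9)), "pso", cfg, maximize)
        assert best == (5, 9)
        assert set(calls) == {(5, 9)}

    @pytest.mark.parametrize("algorithm", ["pso", "ba"])
    def test_same_seed_identical_trace(self, algorithm):
        obj = lambda S, K: S * 10 + K
        cfg = SwarmConfig(population=5, iterations=20, seed=11)
        _, _, t1 = optimize(obj, ((0, 30), (0, 30)), algorithm, cfg, maximize)
        _, _, t2 = optimize(obj, ((0, 30), (0, 30)), algorithm, cfg, maximize)
        assert t1 == t2

    @pytest.mark.parametrize("algorithm", ["pso", "ba"])
    def test_incumbent_monotone_and_in_bounds(self, algorithm):
        obj = lambda S, K: -abs(S - 13) - abs(K - 4)
        cfg = SwarmConfig(population=6, iterations=25, seed=2)
        bounds = ((0, 25), (2, 8))
        _, _, trace = optimize(obj, bounds, algorithm, cfg, maximize)
        incumbent = None
        for e in trace:
            assert bounds[0][0] <= e.S <= bounds[0][1]
            assert bounds[1][0] <= e.K <= bounds[1][1]
            if e.accepted:
                if incumbent is not None:
                    assert e.fitness > incumbent or incumbent is None
                incumbent = e.fitness

    def test_warm_start_pins_first_agent(self):
        obj = lambda S, K: 0.0
        cfg = SwarmConfig(population=3, iterations=1, seed=0)
        comparator = lambda b, c: False
        _, _, trace = optimize(obj, ((0, 100), (0, 100)), "pso", cfg,
                               comparator, warm_start=(42, 17))
        first = trace[0]
        assert (first.S, first.K) == (42, 17)

    def test_matches_brute_force_on_small_grid(self):
        obj = lambda S, K: -((S - 4) ** 2) - ((K - 2) ** 2) + 0.1 * S
        bounds = ((0, 6), (0, 6))
        bf_best, bf_fit, n = brute_force_grid(obj, bounds, maximize)
        assert n == 49
        for seed in range(5):
            cfg = SwarmConfig(population=10, iterations=30, seed=seed)
            best, fit, _ = optimize(obj, bounds, "pso", cfg, maximize)
            assert fit == bf_fit
            assert best == bf_best


class TestBruteForce:
    def test_small_grid_count(self):
        hits = []
        obj = lambda S, K: hits.append((S, K)) or 0.0
        _, _, n = brute_force_grid(obj, ((1, 3), (1, 4)), maximize)
        assert n == 12
        assert len(set(hits)) == 12

    def test_published_combination_count(self):
        # 10:1 ratio with 20 minority rows: S in 100..9900 (9801 values),
        # K in 2..20 → 186,219 combinations
        obj = lambda S, K: 0.0
        bounds = ((100, 9900), (2, 20))
        _, _, n = brute_force_grid(obj, bounds, lambda b, c: False)
        assert bounds[0][1] - bounds[0][0] + 1 == 9801
        assert n == 186_219


class TestDecode:
    @pytest.mark.parametrize(
        "pos,expected",
        [((3.4, 2.5), (3, 3)), ((3.5, -1.0), (4, 2)), ((99.9, 7.49), (20, 7))],
    )
    def test_round_half_up_and_clamp(self, pos, expected):
        assert decode(pos, ((0, 20), (2, 10))) == expected
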