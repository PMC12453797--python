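"""Particle swarm optimizer: schedules, updates, decoding, fitness, search."""

import numpy as np
import pytest

from learnstate import (
    LabeledDataset,
    SwarmConfig,
    accel_at,
    decode_position,
    fitness,
    inertia_at,
    pso_optimize,
    step_position,
    step_velocity,
)
from learnstate.mlp import TrainConfig
from learnstate.pso import Particle


class _FixedRng:
    """Stand-in generator returning a constant for every uniform draw."""

    def __init__(self, value):
        self.value = value

    def random(self, size=None):
        return np.full(size, self.value) if size is not None else self.value


class TestSchedules:
    def test_inertia_endpoints_and_midpoint(self):
        assert inertia_at(0, 100, 0.4, 0.9) == 0.4
        assert inertia_at(100, 100, 0.4, 0.9) == 0.9
        assert inertia_at(50, 100, 0.4, 0.9) == pytest.approx(0.525, abs=1e-12)

    def test_acceleration_endpoints(self):
        assert accel_at(0, 50, 0.5, 2.5, 0.5, 2.5) == (0.5, 2.5)
        assert accel_at(50, 50, 0.5, 2.5, 0.5, 2.5) == (2.5, 0.5)

    def test_equal_bounds_degenerate_to_constants(self):
        for k in (0, 10, 20):
            assert accel_at(k, 20, 1.0, 1.0, 2.0, 2.0) == (1.0, 2.0)

    def test_zero_horizon_raises(self):
        with pytest.raises(ValueError):
            inertia_at(0, 0)
        with pytest.raises(ValueError):
            accel_at(0, 0)

    def test_realized_sequence_matches_closed_form(self):
        K = 25
        seq = [(inertia_at(k, K), *accel_at(k, K)) for k in range(K + 1)]
        for k, (a, c1, c2) in enumerate(seq):
            assert a == (0.9 - 0.4) * (k / K) ** 2 + 0.4
            assert c1 == (2.5 - 0.5) * (k / K) ** 2 + 0.5
            assert c2 == (0.5 - 2.5) * (k / K) ** 2 + 2.5


class TestVelocityStep:
    def test_inertia_only_when_random_draws_vanish(self):
        p = Particle(np.zeros(3), np.array([2.0, -4.0, 6.0]), np.ones(3))
        v = step_velocity(p, np.ones(3), alpha=0.5, c1=1.0, c2=1.0, rng=_FixedRng(0.0))
        assert np.allclose(v, [1.0, -2.0, 3.0])

    def test_stationary_at_joint_best(self):
        pos = np.array([1.0, 2.0])
        p = Particle(pos.copy(), np.zeros(2), pos.copy())
        v = step_velocity(p, pos.copy(), 0.7, 1.5, 1.5, np.random.default_rng(0))
        assert np.allclose(v, 0.0)

    def test_reproducible_under_seed(self):
        p = Particle(np.zeros(2), np.ones(2), np.ones(2))
        v1 = step_velocity(p, 2 * np.ones(2), 0.5, 1.0, 1.0, np.random.default_rng(7))
        v2 = step_velocity(p, 2 * np.ones(2), 0.5, 1.0, 1.0, np.random.default_rng(7))
        assert np.array_equal(v1, v2)

    def test_strict_paper_signs_reverse_the_pull(self):
        p = Particle(np.zeros(1), np.zeros(1), np.ones(1))
        gbest = np.ones(1)
        rng = _FixedRng(1.0)
        attract = step_velocity(p, gbest, 0.0, 1.0, 1.0, rng)
        repel = step_velocity(p, gbest, 0.0, 1.0, 1.0, rng, strict_paper_signs=True)
        assert np.allclose(attract, -repel)
        assert attract[0] > 0  # pulled toward the best

    def test_velocity_clamped(self):
        p = Particle(np.zeros(1), np.zeros(1), np.full(1, 100.0))
        v = step_velocity(p, np.full(1, 100.0), 0.5, 2.0, 2.0, _FixedRng(1.0), vmax=np.array([5.0]))
        assert v[0] == 5.0


class TestPositionStep:
    def test_plain_update(self):
        p = Particle(np.zeros(1), np.ones(1), np.zeros(1))
        pos, vel = step_position(p, ((-5.0, 5.0),))
        assert pos[0] == 1.0 and vel[0] == 1.0

    def test_clamp_zeroes_velocity(self):
        p = Particle(np.array([4.9]), np.array([1.0]), np.array([4.9]))
        pos, vel = step_position(p, ((-5.0, 5.0),))
        assert pos[0] == 5.0 and vel[0] == 0.0

    def test_zero_velocity_keeps_position(self):
        p = Particle(np.array([1.5]), np.zeros(1), np.array([1.5]))
        pos, _ = step_position(p, ((-5.0, 5.0),))
        assert pos[0] == 1.5


class TestDecode:
    def test_nearest_integer_rule(self):
        assert decode_position(np.array([78.4, 0.141, 94.6])) == (78, 0.141, 95)

    def test_reported_optimum_decodes_exactly(self):
        assert decode_position(np.array([78.0, 0.14, 95.0])) == (78, 0.14, 95)

    def test_bound_edges_clip(self):
        hidden, dropout, batch = decode_position(np.array([500.0, 0.99, 1.0]))
        assert (hidden, batch) == (128, 16)
        assert dropout == 0.5  # upper bound of the dropout dimension


def _blob_dataset(n=60, d=4, spread=0.2, seed=0, shuffle_labels=False):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(3 * c, spread, size=(n, d)) for c in range(3)])
    y = np.concatenate([np.full(n, c) for c in range(3)])
    if shuffle_labels:
        y = rng.permutation(y)
    return LabeledDataset(X=X, y=y, feature_names=tuple(f"x{i}" for i in range(d)))


class TestFitness:
    CFG = TrainConfig(max_iter=60)

    def test_separable_data_scores_near_zero(self):
        f = fitness(np.array([20.0, 0.0, 32.0]), _blob_dataset(), inner_folds=3,
                    seed=0, train_cfg=self.CFG)
        assert f <= 0.05

    def test_permuted_labels_score_near_chance(self):
        f = fitness(np.array([20.0, 0.0, 32.0]), _blob_dataset(shuffle_labels=True),
                    inner_folds=3, seed=0, train_cfg=self.CFG)
        assert f == pytest.approx(2.0 / 3.0, abs=0.1)

    def test_deterministic(self):
        pos = np.array([30.0, 0.1, 40.0])
        ds = _blob_dataset(seed=2)
        assert fitness(pos, ds, seed=5, train_cfg=self.CFG) == fitness(
            pos, ds, seed=5, train_cfg=self.CFG
        )


class TestPsoOptimize:
    def test_sphere_function_single_seed(self):
        cfg = SwarmConfig(
            n_particles=20, max_iter=100, inertia=0.5, c1=1.0, c2=1.0,
            bounds=tuple([(-5.0, 5.0)] * 5), seed=0,
        )
        res = pso_optimize(cfg, lambda p: float(np.sum(p**2)))
        assert res.best_fitness < 1e-2

    def test_gbest_history_non_increasing(self):
        cfg = SwarmConfig(n_particles=8, max_iter=40, bounds=tuple([(-5.0, 5.0)] * 3), seed=1)
        res = pso_optimize(cfg, lambda p: float(np.sum(np.abs(p))))
        g = res.gbest_history
        assert np.all(np.diff(g) <= 0)

    def test_frozen_particle_never_moves(self):
        cfg = SwarmConfig(
            n_particles=1, max_iter=10, inertia=0.0, c1=0.0, c2=0.0,
            bounds=((-2.0, 2.0),), seed=3,
        )
        seen = []
        res = pso_optimize(cfg, lambda p: seen.append(p.copy()) or float(p[0] ** 2))
        assert all(np.array_equal(s, seen[0]) for s in seen)
        assert np.array_equal(res.best_position, seen[0])

    def test_fitness_error_propagates_with_context(self):
        cfg = SwarmConfig(n_particles=2, max_iter=2, bounds=((-1.0, 1.0),), seed=0)
        calls = {"n": 0}

        def bad(p):
            calls["n"] += 1
            if calls["n"] > 2:
                raise ValueError("boom")
            return 0.0

        with pytest.raises(RuntimeError, match="position"):
            pso_optimize(cfg, bad)

    def test_single_particle_quadratic_matches_hand_iteration(self):
        """Deterministic r1 = r2 = 0.5: trajectory equals a hand-rolled oracle."""
        import learnstate.pso as pso_mod

        cfg = SwarmConfig(
            n_particles=1, max_iter=10, inertia=0.5, c1=1.0, c2=1.0,
            bounds=((-10.0, 10.0),), velocity_clamp_frac=1.0, seed=0,
        )
        fixed = _FixedRng(0.5)
        real_rng = np.random.default_rng(cfg.seed)
        x0 = real_rng.uniform(-10.0, 10.0)  # same init draw the optimizer makes

        # hand-iterated oracle of the same update equations
        x, v, pbest, gbest = x0, 0.0, x0, x0

        def f(z):
            return z * z

        fb_p, fb_g = f(pbest), f(gbest)
        traj = []
        for _ in range(10):
            v = 0.5 * v + 1.0 * 0.5 * (pbest - x) + 1.0 * 0.5 * (gbest - x)
            v = float(np.clip(v, -20.0, 20.0))
            x = float(np.clip(x + v, -10.0, 10.0))
            traj.append(x)
            if f(x) < fb_p:
                fb_p, pbest = f(x), x
            if f(x) < fb_g:
                fb_g, gbest = f(x), x

        visited = []

        def record(p):
            visited.append(float(p[0]))
            return float(p[0] ** 2)

        orig = pso_mod.np.random.default_rng

        def patched(seed=None):
            # init uses the real stream; velocity updates use the fixed one
            class Hybrid:
                def __init__(self):
                    self._init_rng = orig(cfg.seed)

                def uniform(self, lo, hi, size=None):
                    return self._init_rng.uniform(lo, hi, size)

                def random(self, size=None):
                    return fixed.random(size)

            return Hybrid()

        pso_mod.np.random.default_rng = patched
        try:
            pso_optimize(cfg, record)
        finally:
            pso_mod.np.random.default_rng = orig
        assert visited[0] == pytest.approx(x0, abs=1e-12)
        assert np.allclose(visited[1:], traj, atol=1e-12)
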