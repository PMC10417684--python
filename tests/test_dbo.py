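"""Unit and property tests for the dung beetle optimizer."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dbofuse import dbo


class FixedRng:
    """Stub generator returning scripted uniform/normal draws."""

    def __init__(self, uniforms=(), normals=()):
        self._u = list(uniforms)
        self._n = list(normals)

    def random(self, size=None):
        v = self._u.pop(0)
        return np.full(size, v) if size is not None else v

    def standard_normal(self, size=None):
        v = self._n.pop(0)
        return np.full(size, v) if size is not None else v


@pytest.fixture
def config():
    return dbo.DBOConfig(population_size=30, max_iterations=10, seed=0)


# ----------------------------------------------------------------- updates
@pytest.mark.parametrize(
    "x, x_prev, worst, alpha, expected",
    [
        ((0.0,), (0.0,), (0.0,), 1, (0.0,)),
        ((1.0,), (0.5,), (3.0,), 1, (1.65,)),
        ((1.0,), (0.5,), (3.0,), -1, (1.55,)),
    ],
)
def test_roll_obstacle_free_hand_values(config, x, x_prev, worst, alpha, expected):
    out = dbo.roll_obstacle_free(
        np.array(x), np.array(x_prev), np.array(worst), alpha, config
    )
    np.testing.assert_allclose(out, expected)


def test_roll_dimension_mismatch_rejected(config):
    with pytest.raises(ValueError):
        dbo.roll_obstacle_free(np.zeros(2), np.zeros(3), np.zeros(2), 1, config)


def test_dance_hand_value():
    out = dbo.dance(np.array([2.0]), np.array([1.0]), math.pi / 4)
    np.testing.assert_allclose(out, [3.0])


@pytest.mark.parametrize("theta", [0.0, math.pi / 2, math.pi])
def test_dance_no_change_angles(theta):
    x = np.array([1.5, -2.0])
    np.testing.assert_array_equal(dbo.dance(x, np.array([0.0, 1.0]), theta), x)


@given(st.floats(0.001, math.pi - 0.001))
def test_dance_zero_displacement_is_fixed_point(theta):
    x = np.array([0.7, -1.2])
    np.testing.assert_allclose(dbo.dance(x, x, theta), x)


def test_shrinking_bounds_hand_values():
    b = dbo.Bounds([0.0], [20.0])
    sb = dbo.shrinking_bounds(np.array([5.0]), 0, 100, b)
    assert sb.R == 1.0
    np.testing.assert_allclose(sb.lower_star, [0.0])
    np.testing.assert_allclose(sb.upper_star, [10.0])


def test_shrinking_bounds_collapse_at_tmax():
    b = dbo.Bounds([0.0], [20.0])
    sb = dbo.shrinking_bounds(np.array([5.0]), 100, 100, b)
    assert sb.R == 0.0
    np.testing.assert_allclose(sb.lower_star, sb.upper_star)
    np.testing.assert_allclose(sb.lower_star, [5.0])


def test_shrinking_bounds_negative_anchor_reconciled():
    # naive interval inverts for a negative anchor; must come back valid
    b = dbo.Bounds([-10.0], [10.0])
    sb = dbo.shrinking_bounds(np.array([-5.0]), 0, 100, b)
    assert np.all(sb.lower_star <= sb.upper_star)
    assert b.contains(sb.lower_star) and b.contains(sb.upper_star)


def test_shrinking_bounds_linear_schedule():
    b = dbo.Bounds([0.0], [1.0])
    t_max = 50
    rs = [dbo.shrinking_bounds(np.array([0.5]), t, t_max, b).R for t in range(t_max + 1)]
    np.testing.assert_allclose(rs, 1.0 - np.arange(t_max + 1) / t_max)


def test_update_brood_hand_value():
    sb = dbo.ShrinkingBounds(np.array([0.0]), np.array([4.0]), R=0.5)
    out = dbo.update_brood(
        np.array([2.0]), np.array([1.0]), sb, FixedRng(uniforms=[0.5, 0.5])
    )
    np.testing.assert_allclose(out, [1.0])


def test_update_brood_fixed_point_and_clipping():
    g = np.array([2.0])
    sb = dbo.ShrinkingBounds(g.copy(), g.copy(), R=0.0)
    out = dbo.update_brood(g, g, sb, np.random.default_rng(0))
    np.testing.assert_allclose(out, g)
    # arbitrary inputs stay inside the spawning region
    sb2 = dbo.ShrinkingBounds(np.array([-1.0]), np.array([1.0]), R=0.5)
    rng = np.random.default_rng(1)
    for _ in range(50):
        out = dbo.update_brood(rng.uniform(-5, 5, 1), rng.uniform(-5, 5, 1), sb2, rng)
        assert -1.0 <= out[0] <= 1.0


def test_update_forager_hand_value():
    fb = dbo.ShrinkingBounds(np.array([1.0]), np.array([5.0]), R=0.5)
    out = dbo.update_forager(np.array([3.0]), fb, FixedRng(uniforms=[0.5], normals=[1.0]))
    np.testing.assert_allclose(out, [4.0])


def test_update_forager_fixed_point_and_determinism():
    x = np.array([2.0])
    fb = dbo.ShrinkingBounds(x.copy(), x.copy(), R=0.0)
    np.testing.assert_allclose(
        dbo.update_forager(x, fb, np.random.default_rng(0)), x
    )
    fb2 = dbo.ShrinkingBounds(np.array([0.0]), np.array([4.0]), R=0.5)
    a = dbo.update_forager(np.array([1.0]), fb2, np.random.default_rng(42))
    b = dbo.update_forager(np.array([1.0]), fb2, np.random.default_rng(42))
    np.testing.assert_array_equal(a, b)


def test_update_thief_hand_value(config):
    out = dbo.update_thief(
        np.array([2.0]),
        np.array([1.0]),
        np.array([3.0]),
        config,
        FixedRng(normals=[1.0]),
    )
    np.testing.assert_allclose(out, [4.0])


def test_update_thief_fixed_point(config):
    x = np.array([1.0, -1.0])
    out = dbo.update_thief(x, x, x, config, np.random.default_rng(0))
    np.testing.assert_allclose(out, x)


# ---------------------------------------------------------------- optimize
def test_optimize_constant_objective_flat_history():
    res = dbo.optimize(
        lambda x: 7.0,
        dbo.Bounds([-1.0, -1.0], [1.0, 1.0]),
        dbo.DBOConfig(population_size=10, max_iterations=20, seed=0),
    )
    assert res.best_fitness == 7.0
    np.testing.assert_array_equal(res.history, np.full(21, 7.0))


def test_optimize_1d_quadratic_finds_minimum():
    res = dbo.optimize(
        lambda x: float((x[0] - 2.0) ** 2),
        dbo.Bounds([0.0], [4.0]),
        dbo.DBOConfig(population_size=30, max_iterations=100, seed=3),
    )
    assert abs(res.best_position[0] - 2.0) < 1e-2


def test_optimize_monotone_history_and_bounds_fuzz():
    rng = np.random.default_rng(0)
    for trial in range(5):
        d = int(rng.integers(1, 5))
        a = rng.normal(size=d)

        def objective(x, a=a):
            return float(np.sum((x - a) ** 4) + np.sin(x.sum()))

        bounds = dbo.Bounds(np.full(d, -3.0), np.full(d, 3.0))
        res = dbo.optimize(
            objective,
            bounds,
            dbo.DBOConfig(population_size=12, max_iterations=30, seed=trial),
        )
        assert np.all(np.diff(res.history) <= 0)
        assert bounds.contains(res.population.positions, atol=1e-12)
        assert bounds.contains(res.best_position, atol=1e-12)


def test_optimize_fixed_seed_bit_identical():
    cfg = dbo.DBOConfig(population_size=15, max_iterations=25, seed=11)
    b = dbo.Bounds(np.full(3, -2.0), np.full(3, 2.0))
    r1 = dbo.optimize(lambda x: float(np.sum(x**2)), b, cfg)
    r2 = dbo.optimize(lambda x: float(np.sum(x**2)), b, cfg)
    np.testing.assert_array_equal(r1.best_position, r2.best_position)
    np.testing.assert_array_equal(r1.history, r2.history)
    assert r1.best_fitness == r2.best_fitness
    assert r1.evaluations == r2.evaluations


def test_optimize_nonfinite_objective_treated_as_inf():
    def objective(x):
        return float("nan") if x[0] > 0 else float(x[0] ** 2)

    res = dbo.optimize(
        objective,
        dbo.Bounds([-1.0], [1.0]),
        dbo.DBOConfig(population_size=10, max_iterations=10, seed=0),
    )
    assert np.isfinite(res.best_fitness)


def test_longer_budget_never_worse_on_convex_objective():
    def sphere(x):
        return float(np.sum(x**2))

    b = dbo.Bounds(np.full(3, -5.0), np.full(3, 5.0))
    short, long = [], []
    for seed in range(20):
        short.append(
            dbo.optimize(
                sphere, b, dbo.DBOConfig(population_size=10, max_iterations=40, seed=seed)
            ).best_fitness
        )
        long.append(
            dbo.optimize(
                sphere, b, dbo.DBOConfig(population_size=10, max_iterations=80, seed=seed)
            ).best_fitness
        )
    assert np.median(long) <= np.median(short)


# ------------------------------------------------------------------ config
def test_role_counts_default_and_validation():
    cfg = dbo.DBOConfig(population_size=30)
    assert cfg.role_counts == (6, 6, 7, 11)
    cfg2 = dbo.DBOConfig(population_size=10)
    assert sum(cfg2.role_counts) == 10
    with pytest.raises(ValueError):
        dbo.DBOConfig(population_size=10, role_counts=(1, 2, 3, 5))
    with pytest.raises(ValueError):
        dbo.DBOConfig(k=0.3)
    with pytest.raises(ValueError):
        dbo.DBOConfig(k=0.0)


def test_bounds_validation_and_trace_table():
    with pytest.raises(ValueError):
        dbo.Bounds([1.0], [0.0])
    res = dbo.optimize(
        lambda x: float(x[0] ** 2),
        dbo.Bounds([-1.0], [1.0]),
        dbo.DBOConfig(population_size=6, max_iterations=3, seed=0),
    )
    table = res.trace_table()
    lines = table.strip().split("\n")
    assert lines[0] == "iteration\tbest_fitness\tmean_fitness"
    assert len(lines) == 5  # header + initial + 3 iterations
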