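"""Dung beetle optimizer (DBO).

A swarm-intelligence metaheuristic that minimizes a black-box objective over a
box-bounded continuous domain.  The population is split into four fixed
behavioural roles, each with its own position-update rule:

* **ball-rolling beetles** steer by a global cue and move relative to the worst
  individual; when one meets an obstacle it "dances" (a tangent-function
  detour) to pick a new direction;
* **brood balls** are re-laid inside a spawning region that shrinks linearly
  around the global best solution as iterations progress;
* **foragers** search a similarly shrinking region anchored at the best
  position of the current population;
* **thieves** raid the neighbourhood of the best solutions with Gaussian steps.

The shrinkage schedule is ``R = 1 - t / Tmax``, so both the spawning and the
foraging regions collapse onto their anchors at the final iteration, moving the
search from exploration to exploitation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DBOConfig",
    "Bounds",
    "Population",
    "ShrinkingBounds",
    "OptimizeResult",
    "roll_obstacle_free",
    "dance",
    "shrinking_bounds",
    "update_brood",
    "update_forager",
    "update_thief",
    "optimize",
]

logger = logging.getLogger(__name__)

#: Reference role split for a population of 30: rollers, broods, foragers, thieves.
DEFAULT_ROLE_COUNTS = (6, 6, 7, 11)

ROLE_NAMES = ("roller", "brood", "forager", "thief")


def _scaled_role_counts(population_size: int) -> tuple[int, int, int, int]:
    """Scale the 6/6/7/11 reference split to an arbitrary population size.

    Largest-remainder apportionment, so the counts always sum to
    ``population_size`` and stay proportional to the reference split.
    """
    fracs = np.asarray(DEFAULT_ROLE_COUNTS, dtype=float) / sum(DEFAULT_ROLE_COUNTS)
    raw = fracs * population_size
    base = np.floor(raw).astype(int)
    short = population_size - int(base.sum())
    order = np.argsort(-(raw - base))
    for i in range(short):
        base[order[i]] += 1
    return tuple(int(c) for c in base)


@dataclass
class DBOConfig:
    """Optimizer settings.

    Parameters
    ----------
    population_size : int
        Number of beetles (all roles together).
    max_iterations : int
        ``Tmax``, the number of position-update sweeps.
    k : float
        Flexure (deflection) coefficient of the rolling rule, in ``(0, 0.2]``.
    b_roll : float
        Constant in ``[0, 1]`` weighting the light-intensity term
        ``|x - x_worst|`` of the rolling rule.
    S : float
        Step constant of the thief update.
    role_counts : tuple of int, optional
        (rollers, broods, foragers, thieves); must sum to ``population_size``.
        Defaults to the 6/6/7/11 reference split scaled proportionally.
    obstacle_probability : float
        Per-iteration probability that a roller meets an obstacle and dances
        instead of rolling.
    seed : int
        Seed for the optimizer's random generator.
    """

    population_size: int = 30
    max_iterations: int = 100
    k: float = 0.1
    b_roll: float = 0.3
    S: float = 0.5
    role_counts: tuple[int, int, int, int] | None = None
    obstacle_probability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if not (0.0 < self.k <= 0.2):
            raise ValueError("k must lie in (0, 0.2]")
        if not (0.0 <= self.b_roll <= 1.0):
            raise ValueError("b_roll must lie in [0, 1]")
        if not (0.0 <= self.obstacle_probability <= 1.0):
            raise ValueError("obstacle_probability must lie in [0, 1]")
        if self.role_counts is None:
            self.role_counts = _scaled_role_counts(self.population_size)
        rc = tuple(int(c) for c in self.role_counts)
        if len(rc) != 4 or any(c < 0 for c in rc):
            raise ValueError("role_counts must be four non-negative integers")
        if sum(rc) != self.population_size:
            raise ValueError(
                f"role_counts {rc} must sum to population_size {self.population_size}"
            )
        self.role_counts = rc


@dataclass
class Bounds:
    """Box constraints ``lower[j] <= x[j] <= upper[j]``."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if np.any(self.lower > self.upper):
            raise ValueError("every lower bound must be <= the matching upper bound")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray, atol: float = 0.0) -> bool:
        return bool(
            np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol)
        )


@dataclass
class ShrinkingBounds:
    """Spawning/foraging region at iteration ``t``: an interval shrunk around an
    anchor by the schedule ``R = 1 - t/Tmax`` and reconciled with the global box.
    """

    lower_star: np.ndarray
    upper_star: np.ndarray
    R: float

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower_star, self.upper_star)


@dataclass
class Population:
    """Swarm state: positions, role labels, fitnesses, and best/worst trackers."""

    positions: np.ndarray
    previous_positions: np.ndarray
    fitnesses: np.ndarray
    roles: np.ndarray
    global_best_position: np.ndarray
    global_best_fitness: float
    local_best_position: np.ndarray
    worst_position: np.ndarray
    iteration: int = 0


@dataclass
class OptimizeResult:
    """Outcome of a DBO run."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    mean_history: np.ndarray
    evaluations: int
    population: Population | None = None

    def trace_table(self) -> str:
        """Best/mean fitness per iteration as a plain-text TSV table."""
        lines = ["iteration\tbest_fitness\tmean_fitness"]
        for i, (b, m) in enumerate(zip(self.history, self.mean_history)):
            lines.append(f"{i}\t{float(b)!r}\t{float(m)!r}")
        return "\n".join(lines) + "\n"


def _check_same_shape(*vectors: np.ndarray) -> None:
    shapes = {np.asarray(v).shape for v in vectors}
    if len(shapes) != 1:
        raise ValueError(f"dimension mismatch among operands: {sorted(shapes)}")


def roll_obstacle_free(
    position: np.ndarray,
    previous_position: np.ndarray,
    worst: np.ndarray,
    alpha: int,
    config: DBOConfig,
) -> np.ndarray:
    """Obstacle-free rolling step.

    ``x' = x + alpha * k * x_prev + b * |x - x_worst|`` with ``alpha`` in
    ``{-1, +1}`` (direction deflection) and ``|x - x_worst|`` emulating the
    change in light intensity.  The caller clips the result to bounds.
    """
    position = np.asarray(position, dtype=float)
    previous_position = np.asarray(previous_position, dtype=float)
    worst = np.asarray(worst, dtype=float)
    _check_same_shape(position, previous_position, worst)
    if alpha not in (-1, 1):
        raise ValueError("alpha must be -1 or +1")
    return position + alpha * config.k * previous_position + config.b_roll * np.abs(
        position - worst
    )


def dance(
    position: np.ndarray, previous_position: np.ndarray, theta: float
) -> np.ndarray:
    """Obstacle (dancing) step: ``x' = x + tan(theta) * |x - x_prev|``.

    At ``theta`` exactly 0, pi/2 or pi the beetle does not move.
    """
    position = np.asarray(position, dtype=float)
    previous_position = np.asarray(previous_position, dtype=float)
    _check_same_shape(position, previous_position)
    if not (0.0 <= theta <= math.pi):
        raise ValueError("theta must lie in [0, pi]")
    if theta in (0.0, math.pi / 2, math.pi):
        return position.copy()
    return position + math.tan(theta) * np.abs(position - previous_position)


def shrinking_bounds(
    anchor: np.ndarray, t: int, t_max: int, global_bounds: Bounds
) -> ShrinkingBounds:
    """Shrinking spawning/foraging region around an anchor.

    ``R = 1 - t/Tmax``;
    ``lower* = max(anchor * (1 - R), Lf)``, ``upper* = min(anchor * (1 + R), Uf)``.

    For negative anchor components the naive interval can invert
    (lower* > upper*); the two values are swapped and then clipped into the
    global box so a valid interval is always returned.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not (0 <= t <= t_max):
        raise ValueError("t must lie in [0, t_max]")
    anchor = np.asarray(anchor, dtype=float)
    _check_same_shape(anchor, global_bounds.lower)
    R = 1.0 - t / t_max
    lo = np.maximum(anchor * (1.0 - R), global_bounds.lower)
    hi = np.minimum(anchor * (1.0 + R), global_bounds.upper)
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    lo = global_bounds.clip(lo)
    hi = global_bounds.clip(hi)
    return ShrinkingBounds(lower_star=lo, upper_star=hi, R=R)


def update_brood(
    brood_position: np.ndarray,
    gbest: np.ndarray,
    sbounds: ShrinkingBounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Brood-ball update inside the spawning region.

    ``B' = x_gbest + b1 o (B - lower*) + b2 o (B - upper*)`` with ``b1``,
    ``b2`` independent uniform [0, 1] vectors; the result is clipped into the
    spawning region.
    """
    brood_position = np.asarray(brood_position, dtype=float)
    gbest = np.asarray(gbest, dtype=float)
    _check_same_shape(brood_position, gbest, sbounds.lower_star)
    d = brood_position.size
    b1 = rng.random(d)
    b2 = rng.random(d)
    new = (
        gbest
        + b1 * (brood_position - sbounds.lower_star)
        + b2 * (brood_position - sbounds.upper_star)
    )
    return sbounds.clip(new)


def update_forager(
    position: np.ndarray,
    fbounds: ShrinkingBounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Forager update relative to the shrinking foraging region.

    ``x' = x + C1 * (x - lower*) + C2 o (x - upper*)`` with ``C1`` a single
    standard-normal draw and ``C2`` a uniform [0, 1] vector.  The caller clips
    to the global box.
    """
    position = np.asarray(position, dtype=float)
    _check_same_shape(position, fbounds.lower_star)
    c1 = rng.standard_normal()
    c2 = rng.random(position.size)
    return (
        position
        + c1 * (position - fbounds.lower_star)
        + c2 * (position - fbounds.upper_star)
    )


def update_thief(
    position: np.ndarray,
    gbest: np.ndarray,
    lbest: np.ndarray,
    config: DBOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thief update: a Gaussian raid around the population best.

    ``x' = x_lbest + S * g o (|x - x_gbest| + |x - x_lbest|)`` with ``g`` a
    standard-normal vector.  The caller clips to the global box.
    """
    position = np.asarray(position, dtype=float)
    gbest = np.asarray(gbest, dtype=float)
    lbest = np.asarray(lbest, dtype=float)
    _check_same_shape(position, gbest, lbest)
    g = rng.standard_normal(position.size)
    return lbest + config.S * g * (
        np.abs(position - gbest) + np.abs(position - lbest)
    )


def _safe_eval(objective: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    value = float(objective(x))
    if not math.isfinite(value):
        logger.warning("objective returned non-finite value at %s; using +inf", x)
        return math.inf
    return value


def optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: DBOConfig,
) -> OptimizeResult:
    """Minimize ``objective`` over ``bounds`` with the dung beetle optimizer.

    The swarm is initialized uniformly inside the box and the four role
    subpopulations are updated for ``config.max_iterations`` sweeps.  Selection
    is unconditional replacement with best-ever tracking, so the returned
    fitness trace is monotonically non-increasing.  All randomness derives from
    ``config.seed`` through per-role substreams, so a fixed seed gives a
    bit-identical result.
    """
    master = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in master.spawn(5)]
    rng_init, rng_roll, rng_brood, rng_forage, rng_thief = streams

    d = bounds.dim
    n = config.population_size
    t_max = config.max_iterations
    n_roll, n_brood, n_forage, n_thief = config.role_counts
    roles = np.array(
        ["roller"] * n_roll
        + ["brood"] * n_brood
        + ["forager"] * n_forage
        + ["thief"] * n_thief
    )

    positions = rng_init.uniform(bounds.lower, bounds.upper, size=(n, d))
    previous = positions.copy()
    fitnesses = np.array([_safe_eval(objective, x) for x in positions])
    evaluations = n

    best_idx = int(np.argmin(fitnesses))
    gbest = positions[best_idx].copy()
    gbest_fit = float(fitnesses[best_idx])

    history = [gbest_fit]
    finite = fitnesses[np.isfinite(fitnesses)]
    mean_history = [float(finite.mean()) if finite.size else math.inf]

    for t in range(1, t_max + 1):
        worst = positions[int(np.argmax(fitnesses))].copy()
        lbest = positions[int(np.argmin(fitnesses))].copy()

        sbounds = shrinking_bounds(gbest, t, t_max, bounds)
        fbounds = shrinking_bounds(lbest, t, t_max, bounds)

        new_positions = np.empty_like(positions)
        for i in range(n):
            role = roles[i]
            x = positions[i]
            if role == "roller":
                if rng_roll.random() < config.obstacle_probability:
                    theta = rng_roll.uniform(0.0, math.pi)
                    cand = dance(x, previous[i], theta)
                else:
                    alpha = 1 if rng_roll.random() < 0.5 else -1
                    cand = roll_obstacle_free(x, previous[i], worst, alpha, config)
                cand = bounds.clip(cand)
            elif role == "brood":
                cand = update_brood(x, gbest, sbounds, rng_brood)
            elif role == "forager":
                cand = bounds.clip(update_forager(x, fbounds, rng_forage))
            else:
                cand = bounds.clip(
                    update_thief(x, gbest, lbest, config, rng_thief)
                )
            new_positions[i] = cand

        previous = positions
        positions = new_positions
        fitnesses = np.array([_safe_eval(objective, x) for x in positions])
        evaluations += n

        it_best = int(np.argmin(fitnesses))
        if fitnesses[it_best] < gbest_fit:
            gbest_fit = float(fitnesses[it_best])
            gbest = positions[it_best].copy()
        history.append(gbest_fit)
        finite = fitnesses[np.isfinite(fitnesses)]
        mean_history.append(float(finite.mean()) if finite.size else math.inf)

    population = Population(
        positions=positions,
        previous_positions=previous,
        fitnesses=fitnesses,
        roles=roles,
        global_best_position=gbest.copy(),
        global_best_fitness=gbest_fit,
        local_best_position=positions[int(np.argmin(fitnesses))].copy(),
        worst_position=positions[int(np.argmax(fitnesses))].copy(),
        iteration=t_max,
    )
    return OptimizeResult(
        best_position=gbest,
        best_fitness=gbest_fit,
        history=np.asarray(history),
        mean_history=np.asarray(mean_history),
        evaluations=evaluations,
        population=population,
    )
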