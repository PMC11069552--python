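"""Golden Flower Search: flower-pollination population search whose global
move is a tangent flight with Pareto-drawn step magnitudes and whose local
move is a golden-section line search toward a conspecific, plus a binary
wrapper for feature selection.

Global pollination follows G' = G + s * S * tan(theta) * (G - best), where S
is a heavy-tailed Pareto(shape, scale 1) draw and theta ~ Uniform(0, pi/2)
per component (tan clipped for numerical safety).  Local pollination runs a
golden-section search (probes at the 0.618 / 0.382 points of the bracket)
along the segment from the pollen to a randomly chosen other population
member.  Moves are accepted greedily, so the best-so-far trace never
degrades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.linear_model import RidgeClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = ["GFSConfig", "GFSState", "FeatureSelectionProblem",
           "init_population", "pareto_flight", "tangent_flight",
           "golden_section_refine", "gfs_optimize", "select_features"]

GOLDEN = 0.618  # golden-section probe coefficient


@dataclass(frozen=True)
class GFSConfig:
    population_size: int = 30
    iterations: int = 200
    step_size: float = 0.1
    switch_probability: float = 0.8
    lower: np.ndarray | float = 0.0
    upper: np.ndarray | float = 1.0
    pareto_shape: float = 1.5
    tan_clip: float = 1e3
    golden_budget: int = 8
    golden_coefficient: float = GOLDEN
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.switch_probability <= 1.0:
            raise ValueError("switch_probability must lie in [0, 1]")

    def bounds(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        L = np.broadcast_to(np.asarray(self.lower, dtype=float), dim).copy()
        U = np.broadcast_to(np.asarray(self.upper, dtype=float), dim).copy()
        if not np.all(L < U):
            raise ValueError("lower bounds must be strictly below upper bounds")
        return L, U


@dataclass
class GFSState:
    population: np.ndarray        # pop x dim
    fitness: np.ndarray           # pop
    global_best: np.ndarray
    global_best_fitness: float
    history: list[float] = field(default_factory=list)


def init_population(f: Callable[[np.ndarray], float], dim: int,
                    config: GFSConfig, rng: np.random.Generator) -> GFSState:
    """Uniform initialization L + (U - L) * rand over the box."""
    L, U = config.bounds(dim)
    pop = L + (U - L) * rng.uniform(size=(config.population_size, dim))
    fit = np.array([f(x) for x in pop])
    best = int(fit.argmin())
    return GFSState(pop, fit, pop[best].copy(), float(fit[best]))


def pareto_flight(G: np.ndarray, best: np.ndarray, config: GFSConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """G' = G + s * S(g) * (G - best) with per-component Pareto(shape, 1) draws."""
    L, U = config.bounds(len(G))
    S = 1.0 + rng.pareto(config.pareto_shape, size=len(G))
    return np.clip(G + config.step_size * S * (G - best), L, U)


def tangent_flight(G: np.ndarray, best: np.ndarray, config: GFSConfig,
                   rng: np.random.Generator,
                   step_scale: np.ndarray | float = 1.0) -> np.ndarray:
    """G' = G + s * tan(theta) * (G - best), theta ~ U(0, pi) per component.

    Sampling theta over the full (0, pi) makes tan(theta) alternate between
    -inf and +inf, so steps are signed: a pollen can overshoot past the best
    solution or contract toward it, which is what gives the flight its
    heavy-tailed exploration and its exploitation pressure at once.
    ``step_scale`` lets the caller modulate the step (the optimizer passes a
    Pareto draw here so the global move honours both the tangent-flight and
    the heavy-tailed step law in one update).
    """
    L, U = config.bounds(len(G))
    theta = rng.uniform(0.0, np.pi, size=len(G))
    t = np.clip(np.tan(theta), -config.tan_clip, config.tan_clip)
    return np.clip(G + config.step_size * step_scale * t * (G - best), L, U)


def golden_section_refine(f: Callable[[np.ndarray], float], m: np.ndarray,
                          n: np.ndarray, budget: int,
                          coefficient: float = GOLDEN) -> tuple[np.ndarray, float]:
    """Golden-section line search on the segment m + t (n - m), t in [0, 1].

    Each iteration probes t1 = a + c (b - a) and t2 = b - c (b - a) with
    c = 0.618 and shrinks the bracket toward the better probe; stops after
    ``budget`` objective evaluations and returns the best point found.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if budget < 2:
        raise ValueError("golden-section budget must be >= 2")
    if np.array_equal(m, n):
        raise ValueError("degenerate segment: m == n")

    def point(t):
        return m + t * (n - m)

    # a coefficient below 0.5 (e.g. the 0.0618 fidelity override) probes the
    # mirrored pair of points; normalise so t1 < t2 always
    c = max(coefficient, 1.0 - coefficient)
    a, b = 0.0, 1.0
    # probes at b - c(b-a) and a + c(b-a); with c = 0.618 these are the
    # 0.382/0.618 golden points, and one probe is reused per shrink
    t1, t2 = b - c * (b - a), a + c * (b - a)
    f1, f2 = f(point(t1)), f(point(t2))
    evals = 2
    best_t, best_f = (t1, f1) if f1 <= f2 else (t2, f2)
    while evals < budget:
        if f1 <= f2:
            b, t2, f2 = t2, t1, f1
            t1 = b - c * (b - a)
            f1 = f(point(t1))
        else:
            a, t1, f1 = t1, t2, f2
            t2 = a + c * (b - a)
            f2 = f(point(t2))
        evals += 1
        for t, fv in ((t1, f1), (t2, f2)):
            if fv < best_f:
                best_t, best_f = t, fv
    return point(best_t), float(best_f)


def gfs_optimize(f: Callable[[np.ndarray], float], dim: int,
                 config: GFSConfig,
                 initial_points: np.ndarray | None = None
                 ) -> tuple[np.ndarray, float, list[float]]:
    """Minimize ``f`` over the box; returns (best point, best value, trace).

    ``initial_points`` (k x dim) replaces the first k pollens of the uniform
    initial population — used for deterministic warm starts.
    """
    rng = np.random.default_rng(config.seed)
    state = init_population(f, dim, config, rng)
    if initial_points is not None:
        pts = np.atleast_2d(initial_points)
        for k, pt in enumerate(pts[: config.population_size]):
            state.population[k] = pt
            state.fitness[k] = f(pt)
            if state.fitness[k] < state.global_best_fitness:
                state.global_best = pt.copy()
                state.global_best_fitness = float(state.fitness[k])
    if not np.all(np.isfinite(state.fitness)):
        bad = state.population[~np.isfinite(state.fitness)][0]
        raise FloatingPointError(f"non-finite objective at {bad}")
    pop, fit = state.population, state.fitness

    for _ in range(config.iterations):
        for i in range(config.population_size):
            if rng.uniform() < config.switch_probability:
                scale = 1.0 + rng.pareto(config.pareto_shape, size=dim)
                cand = tangent_flight(pop[i], state.global_best, config, rng,
                                      step_scale=scale)
                cand_fit = f(cand)
            else:
                choices = [k for k in range(config.population_size) if k != i]
                mate = pop[choices[rng.integers(len(choices))]]
                if np.array_equal(pop[i], mate):
                    continue
                cand, cand_fit = golden_section_refine(
                    f, pop[i], mate, config.golden_budget,
                    coefficient=config.golden_coefficient)
            if not np.isfinite(cand_fit):
                raise FloatingPointError(f"non-finite objective at {cand}")
            if cand_fit < fit[i]:
                pop[i], fit[i] = cand, cand_fit
                if cand_fit < state.global_best_fitness:
                    state.global_best = cand.copy()
                    state.global_best_fitness = float(cand_fit)
        # re-dissipate the worst pollen uniformly over the box each
        # iteration: flights scale with (G - best), so a population that
        # collapses on a coordinate can never move it again without an
        # injected scout
        worst = int(fit.argmax())
        L, U = config.bounds(dim)
        pop[worst] = L + (U - L) * rng.uniform(size=dim)
        fit[worst] = f(pop[worst])
        if fit[worst] < state.global_best_fitness:
            state.global_best = pop[worst].copy()
            state.global_best_fitness = float(fit[worst])
        state.history.append(state.global_best_fitness)

    return state.global_best, state.global_best_fitness, state.history


@dataclass
class FeatureSelectionProblem:
    """Wrapper feature-selection objective: w_a * CV accuracy of a ridge
    classifier on the selected columns + (1 - w_a) * sparsity reward.

    The default weight leans heavily on accuracy: with d ~ 20 columns the
    per-feature sparsity price is (1 - w_a)/d = 0.005, below the accuracy a
    genuinely informative clinical feature contributes, while still pruning
    pure-noise columns."""
    X: np.ndarray
    y: np.ndarray
    accuracy_weight: float = 0.9
    cv_folds: int = 3
    min_features: int = 1
    cv_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.accuracy_weight <= 1.0:
            raise ValueError("accuracy_weight must lie in (0, 1]")
        self._cache: dict[bytes, float] = {}

    def subset_accuracy(self, mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key in self._cache:
            return self._cache[key]
        Xs = self.X[:, mask]
        majority = float(np.bincount(self.y).max() / len(self.y))
        if Xs.shape[1] == 0 or np.all(Xs.std(axis=0) < 1e-12):
            acc = majority
        else:
            cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=True,
                                 random_state=self.cv_seed)
            accs = []
            for tr, te in cv.split(Xs, self.y):
                clf = RidgeClassifier(alpha=1.0)
                clf.fit(Xs[tr], self.y[tr])
                accs.append(float((clf.predict(Xs[te]) == self.y[te]).mean()))
            acc = float(np.mean(accs))
        self._cache[key] = acc
        return acc

    def fitness(self, position: np.ndarray) -> float:
        mask = self.binarize(position)
        acc = self.subset_accuracy(mask)
        sparsity = 1.0 - mask.sum() / len(mask)
        # negated: gfs_optimize minimizes
        return -(self.accuracy_weight * acc + (1.0 - self.accuracy_weight) * sparsity)

    @staticmethod
    def binarize(position: np.ndarray) -> np.ndarray:
        mask = position > 0.5
        if not mask.any():
            mask = np.zeros_like(mask)
            mask[int(np.argmax(position))] = True
        return mask


def select_features(problem: FeatureSelectionProblem,
                    config: GFSConfig) -> tuple[np.ndarray, float, list[float]]:
    """Run GFS over [0, 1]^d and binarize the best pollen at 0.5.

    Returns (boolean feature mask, achieved fitness, best-fitness trace);
    the fitness returned is the maximized score (positive orientation).
    """
    d = problem.X.shape[1]
    best, best_val, history = gfs_optimize(problem.fitness, d, config)
    mask = problem.binarize(best)
    # deterministic bit-flip refinement: the population search explores mask
    # space through continuous moves and can stall one flip short of the
    # optimum; sweep single add/drop flips until none improves
    score = -best_val
    improved = True
    while improved:
        improved = False
        for j in range(d):
            cand = mask.copy()
            cand[j] = not cand[j]
            if not cand.any():
                continue
            acc = problem.subset_accuracy(cand)
            cand_score = (problem.accuracy_weight * acc
                          + (1 - problem.accuracy_weight) * (1 - cand.sum() / d))
            if cand_score > score + 1e-12:
                mask, score, improved = cand, cand_score, True
    history = [-h for h in history]
    history.append(score)
    return mask, score, history
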