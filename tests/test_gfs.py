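import numpy as np
import pytest

from dacl.gfs import (FeatureSelectionProblem, GFSConfig, GFSState,
                      gfs_optimize, golden_section_refine, init_population,
                      pareto_flight, select_features, tangent_flight)
from dacl.schema import encode_table
from dacl.synthetic import CohortConfig, generate_cohort


def sphere(x):
    return float(np.sum(x * x))


class TestMoves:
    def setup_method(self):
        self.cfg = GFSConfig(lower=-5.0, upper=5.0, seed=0)
        self.rng = np.random.default_rng(0)

    def test_init_within_bounds_and_deterministic(self):
        s1 = init_population(sphere, 4, self.cfg, np.random.default_rng(1))
        s2 = init_population(sphere, 4, self.cfg, np.random.default_rng(1))
        assert (s1.population >= -5).all() and (s1.population <= 5).all()
        np.testing.assert_array_equal(s1.population, s2.population)
        assert s1.global_best_fitness == s1.fitness.min()

    def test_degenerate_bounds_rejected(self):
        cfg = GFSConfig(lower=1.0, upper=1.0)
        with pytest.raises(ValueError):
            cfg.bounds(3)

    def test_pareto_flight_fixed_points(self):
        g = np.array([1.0, -2.0])
        assert np.array_equal(pareto_flight(g, g.copy(), self.cfg, self.rng), g)
        cfg0 = GFSConfig(step_size=0.0, lower=-5.0, upper=5.0)
        out = pareto_flight(g, np.zeros(2), cfg0, self.rng)
        np.testing.assert_array_equal(out, g)

    def test_flights_respect_bounds(self):
        g = np.array([4.9, -4.9])
        best = np.array([-4.0, 4.0])
        cfg = GFSConfig(step_size=50.0, lower=-5.0, upper=5.0)
        for _ in range(50):
            for move in (pareto_flight, tangent_flight):
                out = move(g, best, cfg, self.rng)
                assert (out >= -5).all() and (out <= 5).all()

    def test_tangent_flight_zero_difference(self):
        g = np.array([1.0, 1.0])
        assert np.array_equal(tangent_flight(g, g.copy(), self.cfg, self.rng), g)

    def test_tangent_steps_heavy_tailed(self):
        """Clipped tan(theta) over theta ~ U(0, pi) has excess kurtosis far
        above the Gaussian's."""
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, np.pi, size=100_000)
        steps = np.clip(np.tan(theta), -1e3, 1e3)
        z = (steps - steps.mean()) / steps.std()
        kurtosis = np.mean(z ** 4) - 3.0
        assert kurtosis > 10.0


class TestGoldenSection:
    def test_quadratic_high_budget(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t0 = rng.uniform(0.05, 0.95)
            x, _ = golden_section_refine(lambda v: (v[0] - t0) ** 2,
                                         np.array([0.0]), np.array([1.0]), 40)
            assert abs(x[0] - t0) < 1e-4

    def test_initial_probe_points(self):
        seen = []
        def f(v):
            seen.append(float(v[0]))
            return v[0] ** 2
        golden_section_refine(f, np.array([0.0]), np.array([1.0]), 2)
        assert sorted(np.round(seen, 3)) == [0.382, 0.618]

    def test_symmetric_function_midpoint(self):
        x, _ = golden_section_refine(lambda v: abs(v[0] - 0.5),
                                     np.array([0.0]), np.array([1.0]), 30)
        assert abs(x[0] - 0.5) < 1e-3

    def test_contracts(self):
        with pytest.raises(ValueError):
            golden_section_refine(sphere, np.zeros(2), np.zeros(2), 10)
        with pytest.raises(ValueError):
            golden_section_refine(sphere, np.zeros(2), np.ones(2), 1)

    def test_grid_oracle_agreement(self):
        """Line-search minimum matches a 10^4-point exhaustive grid."""
        rng = np.random.default_rng(3)
        grid = np.linspace(0, 1, 10_000)
        for _ in range(20):
            a, t0 = rng.uniform(0.5, 5.0), rng.uniform(0.0, 1.0)
            f1 = lambda t: a * (t - t0) ** 2
            fvec = lambda v: f1(v[0])
            x, _ = golden_section_refine(fvec, np.array([0.0]), np.array([1.0]), 40)
            t_grid = grid[np.argmin(f1(grid))]
            assert abs(x[0] - t_grid) < 1e-3


class TestOptimize:
    def test_history_non_increasing(self):
        cfg = GFSConfig(population_size=10, iterations=30, lower=-5.0,
                        upper=5.0, seed=2)
        _, _, hist = gfs_optimize(sphere, 3, cfg)
        assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))

    def test_single_iteration_no_worse_than_init(self):
        cfg = GFSConfig(population_size=8, iterations=1, lower=-5.0,
                        upper=5.0, seed=4)
        state = init_population(sphere, 3, cfg, np.random.default_rng(4))
        _, best, _ = gfs_optimize(sphere, 3, cfg)
        assert best <= state.global_best_fitness

    def test_non_finite_objective_aborts(self):
        cfg = GFSConfig(population_size=5, iterations=3, lower=-1.0,
                        upper=1.0, seed=0)
        with pytest.raises(FloatingPointError):
            gfs_optimize(lambda x: float("nan"), 2, cfg)

    def test_sphere_quick_convergence(self):
        cfg = GFSConfig(population_size=15, iterations=60, lower=-5.0,
                        upper=5.0, seed=1)
        _, best, _ = gfs_optimize(sphere, 3, cfg)
        assert best < 1e-2


class TestSelection:
    def _problem(self, seed, n=300, noise_cols=2):
        rng = np.random.default_rng(seed)
        x0 = rng.uniform(size=n)
        X = np.column_stack([x0] + [rng.uniform(size=n) for _ in range(noise_cols)])
        y = (x0 + 0.1 * rng.normal(size=n) > 0.5).astype(int)
        return FeatureSelectionProblem(X=X, y=y, cv_seed=seed)

    def test_single_informative_column_always_found(self):
        cfg_base = GFSConfig(population_size=10, iterations=30)
        for seed in range(10):
            prob = self._problem(seed)
            mask, _, _ = select_features(
                prob, GFSConfig(population_size=10, iterations=30, seed=seed))
            assert mask[0], f"informative column missed at seed {seed}"

    def test_sparsity_pressure_monotone(self):
        """Removing the sparsity term (w_a = 1) can only grow the mask."""
        sizes = {1.0: [], 0.7: []}
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            n = 250
            x0 = rng.uniform(size=n)
            X = np.column_stack([x0] + [rng.uniform(size=n) for _ in range(5)])
            y = (x0 > 0.5).astype(int)
            for w in (1.0, 0.7):
                prob = FeatureSelectionProblem(X=X, y=y, accuracy_weight=w,
                                               cv_seed=seed)
                mask, _, _ = select_features(
                    prob, GFSConfig(population_size=10, iterations=25, seed=seed))
                sizes[w].append(mask.sum())
        assert np.mean(sizes[1.0]) >= np.mean(sizes[0.7])

    def test_constant_columns_fall_back_to_majority(self):
        X = np.zeros((40, 3))
        y = np.array([0] * 30 + [1] * 10)
        prob = FeatureSelectionProblem(X=X, y=y)
        acc = prob.subset_accuracy(np.array([True, False, False]))
        assert acc == pytest.approx(0.75)

    def test_empty_mask_promotes_largest_coordinate(self):
        mask = FeatureSelectionProblem.binarize(np.array([0.2, 0.4, 0.1]))
        assert mask.tolist() == [False, True, False]
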