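import numpy as np
import pytest

from cellopt.ga import GAConfig, decode, evolve, multi_run


def sphere_fitness(x):
    """Concave test objective with its maximum (100) at the origin."""
    return 100.0 - float(np.sum(np.asarray(x) ** 2))


class TestConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(crossover_prob=1.5)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(bounds=((1.0, -1.0), (-1, 1), (-1, 1)))


class TestDecode:
    def test_corner_codes(self):
        cfg = GAConfig()
        np.testing.assert_allclose(decode(np.zeros(48, dtype=int), cfg), [-1.68] * 3)
        np.testing.assert_allclose(decode(np.ones(48, dtype=int), cfg), [1.68] * 3)

    def test_two_bit_enumeration(self):
        # levels for 2 bits on [0, 3]: 00->0, 01->1, 10->2, 11->3 (MSB first)
        cfg = GAConfig(bits_per_var=2, bounds=((0, 3), (0, 3), (0, 3)))
        np.testing.assert_allclose(decode([1, 0, 0, 1, 1, 1], cfg), [2.0, 1.0, 3.0])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            decode(np.zeros(47, dtype=int), GAConfig())

    def test_image_inside_bounds(self):
        cfg = GAConfig(bits_per_var=6)
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = decode(rng.integers(0, 2, cfg.chrom_length), cfg)
            assert np.all(x >= -1.68) and np.all(x <= 1.68)


class TestEvolve:
    def test_finds_analytic_optimum_of_sphere(self):
        """With the reference operator rates (weak proportional selection,
        0.24 expected bit flips per child) the search localizes the origin
        to ~0.2 coded units and 0.2 fitness points for most seeds."""
        hits = 0
        for seed in range(10):
            res = evolve(GAConfig(seed=seed), sphere_fitness)
            if np.all(np.abs(res.best_x) <= 0.2) and res.best_fitness >= 99.8:
                hits += 1
        assert hits >= 6

    def test_best_trace_non_decreasing_with_elitism(self):
        for seed in (0, 1, 2, 3, 4):
            res = evolve(GAConfig(seed=seed), sphere_fitness)
            assert np.all(np.diff(res.best_per_generation) >= 0)
            assert res.best_fitness == res.best_per_generation[-1]

    def test_no_variation_operators_keeps_population_constant(self):
        cfg = GAConfig(mutation_prob=0.0, crossover_prob=0.0, elitism=20, seed=5)
        res = evolve(cfg, sphere_fitness)
        np.testing.assert_allclose(res.avg_per_generation, res.avg_per_generation[0])
        np.testing.assert_allclose(res.best_per_generation, res.best_per_generation[0])

    def test_deterministic_given_seed(self):
        a = evolve(GAConfig(seed=7), sphere_fitness)
        b = evolve(GAConfig(seed=7), sphere_fitness)
        np.testing.assert_array_equal(a.best_x, b.best_x)
        np.testing.assert_array_equal(a.best_per_generation, b.best_per_generation)
        np.testing.assert_array_equal(a.avg_per_generation, b.avg_per_generation)

    def test_all_nonpositive_fitness_falls_back_to_uniform(self):
        res = evolve(GAConfig(seed=0, generations=5), lambda x: -1.0)
        assert res.best_fitness == -1.0

    def test_trained_surface_trace_plateaus(self, reference_fit):
        res = evolve(GAConfig(seed=3), lambda c: float(reference_fit.predict(coded=c)))
        assert np.all(np.diff(res.best_per_generation) >= 0)
        # once converged the best trace remains unchanged
        assert res.best_per_generation[-1] == res.best_per_generation[-5]


def multimodal_fitness(x):
    x = np.asarray(x)
    return float(
        70 + 15 * np.sin(2.0 * x[0]) - 4 * (x[1] - 0.5) ** 2
        + 6 * np.cos(x[2]) + 2 * x[0] * x[2]
    )


def linear_fitness(x):
    x = np.asarray(x)
    return float(50 + 5 * x[0] + 3 * x[1] + 4 * x[2])


class TestAgainstExhaustiveEnumeration:
    """On small (9-bit) chromosomes every point can be enumerated, so the
    evolved best can be compared with the exact global maximum.  The per-bit
    mutation rate is raised to keep the expected flips per chromosome at the
    level the 48-bit reference settings imply (~0.2)."""

    @pytest.mark.parametrize(
        "fitness", [sphere_fitness, multimodal_fitness, linear_fitness]
    )
    def test_small_landscapes_reach_global_max(self, fitness):
        cfg0 = GAConfig(bits_per_var=3, mutation_prob=0.02)
        length = cfg0.chrom_length
        best = -np.inf
        for code in range(2**length):
            bits = [(code >> (length - 1 - i)) & 1 for i in range(length)]
            best = max(best, fitness(decode(np.array(bits), cfg0)))

        n_seeds = 40
        hits = sum(
            evolve(GAConfig(bits_per_var=3, mutation_prob=0.02, seed=seed),
                   fitness).best_fitness >= best - 1e-9
            for seed in range(n_seeds)
        )
        assert hits / n_seeds >= 0.95


class TestMultiRun:
    def test_single_run_ranges_collapse(self):
        s = multi_run(GAConfig(n_runs=1, seed=0), sphere_fitness)
        assert s.max_range[0] == s.max_range[1] == s.mean_of_max
        assert s.min_range[0] == s.min_range[1]

    def test_quadratic_mean_of_max_near_analytic_optimum(self):
        s = multi_run(GAConfig(n_runs=10, seed=0), sphere_fitness)
        assert s.mean_of_max == pytest.approx(100.0, abs=0.5)
        assert s.min_range[0] <= s.avg_range[0] <= s.max_range[1]

    def test_invariants_of_summary(self):
        s = multi_run(GAConfig(n_runs=8, seed=3), sphere_fitness)
        assert s.max_range[0] <= s.mean_of_max <= s.max_range[1]
        assert s.best_overall_fitness == s.max_range[1]

    def test_actual_units_mapping(self):
        from cellopt.design import REFERENCE_FACTORS, coded_to_actual

        s = multi_run(GAConfig(n_runs=2, seed=1), sphere_fitness, factors=REFERENCE_FACTORS)
        np.testing.assert_allclose(
            s.best_overall_x_actual, coded_to_actual(s.best_overall_x, REFERENCE_FACTORS)
        )
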