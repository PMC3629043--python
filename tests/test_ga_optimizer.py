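"""GA operators: selection, crossover, mutation, and the evolution loop."""

import numpy as np
import pytest

import waveopt as w
from waveopt.ga_optimizer import (
    FitnessRecord,
    GAConfig,
    nearest_rank_percentile_index,
)
from waveopt.inverse_model import WavelengthSet


class TestPercentileSelection:
    def test_five_percentiles_of_three_summaries_give_15_indices(self):
        rng = np.random.default_rng(1)
        summaries = rng.uniform(1, 100, size=(40, 3))
        idx = w.select_percentile_spectra(summaries)
        assert len(idx) == 15
        assert all(0 <= i < 40 for i in idx)

    def test_identical_values_select_same_index(self):
        summaries = np.ones((10, 3))
        idx = w.select_percentile_spectra(summaries)
        for block in (idx[0:5], idx[5:10], idx[10:15]):
            assert len(set(block)) == 1

    def test_nearest_rank_matches_sort_oracle(self):
        values = np.array([7, 1, 9, 3, 5, 10, 2, 8, 4, 6], dtype=float)
        sorted_values = np.sort(values)
        for p in (10, 25, 50, 75, 90):
            got = values[nearest_rank_percentile_index(values, p)]
            # brute-force oracle: nearest-rank = ceil(p/100 * n)-th smallest
            want = sorted_values[int(np.ceil(p / 100 * values.size)) - 1]
            assert got == want

    def test_1_to_10_examples(self):
        values = np.arange(1.0, 11.0)
        for p, expected in ((10, 1.0), (50, 5.0), (90, 9.0)):
            assert values[nearest_rank_percentile_index(values, p)] == expected

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            w.select_percentile_spectra(np.empty((0, 3)))


class TestInitPopulation:
    def test_shapes_and_distinctness(self, grid10):
        config = GAConfig(grid=grid10, n_wavelengths=8, population_size=50,
                          rng_seed=3)
        population = w.init_population(config)
        assert len(population) == 50
        for ws in population:
            assert len(ws) == 8
            assert len(set(ws.wavelengths)) == 8

    def test_full_grid_when_k_equals_count(self, grid10):
        config = GAConfig(grid=grid10, n_wavelengths=grid10.count,
                          population_size=5, elite_count=2, rng_seed=0)
        for ws in w.init_population(config):
            assert ws.wavelengths == tuple(grid10.wavelengths())

    def test_same_seed_same_population(self, grid10):
        config = GAConfig(grid=grid10, n_wavelengths=8, rng_seed=11)
        assert ([ws.wavelengths for ws in w.init_population(config)]
                == [ws.wavelengths for ws in w.init_population(config)])

    def test_k_larger_than_grid_raises(self, grid10):
        with pytest.raises(ValueError):
            GAConfig(grid=grid10, n_wavelengths=17)


class TestFitness:
    def test_rms_of_hand_built_errors(self, grid10):
        ws = WavelengthSet((450, 460, 470), grid10)
        errors = np.array([[3.0, 4.0, 0.0]])
        record = FitnessRecord(ws, errors,
                               float(np.sqrt(np.mean(errors ** 2))))
        assert record.fitness == pytest.approx(np.sqrt((9 + 16) / 3))
        two = np.array([[3.0], [4.0]]).reshape(1, -1)  # errors {3,4}
        rms = float(np.sqrt(np.mean(np.array([3.0, 4.0]) ** 2)))
        assert rms == pytest.approx(3.5355, abs=1e-4)

    def test_full_grid_self_comparison_is_tiny(self, basis, grid10):
        params = w.table1_fixture()[:3]
        spectra = w.simulate_spectra(params, grid10, basis)
        training = w.build_training_set(spectra, basis, n_starts=3, seed=0)
        record = w.fitness(WavelengthSet.full(grid10), training, basis,
                           n_starts=3, seed=0)
        assert record.per_comparison_errors.shape == (3, 3)
        assert record.fitness <= 0.5

    def test_training_set_of_15_gives_45_comparisons(self, basis, grid10):
        params = w.table1_fixture()
        spectra = w.simulate_spectra(params, grid10, basis)
        training = w.build_training_set(spectra, basis, n_starts=2, seed=0)
        subset = WavelengthSet((450, 470, 490, 510, 540, 560, 580, 600),
                               grid10)
        record = w.fitness(subset, training, basis, n_starts=2, seed=0)
        assert record.per_comparison_errors.size == 45


class TestRoulette:
    def test_two_fitness_example_probabilities(self):
        rng = np.random.default_rng(0)
        draws = np.array([w.roulette_select(np.array([1.0, 2.0]), rng)
                          for _ in range(30_000)])
        p0 = np.mean(draws == 0)
        # inverse-fitness probabilities: (2/3, 1/3)
        assert p0 == pytest.approx(2 / 3, abs=3 * np.sqrt(2 / 9 / 30_000))

    def test_equal_fitnesses_are_uniform(self):
        rng = np.random.default_rng(1)
        draws = np.array([w.roulette_select(np.ones(4), rng)
                          for _ in range(20_000)])
        freqs = np.bincount(draws, minlength=4) / draws.size
        assert np.all(np.abs(freqs - 0.25)
                      < 3 * np.sqrt(0.25 * 0.75 / draws.size))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            w.roulette_select(np.array([]), np.random.default_rng(0))


class TestCrossoverMutation:
    def test_identical_parents_give_same_child(self, grid10):
        rng = np.random.default_rng(0)
        p = WavelengthSet((450, 470, 500, 550, 600), grid10)
        assert w.crossover(p, p, rng).wavelengths == p.wavelengths

    def test_disjoint_parents_cut_counts(self, grid10):
        rng = np.random.default_rng(5)
        p1 = WavelengthSet((450, 460, 470, 480), grid10)
        p2 = WavelengthSet((530, 540, 550, 560), grid10)
        child = w.crossover(p1, p2, rng)
        from_p1 = sum(v in p1.wavelengths for v in child.wavelengths)
        from_p2 = sum(v in p2.wavelengths for v in child.wavelengths)
        assert from_p1 + from_p2 == 4 and 1 <= from_p1 <= 3

    def test_crossover_validity_sweep(self, grid10):
        rng = np.random.default_rng(7)
        points = grid10.wavelengths()
        for _ in range(1000):
            a = WavelengthSet(tuple(np.sort(rng.choice(points, 6,
                                                       replace=False))),
                              grid10)
            b = WavelengthSet(tuple(np.sort(rng.choice(points, 6,
                                                       replace=False))),
                              grid10)
            child = w.crossover(a, b, rng)
            assert len(child) == 6
            assert len(set(child.wavelengths)) == 6
            assert all(v in grid10 for v in child.wavelengths)

    def test_length_mismatch_raises(self, grid10):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            w.crossover(WavelengthSet((450, 460), grid10),
                        WavelengthSet((450, 460, 470), grid10), rng)

    def test_mutation_validity_sweep_and_bounds(self, grid10):
        rng = np.random.default_rng(8)
        points = grid10.wavelengths()
        for _ in range(1000):
            parent = WavelengthSet(tuple(np.sort(rng.choice(points, 5,
                                                            replace=False))),
                                   grid10)
            child = w.mutate(parent, sigma_nm=30.0, rng=rng)
            assert len(child) == 5
            assert len(set(child.wavelengths)) == 5
            assert all(450 <= v <= 600 and v in grid10
                       for v in child.wavelengths)

    def test_tiny_sigma_rarely_changes_anything(self, grid10):
        rng = np.random.default_rng(9)
        parent = WavelengthSet((450, 480, 510, 540, 570), grid10)
        unchanged = sum(
            w.mutate(parent, sigma_nm=1e-6, rng=rng).wavelengths
            == parent.wavelengths
            for _ in range(200))
        assert unchanged == 200  # snaps back to the same grid point

    def test_boundary_set_stays_in_range(self, grid10):
        rng = np.random.default_rng(10)
        parent = WavelengthSet((450, 460, 580, 590, 600), grid10)
        for _ in range(500):
            child = w.mutate(parent, sigma_nm=100.0, rng=rng)
            assert min(child.wavelengths) >= 450
            assert max(child.wavelengths) <= 600

    def test_invalid_sigma_raises(self, grid10):
        with pytest.raises(ValueError):
            w.mutate(WavelengthSet((450, 460), grid10), 0.0,
                     np.random.default_rng(0))


def _counting_fitness(grid):
    """Cheap deterministic fitness: distance to a target set."""
    target = np.array([470.0, 500.0, 540.0, 560.0, 580.0])

    def fn(ws):
        errs = np.abs(np.subtract.outer(ws.as_array(), target)).min(axis=1)
        errors = np.tile(errs.mean(), (1, 3))
        return FitnessRecord(ws, errors, float(errs.mean()) + 1e-9)

    return fn


class TestEvolve:
    def test_offspring_split_default_config(self, grid10):
        config = GAConfig(grid=grid10, n_wavelengths=8)
        offspring = config.population_size - config.elite_count
        assert offspring == 35
        assert int(round(config.crossover_fraction * offspring)) == 7

    def test_stall_termination_on_uniform_population(self, grid10, monkeypatch):
        config = GAConfig(grid=grid10, n_wavelengths=5, population_size=10,
                          elite_count=3, stall_generations=4,
                          max_generations=50, rng_seed=2)
        fixed = WavelengthSet((450, 480, 510, 540, 570), grid10)
        monkeypatch.setattr("waveopt.ga_optimizer.init_population",
                            lambda cfg, rng=None: [fixed] * 10)
        calls = {"n": 0}

        def fn(ws):
            calls["n"] += 1
            return FitnessRecord(ws, np.zeros((1, 3)), 1.0)

        result = w.evolve(config, fitness_fn=fn)
        # identical population + deterministic fitness: improvement is
        # impossible, so the run stalls within stall_generations + 1
        assert result.stalled
        assert result.n_generations <= config.stall_generations + 1

    def test_best_fitness_non_increasing_and_reproducible(self, grid10):
        config = GAConfig(grid=grid10, n_wavelengths=5, population_size=16,
                          elite_count=4, max_generations=25,
                          stall_generations=6, rng_seed=4)
        fn = _counting_fitness(grid10)
        r1 = w.evolve(config, fitness_fn=fn)
        r2 = w.evolve(config, fitness_fn=fn)
        assert r1.best_per_generation == r2.best_per_generation
        assert [ws.wavelengths for ws in r1.final_population] == \
            [ws.wavelengths for ws in r2.final_population]
        hist = r1.best_per_generation
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))
        assert len(r1.top_records) == 3
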