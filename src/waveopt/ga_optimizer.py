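"""Genetic-algorithm wavelength selection with extraction-error fitness.

A candidate solution ("chromosome") is a set of k distinct center
wavelengths on an increment grid.  Its fitness is the RMS of the absolute
percent errors of [THb], [βc], and ⟨µs'⟩ extracted from every training
spectrum at the reduced wavelength set, relative to the full-spectrum
extraction of the same spectrum (15 spectra × 3 parameters = 45
comparisons for the standard training set; lower is better).

One generation: rank by fitness, copy the elite unchanged, then create the
remaining offspring from roulette-selected parents (selection probability
inversely proportional to fitness) — a fixed fraction via single-point
crossover, the rest via Gaussian mutation of one wavelength.  Duplicate
wavelengths created by either operator are repaired by discarding the
duplicate and inserting a fresh uniformly drawn grid wavelength.  The run
stops when the best fitness has stalled for a fixed number of generations
or at the generation cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .forward_model import (
    DEFAULT_GEOMETRY,
    GeometryConfig,
    PhotonRecordSet,
    ReflectanceSpectrum,
)
from .inverse_model import (
    ExtractionResult,
    WavelengthSet,
    extract_properties,
    extraction_errors,
)
from .optics_core import AbsorberSpectrum, WavelengthGrid

#: Percent error charged per parameter when an extraction fails outright.
FAILED_EXTRACTION_PENALTY = 100.0

#: Floor applied to fitness values before inversion for roulette weights.
ROULETTE_EPS = 1e-12

#: Relative tolerance for "unchanged best fitness" in stall detection.
STALL_RTOL = 1e-9


@dataclass(frozen=True)
class GAConfig:
    grid: WavelengthGrid
    n_wavelengths: int = 8
    population_size: int = 50
    elite_count: int = 15
    crossover_fraction: float = 0.20
    mutation_sigma_nm: float | None = None  # default: 3 × grid step
    max_generations: int = 50
    stall_generations: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.crossover_fraction <= 1:
            raise ValueError("crossover_fraction must lie in [0, 1]")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")
        if self.n_wavelengths > self.grid.count:
            raise ValueError("n_wavelengths exceeds the number of grid points")

    @property
    def sigma_nm(self) -> float:
        if self.mutation_sigma_nm is not None:
            return self.mutation_sigma_nm
        return 3.0 * self.grid.step_nm


@dataclass(frozen=True)
class FitnessRecord:
    wavelength_set: WavelengthSet
    per_comparison_errors: np.ndarray  # (n_samples, 3) signed percent errors
    fitness: float

    def __post_init__(self) -> None:
        errs = np.asarray(self.per_comparison_errors, dtype=float)
        if errs.ndim != 2 or errs.shape[1] != 3:
            raise ValueError("per-comparison errors must be (n_samples, 3)")
        if self.fitness < 0:
            raise ValueError("fitness must be non-negative")
        object.__setattr__(self, "per_comparison_errors", errs)


@dataclass(frozen=True)
class TrainingSet:
    """Spectra plus their full-spectrum reference extractions."""

    spectra: tuple[ReflectanceSpectrum, ...]
    reference_extractions: tuple[ExtractionResult, ...]

    def __post_init__(self) -> None:
        if len(self.spectra) != len(self.reference_extractions):
            raise ValueError("spectra and reference extractions must align")
        if not all(r.converged for r in self.reference_extractions):
            raise ValueError("all reference extractions must have converged")

    def __len__(self) -> int:
        return len(self.spectra)


# ---------------------------------------------------------------------------
# training-set selection
# ---------------------------------------------------------------------------

def nearest_rank_percentile_index(values: np.ndarray, p: float) -> int:
    """Index (into ``values``) of the nearest-rank empirical p-th percentile."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty population")
    order = np.argsort(values, kind="stable")
    rank = int(np.ceil(p / 100.0 * values.size))  # 1-based nearest rank
    rank = min(max(rank, 1), values.size)
    # ties resolve to the first sample holding the percentile value, so a
    # population of identical values selects one canonical index
    return int(np.flatnonzero(values == values[order[rank - 1]])[0])


def select_percentile_spectra(summaries: np.ndarray,
                              percentiles: Sequence[float] = (10, 25, 50, 75, 90),
                              ) -> list[int]:
    """Training-set indices at empirical-cdf percentiles of each summary.

    ``summaries`` is (n_samples, 3): columns [THb], [βc], ⟨µs'⟩.  For each
    summary in turn, the sample at each nearest-rank percentile is chosen;
    with 5 percentiles this yields 15 indices (duplicates permitted when
    the same sample sits at a percentile of more than one summary).
    """
    summaries = np.asarray(summaries, dtype=float)
    if summaries.ndim != 2:
        raise ValueError("summaries must be a 2-D (n_samples, n_params) array")
    if summaries.shape[0] < len(percentiles):
        raise ValueError("population smaller than the number of percentiles")
    out: list[int] = []
    for col in range(summaries.shape[1]):
        for p in percentiles:
            out.append(nearest_rank_percentile_index(summaries[:, col], p))
    return out


def build_training_set(spectra: Sequence[ReflectanceSpectrum],
                       basis: Mapping[str, AbsorberSpectrum],
                       model: str = "diffusion",
                       geometry: GeometryConfig = DEFAULT_GEOMETRY,
                       records: PhotonRecordSet | None = None,
                       n_starts: int = 5,
                       seed: int = 0) -> TrainingSet:
    """Full-grid reference extraction of every spectrum."""
    refs = []
    for spectrum in spectra:
        full = WavelengthSet.full(spectrum.grid)
        refs.append(extract_properties(spectrum, full, basis, model=model,
                                       geometry=geometry, records=records,
                                       n_starts=n_starts, seed=seed))
    return TrainingSet(tuple(spectra), tuple(refs))


# ---------------------------------------------------------------------------
# GA operators
# ---------------------------------------------------------------------------

def init_population(config: GAConfig,
                    rng: np.random.Generator | None = None) -> list[WavelengthSet]:
    """Uniform random wavelength combinations, without replacement."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    points = config.grid.wavelengths()
    population = []
    for _ in range(config.population_size):
        chosen = rng.choice(points, size=config.n_wavelengths, replace=False)
        population.append(WavelengthSet(tuple(np.sort(chosen)), config.grid))
    return population


def fitness(wavelength_set: WavelengthSet, training: TrainingSet,
            basis: Mapping[str, AbsorberSpectrum],
            model: str = "diffusion",
            geometry: GeometryConfig = DEFAULT_GEOMETRY,
            records: PhotonRecordSet | None = None,
            n_starts: int = 2,
            seed: int = 0,
            penalty: float = FAILED_EXTRACTION_PENALTY) -> FitnessRecord:
    """RMS of the absolute percent extraction errors across the training set.

    Each training spectrum contributes 3 comparisons (THb, βc, ⟨µs'⟩) of
    the reduced-set extraction against the stored full-spectrum reference.
    A failed extraction contributes the penalty error for each parameter.
    """
    errors = np.empty((len(training), 3))
    for i, (spectrum, reference) in enumerate(
            zip(training.spectra, training.reference_extractions)):
        try:
            reduced = extract_properties(spectrum, wavelength_set, basis,
                                         model=model, geometry=geometry,
                                         records=records, n_starts=n_starts,
                                         seed=seed)
        except Exception:
            errors[i] = penalty
            continue
        if not np.isfinite(reduced.residual_norm):
            errors[i] = penalty
            continue
        errors[i] = extraction_errors(reduced, reference)
    value = float(np.sqrt(np.mean(np.abs(errors) ** 2)))
    return FitnessRecord(wavelength_set, errors, value)


def roulette_select(fitnesses: np.ndarray,
                    rng: np.random.Generator) -> int:
    """Sample a parent index with probability ∝ 1/fitness."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("empty fitness array")
    weights = 1.0 / np.maximum(f, ROULETTE_EPS)
    return int(rng.choice(f.size, p=weights / weights.sum()))


def _repair_duplicates(values: list[float], grid: WavelengthGrid,
                       rng: np.random.Generator) -> list[float]:
    """Discard duplicates; insert fresh uniform grid wavelengths not present."""
    points = grid.wavelengths()
    seen: list[float] = []
    dups = 0
    for v in values:
        if v in seen:
            dups += 1
        else:
            seen.append(v)
    for _ in range(dups):
        candidates = points[~np.isin(points, seen)]
        seen.append(float(rng.choice(candidates)))
    return sorted(seen)


def crossover(parent1: WavelengthSet, parent2: WavelengthSet,
              rng: np.random.Generator) -> WavelengthSet:
    """Single-point crossover of two (sorted) wavelength sets.

    A uniform random cut splits both parents; the child takes the head of
    one and the tail of the other, then duplicate wavelengths are repaired.
    """
    if len(parent1) != len(parent2):
        raise ValueError("parents must have equal length")
    k = len(parent1)
    cut = int(rng.integers(1, k)) if k > 1 else 0
    child = list(parent1.wavelengths[:cut]) + list(parent2.wavelengths[cut:])
    return WavelengthSet(tuple(_repair_duplicates(child, parent1.increment_grid,
                                                  rng)), parent1.increment_grid)


def mutate(parent: WavelengthSet, sigma_nm: float,
           rng: np.random.Generator) -> WavelengthSet:
    """Gaussian mutation of one uniformly chosen wavelength.

    The chosen wavelength is perturbed by N(0, σ²), snapped to the nearest
    grid point, clamped to the grid range, and duplicate-repaired.
    """
    if sigma_nm <= 0:
        raise ValueError("sigma_nm must be positive")
    grid = parent.increment_grid
    values = list(parent.wavelengths)
    pos = int(rng.integers(0, len(values)))
    values[pos] = grid.snap(values[pos] + rng.normal(0.0, sigma_nm))
    return WavelengthSet(tuple(_repair_duplicates(values, grid, rng)), grid)


# ---------------------------------------------------------------------------
# the evolution loop
# ---------------------------------------------------------------------------

@dataclass
class EvolveResult:
    best_per_generation: list[float]
    final_population: list[WavelengthSet]
    final_fitnesses: list[float]
    top_records: list[FitnessRecord]
    n_generations: int
    stalled: bool

    @property
    def top3(self) -> list[WavelengthSet]:
        return [r.wavelength_set for r in self.top_records[:3]]


def evolve(config: GAConfig,
           training: TrainingSet | None = None,
           basis: Mapping[str, AbsorberSpectrum] | None = None,
           fitness_fn: Callable[[WavelengthSet], FitnessRecord] | None = None,
           model: str = "diffusion",
           geometry: GeometryConfig = DEFAULT_GEOMETRY,
           records: PhotonRecordSet | None = None,
           inverse_n_starts: int = 2,
           progress: Callable[[int, float], None] | None = None) -> EvolveResult:
    """Run the GA and return the fitness history plus the top-ranked sets.

    ``fitness_fn`` may replace the default training-set fitness (useful for
    custom objectives); fitness values are memoized per unique wavelength
    set, so elites and rediscovered solutions cost nothing to re-rank.
    """
    if fitness_fn is None:
        if training is None or basis is None:
            raise ValueError("either fitness_fn or (training, basis) is required")

        def fitness_fn(ws: WavelengthSet) -> FitnessRecord:
            return fitness(ws, training, basis, model=model, geometry=geometry,
                           records=records, n_starts=inverse_n_starts,
                           seed=config.rng_seed)

    rng = np.random.default_rng(config.rng_seed)
    cache: dict[tuple[float, ...], FitnessRecord] = {}

    def evaluate(ws: WavelengthSet) -> FitnessRecord:
        key = ws.wavelengths
        if key not in cache:
            cache[key] = fitness_fn(ws)
        return cache[key]

    population = init_population(config, rng)
    n_offspring = config.population_size - config.elite_count
    n_cross = int(round(config.crossover_fraction * n_offspring))
    best_history: list[float] = []
    stall = 0
    stalled = False

    for _generation in range(config.max_generations):
        records_now = [evaluate(ws) for ws in population]
        order = np.argsort([r.fitness for r in records_now], kind="stable")
        population = [population[i] for i in order]
        records_now = [records_now[i] for i in order]
        fitnesses = np.array([r.fitness for r in records_now])

        best = float(fitnesses[0])
        if best_history and abs(best - best_history[-1]) <= STALL_RTOL * max(
                abs(best_history[-1]), 1.0):
            stall += 1
        else:
            stall = 0
        best_history.append(best)
        if progress is not None:
            progress(len(best_history), best)
        if stall >= config.stall_generations:
            stalled = True
            break
        if len(best_history) >= config.max_generations:
            break

        elites = population[:config.elite_count]
        offspring: list[WavelengthSet] = []
        for j in range(n_offspring):
            if j < n_cross:
                p1 = population[roulette_select(fitnesses, rng)]
                p2 = population[roulette_select(fitnesses, rng)]
                offspring.append(crossover(p1, p2, rng))
            else:
                parent = population[roulette_select(fitnesses, rng)]
                offspring.append(mutate(parent, config.sigma_nm, rng))
        population = list(elites) + offspring

    final_records = sorted((evaluate(ws) for ws in population),
                           key=lambda r: r.fitness)
    return EvolveResult(
        best_per_generation=best_history,
        final_population=[r.wavelength_set for r in final_records],
        final_fitnesses=[r.fitness for r in final_records],
        top_records=final_records[:3],
        n_generations=len(best_history),
        stalled=stalled,
    )
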