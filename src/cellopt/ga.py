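"""Binary-coded genetic algorithm over the coded factor cube.

Each candidate is a fixed-length bit string: ``n_vars`` variables at
``bits_per_var`` bits each, most-significant bit first, decoded linearly
onto per-variable bounds.  One generation applies fitness-proportional
(roulette-wheel) selection, single-point crossover on mated pairs,
independent per-bit mutation, and copies the elite individual(s) unchanged,
which makes the best-fitness trace non-decreasing.

The intended fitness is a trained network's predicted efficiency in percent
(strictly positive over the search cube), used directly as the roulette
weight; multi-run aggregation repeats the search from independent seeds and
summarises the per-run maxima, minima and averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .design import coded_to_actual

logger = logging.getLogger(__name__)

__all__ = ["GAConfig", "GARunResult", "MultiRunSummary", "decode", "evolve", "multi_run"]

_CUBE = ((-1.68, 1.68), (-1.68, 1.68), (-1.68, 1.68))


@dataclass(frozen=True)
class GAConfig:
    """Working parameters of the search.

    Defaults follow the reference optimization: 50 generations, population
    20, 3 binary-coded variables, crossover probability 0.4, per-bit
    mutation probability 0.005, searched over the coded CCD cube
    [-1.68, 1.68]^3, 50 independent runs.  ``bits_per_var`` (16) sets the
    decoding resolution, ~5e-5 coded units.
    """

    generations: int = 50
    pop_size: int = 20
    n_vars: int = 3
    bits_per_var: int = 16
    crossover_prob: float = 0.4
    mutation_prob: float = 0.005
    bounds: tuple = _CUBE
    elitism: int = 1
    seed: int = 0
    n_runs: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        if len(bounds) != self.n_vars:
            raise ValueError(f"need {self.n_vars} bounds pairs, got {len(bounds)}")
        if any(lo >= hi for lo, hi in bounds):
            raise ValueError("each bound must satisfy low < high")
        object.__setattr__(self, "bounds", bounds)

    @property
    def chrom_length(self) -> int:
        return self.n_vars * self.bits_per_var


@dataclass(frozen=True)
class GARunResult:
    """Trace and outcome of one evolutionary run."""

    best_x: np.ndarray
    best_fitness: float
    best_per_generation: np.ndarray
    avg_per_generation: np.ndarray
    min_fitness_seen: float
    mean_fitness_final: float
    seed: int


@dataclass(frozen=True)
class MultiRunSummary:
    """Aggregate of independent runs: ranges are (low, high) across runs."""

    max_range: tuple[float, float]
    min_range: tuple[float, float]
    avg_range: tuple[float, float]  # final-generation population means
    avg_over_generations_range: tuple[float, float]  # per-run mean of generation averages
    mean_of_max: float
    best_overall_x: np.ndarray
    best_overall_fitness: float
    best_overall_x_actual: np.ndarray | None = None
    runs: tuple[GARunResult, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "max_range": list(self.max_range),
            "min_range": list(self.min_range),
            "avg_range": list(self.avg_range),
            "avg_over_generations_range": list(self.avg_over_generations_range),
            "mean_of_max": self.mean_of_max,
            "best_overall_x_coded": list(np.asarray(self.best_overall_x)),
            "best_overall_fitness": self.best_overall_fitness,
        }
        if self.best_overall_x_actual is not None:
            d["best_overall_x_actual"] = list(np.asarray(self.best_overall_x_actual))
        return d


def decode(chrom, cfg: GAConfig) -> np.ndarray:
    """Decode a bit string to a coded 3-vector, MSB first per variable."""
    bits = np.asarray(chrom, dtype=int)
    if bits.shape != (cfg.chrom_length,):
        raise ValueError(
            f"chromosome length {bits.size} != n_vars*bits_per_var = {cfg.chrom_length}"
        )
    weights = 2 ** np.arange(cfg.bits_per_var - 1, -1, -1)
    ints = bits.reshape(cfg.n_vars, cfg.bits_per_var) @ weights
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    return lo + ints / (2**cfg.bits_per_var - 1) * (hi - lo)


def _roulette(rng: np.random.Generator, fitness: np.ndarray, k: int) -> np.ndarray:
    if fitness.max() <= 0:
        logger.info("all fitness values <= 0; selection falls back to uniform")
        probs = np.full(len(fitness), 1.0 / len(fitness))
    else:
        w = np.clip(fitness, 0.0, None)
        probs = w / w.sum()
    return rng.choice(len(fitness), size=k, p=probs)


def evolve(cfg: GAConfig, fitness) -> GARunResult:
    """Run one seeded evolutionary search maximizing ``fitness(coded) -> %``."""
    rng = np.random.default_rng(cfg.seed)
    pop = rng.integers(0, 2, size=(cfg.pop_size, cfg.chrom_length))
    best_trace = np.empty(cfg.generations)
    avg_trace = np.empty(cfg.generations)
    min_seen = np.inf
    best_chrom, best_fit = None, -np.inf

    for gen in range(cfg.generations):
        fits = np.array([fitness(decode(ind, cfg)) for ind in pop])
        min_seen = min(min_seen, fits.min())
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_chrom = pop[gen_best].copy()
        best_trace[gen] = fits.max()
        avg_trace[gen] = fits.mean()
        if gen == cfg.generations - 1:
            final_mean = float(fits.mean())
            break
        # next generation: elite(s) unchanged, rest from selection + operators
        elite_idx = np.argsort(fits)[::-1][: cfg.elitism]
        parents = pop[_roulette(rng, fits, cfg.pop_size)]
        children = parents.copy()
        for i in range(0, cfg.pop_size - 1, 2):
            if rng.random() < cfg.crossover_prob:
                point = int(rng.integers(1, cfg.chrom_length))
                children[i, point:], children[i + 1, point:] = (
                    parents[i + 1, point:].copy(),
                    parents[i, point:].copy(),
                )
        if cfg.mutation_prob > 0:
            flips = rng.random(children.shape) < cfg.mutation_prob
            children = np.where(flips, 1 - children, children)
        n_elite = min(cfg.elitism, cfg.pop_size)
        pop = np.vstack([pop[elite_idx[:n_elite]], children[: cfg.pop_size - n_elite]])

    return GARunResult(
        best_x=decode(best_chrom, cfg),
        best_fitness=best_fit,
        best_per_generation=best_trace,
        avg_per_generation=avg_trace,
        min_fitness_seen=float(min_seen),
        mean_fitness_final=final_mean,
        seed=cfg.seed,
    )


def multi_run(cfg: GAConfig, fitness, factors=None) -> MultiRunSummary:
    """Aggregate ``cfg.n_runs`` independent runs (seeds seed, seed+1, ...).

    If ``factors`` is given, the best point is also reported in actual
    units through the coded->actual transform.
    """
    if cfg.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs = []
    for i in range(cfg.n_runs):
        run_cfg = GAConfig(**{**cfg.__dict__, "seed": cfg.seed + i})
        runs.append(evolve(run_cfg, fitness))
    maxima = np.array([r.best_fitness for r in runs])
    minima = np.array([r.min_fitness_seen for r in runs])
    finals = np.array([r.mean_fitness_final for r in runs])
    gen_means = np.array([r.avg_per_generation.mean() for r in runs])
    best_i = int(np.argmax(maxima))
    best_x = runs[best_i].best_x
    return MultiRunSummary(
        max_range=(float(maxima.min()), float(maxima.max())),
        min_range=(float(minima.min()), float(minima.max())),
        avg_range=(float(finals.min()), float(finals.max())),
        avg_over_generations_range=(float(gen_means.min()), float(gen_means.max())),
        mean_of_max=float(maxima.mean()),
        best_overall_x=best_x,
        best_overall_fitness=float(maxima.max()),
        best_overall_x_actual=None if factors is None else coded_to_actual(best_x, factors),
        runs=tuple(runs),
    )
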