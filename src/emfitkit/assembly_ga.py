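"""Genetic-algorithm assembly fitting of multiple rigid components.

Each genome holds one rigid placement per component; fitness is the
chosen map similarity (mutual information by default, CCC selectable)
between the target map and the density simulated from all placed
components, minus a penalty proportional to the fraction of Cα atoms
clashing with another component.  Generations proceed by tournament
selection, uniform per-component crossover, Gaussian pose mutation and
elitism, so the best fitness never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .align import QMCConfig, _quaternion_rotation, _random_rotation_matrix, qmc_global
from .map_core import DensityMap
from .model_core import AtomicModel, RigidTransform, apply_transform, rmsd_ca
from .score_global import GLOBAL_SCORES, HIGHER_IS_BETTER, UndefinedScoreError
from .simulate import SimulationParams, simulate_map

__all__ = ["AssemblyGenome", "GAConfig", "GenerationStats", "fitness", "evolve", "rmsd_trace"]

CLASH_DISTANCE = 3.0  # Å between Calpha atoms of different components


@dataclass
class AssemblyGenome:
    """One candidate assembly: a rigid placement per component."""

    placements: list[RigidTransform]

    def copy(self) -> "AssemblyGenome":
        return AssemblyGenome(
            [RigidTransform(t.rotation.copy(), t.translation.copy(), t.centre.copy())
             for t in self.placements]
        )


@dataclass
class GAConfig:
    pop_size: int = 20
    n_generations: int = 10
    mutation_rate: float = 0.8
    crossover_rate: float = 0.7
    clash_weight: float = 1.0
    elite_count: int = 2
    seed: int = 42
    objective: str = "mi"
    mut_trans_step: float = 3.0  # Å, coarse mutation scale
    mut_rot_step: float = 10.0  # degrees, coarse mutation scale
    refine_steps: int = 48  # greedy elite-improvement trials per generation

    def __post_init__(self) -> None:
        if self.pop_size < 2 or not 0 <= self.elite_count < self.pop_size:
            raise ValueError("need pop_size >= 2 and 0 <= elite_count < pop_size")
        for rate in (self.mutation_rate, self.crossover_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.clash_weight < 0:
            raise ValueError("clash_weight must be >= 0")
        if self.objective not in GLOBAL_SCORES:
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class GenerationStats:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_genome: AssemblyGenome = field(repr=False, default=None)  # type: ignore[assignment]


def _placed(components: list[AtomicModel], genome: AssemblyGenome) -> list[AtomicModel]:
    return [apply_transform(c, t) for c, t in zip(components, genome.placements)]


def _clash_fraction(placed: list[AtomicModel]) -> float:
    """Fraction of Cα atoms within CLASH_DISTANCE of a Cα of another component."""
    cas = [np.array([a.coords for a in m.ca_atoms()]) for m in placed]
    total = sum(len(c) for c in cas)
    if total == 0 or len(cas) < 2:
        return 0.0
    clashing = 0
    for i, own in enumerate(cas):
        if len(own) == 0:
            continue
        others = np.vstack([c for j, c in enumerate(cas) if j != i and len(c)])
        if len(others) == 0:
            continue
        d, _ = cKDTree(others).query(own)
        clashing += int((d < CLASH_DISTANCE).sum())
    return clashing / total


def fitness(
    genome: AssemblyGenome,
    components: list[AtomicModel],
    density_map: DensityMap,
    params: SimulationParams,
    cfg: GAConfig | None = None,
) -> float:
    """Map-similarity score of the placed assembly minus the clash penalty."""
    cfg = cfg or GAConfig()
    if not components:
        raise ValueError("no components to place")
    placed = _placed(components, genome)
    merged = AtomicModel(
        [a for m in placed for a in m.atoms], id="assembly"
    )
    sim = simulate_map(merged, params, grid=density_map)
    fn = GLOBAL_SCORES[cfg.objective]
    sign = 1.0 if HIGHER_IS_BETTER[cfg.objective] else -1.0
    if cfg.objective in ("ccc", "lsf"):
        score = sign * fn(density_map, sim)
    else:
        score = sign * fn(density_map, sim, None)
    return float(score - cfg.clash_weight * _clash_fraction(placed))


def _initial_population(
    components, density_map, params, cfg, rng
) -> list[AssemblyGenome]:
    """Seed placements from a per-component quasi-Monte Carlo scan."""
    centre = 0.5 * (
        np.asarray(density_map.origin)
        + np.asarray(density_map.origin)
        + (np.asarray(density_map.shape) - 1) * np.asarray(density_map.voxel_size)
    )
    per_component: list[list[RigidTransform]] = []
    for comp in components:
        probe = simulate_map(comp, params)
        half = 0.5 * (np.asarray(density_map.shape) - 1) * np.asarray(
            density_map.voxel_size
        )
        offset = centre - comp.centroid()
        bounds = np.stack([offset - half, offset + half], axis=1)
        ranked = qmc_global(
            probe,
            density_map,
            QMCConfig(
                n_samples=max(cfg.pop_size * 8, 128),
                trans_bounds=bounds,
                keep_top=cfg.pop_size,
                seed=int(rng.integers(2**31 - 1)),
            ),
        )
        pool = [t for t, _ in ranked]
        per_component.append(pool)
    population = []
    for i in range(cfg.pop_size):
        placements = []
        for pool in per_component:
            j = i if i < len(pool) else int(rng.integers(len(pool)))
            placements.append(pool[j])
        population.append(AssemblyGenome(placements))
    return population


def _mutate(genome: AssemblyGenome, cfg: GAConfig, rng) -> None:
    """Perturb one component's placement.

    Half of the mutations take fine steps (2 deg, 0.5 Å) for late-stage
    pose refinement, half take the coarse configured steps to escape
    local basins.  The rotation pivots about the component's original
    centroid, so orientation changes do not drag the placed position.
    """
    k = int(rng.integers(len(genome.placements)))
    t = genome.placements[k]
    axis = rng.normal(size=3)
    while np.linalg.norm(axis) < 1e-12:
        axis = rng.normal(size=3)
    if rng.random() < 0.5:
        rot_step, trans_step = 2.0, 0.5
    else:
        rot_step, trans_step = cfg.mut_rot_step, cfg.mut_trans_step
    angle = np.radians(rng.normal(0.0, rot_step))
    shift = rng.normal(0.0, trans_step, size=3)
    rot = _random_rotation_matrix(axis, angle) @ t.rotation
    genome.placements[k] = RigidTransform(rot, t.translation + shift, t.centre)


def evolve(
    components: list[AtomicModel],
    density_map: DensityMap,
    params: SimulationParams,
    cfg: GAConfig | None = None,
    initial_population: list[AssemblyGenome] | None = None,
) -> tuple[AssemblyGenome, list[GenerationStats]]:
    """Run the genetic algorithm and return the best genome plus statistics.

    The population is seeded by a quasi-Monte Carlo placement scan per
    component.  Each generation applies tournament selection (size 2),
    uniform crossover that swaps whole component placements, Gaussian
    pose mutation, and elitism keeping the ``elite_count`` best genomes;
    elites additionally receive ``refine_steps`` greedy improvement
    trials (mutation-style proposals accepted only when fitness rises),
    so the elite best fitness is nondecreasing.  Fully deterministic for
    a fixed seed.
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.seed)

    def fit_of(genome: AssemblyGenome) -> float:
        try:
            return fitness(genome, components, density_map, params, cfg)
        except UndefinedScoreError:
            return float("-inf")  # assembly entirely outside the map

    def refine(genome: AssemblyGenome, value: float) -> tuple[AssemblyGenome, float]:
        for _ in range(cfg.refine_steps):
            trial = genome.copy()
            _mutate(trial, cfg, rng)
            trial_fit = fit_of(trial)
            if trial_fit > value:
                genome, value = trial, trial_fit
        return genome, value

    if initial_population is not None:
        if len(initial_population) != cfg.pop_size:
            raise ValueError("initial_population size must equal pop_size")
        population = [g.copy() for g in initial_population]
    else:
        population = _initial_population(components, density_map, params, cfg, rng)
    fits = [fit_of(g) for g in population]

    stats: list[GenerationStats] = []
    order = np.argsort(fits)[::-1]
    stats.append(
        GenerationStats(0, fits[order[0]], float(np.mean(fits)),
                        population[order[0]].copy())
    )

    for gen in range(1, cfg.n_generations + 1):
        order = np.argsort(fits)[::-1]
        new_pop = [population[i].copy() for i in order[: cfg.elite_count]]
        new_fits = [fits[i] for i in order[: cfg.elite_count]]
        for e in range(len(new_pop)):
            new_pop[e], new_fits[e] = refine(new_pop[e], new_fits[e])
        while len(new_pop) < cfg.pop_size:
            parents = []
            for _ in range(2):
                i, j = rng.integers(cfg.pop_size, size=2)
                parents.append(population[i] if fits[i] >= fits[j] else population[j])
            child = parents[0].copy()
            if rng.random() < cfg.crossover_rate:
                for k in range(len(child.placements)):
                    if rng.random() < 0.5:
                        child.placements[k] = parents[1].placements[k]
                child = child.copy()
            if rng.random() < cfg.mutation_rate:
                _mutate(child, cfg, rng)
            new_pop.append(child)
            new_fits.append(fit_of(new_pop[-1]))
        population, fits = new_pop, new_fits
        order = np.argsort(fits)[::-1]
        stats.append(
            GenerationStats(gen, fits[order[0]], float(np.mean(fits)),
                            population[order[0]].copy())
        )
    best = max(range(len(population)), key=lambda i: fits[i])
    return population[best].copy(), stats


def rmsd_trace(
    stats: list[GenerationStats],
    components: list[AtomicModel],
    truth: list[AtomicModel],
) -> list[float]:
    """Per-generation Cα RMSD of the best genome against the true assembly.

    Purely diagnostic — the true conformation is never available to
    :func:`evolve` itself.
    """
    if len(components) != len(truth):
        raise ValueError("truth must list one model per component")
    out = []
    for s in stats:
        placed = _placed(components, s.best_genome)
        merged_p = AtomicModel([a for m in placed for a in m.atoms])
        merged_t = AtomicModel([a for m in truth for a in m.atoms])
        out.append(rmsd_ca(merged_p, merged_t))
    return out
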