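"""Constrained particle swarm optimization over fixed-size feature subsets.

Each particle lives in a continuous k-dimensional box over the feature
index range; positions decode to subsets of exactly k distinct features
(round, then repair duplicates by advancing to the nearest unused index,
wrapping).  Fitness is the mean stratified-bootstrap c-index of the
decoded Cox model.  The best model over several independent swarms is
refit once on the full training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SurvivalData, ValidationError
from .survival import (
    FitError,
    SurvivalModel,
    bootstrap_cindex,
    fit_cox,
    stratified_bootstrap,
)


@dataclass
class CPSOConfig:
    k: int = 5
    iterations: int = 500
    runs: int = 20  # desk default; the original protocol ran 1000 swarms
    swarm_size: int = 30
    inertia: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    v_max: float = 0.25  # fraction of the index range
    bootstrap_B: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.iterations < 1 or self.runs < 1 or self.swarm_size < 1:
            raise ValidationError("counts must be positive")
        if self.bootstrap_B < 1:
            raise ValidationError("bootstrap_B must be >= 1")


def decode_position(position, feature_count: int) -> tuple:
    """Decode continuous coordinates to k distinct feature indices.

    Coordinates are rounded to the nearest index; a duplicate advances
    upward (wrapping at feature_count) to the nearest unused index.
    """
    position = np.asarray(position, dtype=float)
    k = position.size
    if k > feature_count:
        raise ValidationError("k exceeds the number of features")
    used: set = set()
    out = []
    for coord in np.clip(position, 0, feature_count - 1):
        idx = int(np.floor(coord + 0.5)) % feature_count
        while idx in used:
            idx = (idx + 1) % feature_count
        used.add(idx)
        out.append(idx)
    return tuple(out)


@dataclass
class Swarm:
    positions: np.ndarray  # (swarm_size, k)
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float


def init_swarm(config: CPSOConfig, feature_count: int, rng) -> Swarm:
    hi = feature_count - 1
    pos = rng.uniform(0, hi, size=(config.swarm_size, config.k))
    vmax = config.v_max * hi
    vel = rng.uniform(-vmax, vmax, size=(config.swarm_size, config.k))
    return Swarm(
        positions=pos,
        velocities=vel,
        pbest_positions=pos.copy(),
        pbest_fitness=np.full(config.swarm_size, -np.inf),
        gbest_position=pos[0].copy(),
        gbest_fitness=-np.inf,
    )


def step_swarm(swarm: Swarm, fitness: np.ndarray, config: CPSOConfig,
               feature_count: int, rng) -> Swarm:
    """One velocity/position update; bests update on strict improvement."""
    improved = fitness > swarm.pbest_fitness
    swarm.pbest_fitness[improved] = fitness[improved]
    swarm.pbest_positions[improved] = swarm.positions[improved]
    best = int(np.argmax(swarm.pbest_fitness))
    if swarm.pbest_fitness[best] > swarm.gbest_fitness:
        swarm.gbest_fitness = float(swarm.pbest_fitness[best])
        swarm.gbest_position = swarm.pbest_positions[best].copy()

    shape = swarm.positions.shape
    r1, r2 = rng.random(shape), rng.random(shape)
    hi = feature_count - 1
    vmax = config.v_max * hi
    swarm.velocities = (
        config.inertia * swarm.velocities
        + config.c1 * r1 * (swarm.pbest_positions - swarm.positions)
        + config.c2 * r2 * (swarm.gbest_position[None, :] - swarm.positions)
    )
    np.clip(swarm.velocities, -vmax, vmax, out=swarm.velocities)
    swarm.positions = np.clip(swarm.positions + swarm.velocities, 0, hi)
    return swarm


def run_cpso(X, survival: SurvivalData, config: CPSOConfig,
             sources=None) -> SurvivalModel:
    """Select a k-feature Cox model by repeated constrained PSO.

    ``X`` is an OmicsMatrix/MergedMatrix-like object (``.df`` features x
    patients, ``.source_of``).  Fitness within a run reuses one fixed set
    of stratified bootstrap resamples, so identical subsets share a
    deterministic, memoizable fitness.
    """
    df = X.df.T  # patients x features
    values = df.to_numpy(dtype=float)
    feature_ids = list(df.columns)
    p = len(feature_ids)
    if config.k > p:
        raise ValidationError("k exceeds the number of features")
    master = np.random.SeedSequence(config.seed)
    run_seeds = master.spawn(config.runs)

    best_subset, best_fitness = None, -np.inf
    for run_seed in run_seeds:
        boot_seed, pso_seed = run_seed.spawn(2)
        resamples = [
            stratified_bootstrap(survival, s)
            for s in boot_seed.spawn(config.bootstrap_B)
        ]
        cache: dict = {}

        def fitness_of(subset: tuple) -> float:
            key = tuple(sorted(subset))
            if key not in cache:
                try:
                    cache[key] = bootstrap_cindex(
                        values[:, list(key)], survival,
                        B=config.bootstrap_B, resamples=resamples,
                    )
                except FitError:
                    cache[key] = -np.inf
            return cache[key]

        rng = np.random.default_rng(pso_seed)
        swarm = init_swarm(config, p, rng)
        for _ in range(config.iterations):
            fits = np.array([
                fitness_of(decode_position(pos, p)) for pos in swarm.positions
            ])
            swarm = step_swarm(swarm, fits, config, p, rng)
        if swarm.gbest_fitness > best_fitness:
            best_fitness = swarm.gbest_fitness
            best_subset = decode_position(swarm.gbest_position, p)

    if best_subset is None or not np.isfinite(best_fitness):
        raise FitError("no CPSO run produced a fittable model")
    chosen = [feature_ids[i] for i in best_subset]
    final = fit_cox(df[chosen], survival)
    srcs = [X.source_of(f) for f in chosen]
    return SurvivalModel(
        feature_ids=chosen,
        sources=srcs,
        beta=final.beta,
        selector="CPSO",
        fitness=float(best_fitness),
        fit=final,
        extras={"k": config.k, "runs": config.runs},
    )
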