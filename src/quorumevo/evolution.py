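"""The generational loop: found groups, evaluate, select, mutate, repeat.

A Wright-Fisher-like scheme with non-overlapping generations and a fixed
propagule-pool size. Each generation:

1. the pool is scattered into sub-populations under the mixing regime;
2. every individual is scored across the density grid (mean payoff);
3. ``pool_size`` offspring are drawn by multinomial selection with weights
   ``payoff - min(payoff) + eps`` (payoffs can sit on an arbitrary scale,
   so weights are shifted to be non-negative while preserving order; if all
   payoffs tie the draw is uniform — pure drift);
4. offspring mutate per the mutation model;
5. optionally a fixed fraction of offspring is replaced by immutable
   constitutive cheats (cheat injection).

Runs are bit-reproducible given (config, seed). Replicates derive their
seeds deterministically from a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_dynamics import DynamicsParams, SignalEnvironment
from .fitness import DensityGrid, GroupEvaluation, PayoffParams, build_density_grid, evaluate_pool_groups
from .population import (
    CHEAT_LINEAGE,
    Genotype,
    MixingConfig,
    MutationModel,
    Population,
    TraitBounds,
    group_sizes_for_pool,
    make_cheat,
    mutate_population,
)

__all__ = [
    "RECORD_COLUMNS",
    "SCHEMA_VERSION",
    "SimulationConfig",
    "GenerationRecord",
    "SimulationResult",
    "ReplicateSet",
    "run_generation",
    "run_simulation",
    "summarize_last_k",
    "run_replicates",
    "records_to_frame",
]

SCHEMA_VERSION = 1
RECORD_COLUMNS = [
    "generation",
    "p_mean",
    "p_sd",
    "s_th_mean",
    "s_th_sd",
    "r_mean",
    "r_sd",
    "payoff_mean",
    "coop_fraction",
    "n_lineages",
    "cheat_fraction",
]

_SUMMARY_FIELDS = [
    "p_mean",
    "s_th_mean",
    "r_mean",
    "payoff_mean",
    "coop_fraction",
    "n_lineages",
    "cheat_fraction",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one evolutionary run.

    Defaults mirror the full-scale study conditions (pool of 5,000 evolving
    for 5,000 generations on the 100-density grid); desk-scale work uses
    ``scaled()`` or the presets.
    """

    pool_size: int = 5000
    generations: int = 5000
    mixing: MixingConfig = MixingConfig(fixed_g=1)
    mutation: MutationModel = MutationModel()
    payoff: PayoffParams = PayoffParams()
    dynamics: DynamicsParams = DynamicsParams()
    bounds: TraitBounds = TraitBounds()
    u: float = 1e-4
    m: float = 0.0
    noise_sd: float = 0.0
    grid_low: float = 10.0**1.5
    grid_high: float = 1e5
    grid_count: int = 100
    init_p: float = 1e-9
    init_s_th: float = 10.0
    init_r: float = 0.0
    cheat_injection_rate: float = 0.0
    summary_window: int = 50

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 <= self.cheat_injection_rate <= 1.0:
            raise ValueError("cheat_injection_rate must be in [0, 1]")
        if self.summary_window < 1:
            raise ValueError("summary_window must be >= 1")
        if self.u <= 0 or self.m < 0 or self.noise_sd < 0:
            raise ValueError("need u > 0, m >= 0, noise_sd >= 0")
        for name in ("init_p", "init_s_th", "init_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def build_grid(self) -> DensityGrid:
        return build_density_grid(self.grid_low, self.grid_high, self.grid_count)

    def build_env(self, N: float = 1.0) -> SignalEnvironment:
        return SignalEnvironment(N=N, u=self.u, m=self.m, noise_sd=self.noise_sd)

    def initial_genotype(self) -> Genotype:
        return Genotype(p=self.init_p, S_Th=self.init_s_th, r=self.init_r)

    def scaled(self, factor: float, min_pool: int = 50, min_generations: int = 20) -> "SimulationConfig":
        """Down-sample pool size and generations by ``factor`` for desk runs."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return replace(
            self,
            pool_size=max(min_pool, int(round(self.pool_size * factor))),
            generations=max(min_generations, int(round(self.generations * factor))),
        )


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation population summary."""

    generation: int
    p_mean: float
    p_sd: float
    s_th_mean: float
    s_th_sd: float
    r_mean: float
    r_sd: float
    payoff_mean: float
    coop_fraction: float
    n_lineages: int
    cheat_fraction: float

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, c) for c in RECORD_COLUMNS)


@dataclass
class SimulationResult:
    """Outcome of one run: record stream plus final-generation state.

    ``final_eval``/``final_order``/``final_sizes`` describe the last
    generation's grouping and evaluation (members of ``final_pool`` appear
    in ``final_order`` within the evaluation); ``parent_indices`` maps each
    individual of the returned offspring pool back to its parent in
    ``final_pool``, supporting parent-offspring selection analyses.
    """

    config: SimulationConfig
    seed: int
    records: list[GenerationRecord]
    final_pool: Population
    offspring_pool: Population
    final_eval: GroupEvaluation
    final_order: np.ndarray
    final_sizes: np.ndarray
    parent_indices: np.ndarray

    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def records_to_frame(records: Sequence[GenerationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_tuple() for r in records], columns=RECORD_COLUMNS)


def _selection_probabilities(fitness: np.ndarray) -> np.ndarray:
    span = float(fitness.max() - fitness.min())
    if span == 0.0 or not np.isfinite(span):
        return np.full(fitness.size, 1.0 / fitness.size)
    eps = 1e-9 * span
    w = fitness - fitness.min() + eps
    return w / w.sum()


def _summarize_pool(
    generation: int, pop: Population, evaluation: GroupEvaluation
) -> GenerationRecord:
    return GenerationRecord(
        generation=generation,
        p_mean=float(pop.p.mean()),
        p_sd=float(pop.p.std()),
        s_th_mean=float(pop.s_th.mean()),
        s_th_sd=float(pop.s_th.std()),
        r_mean=float(pop.r.mean()),
        r_sd=float(pop.r.std()),
        payoff_mean=float(evaluation.fitness.mean()),
        coop_fraction=float(evaluation.on.mean()),
        n_lineages=pop.n_lineages(),
        cheat_fraction=float(pop.immutable.mean()),
    )


class _Engine:
    """Mutable per-run state (rng, lineage counter) around the pure steps."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.grid = config.build_grid()
        self.env = config.build_env(N=config.grid_high)
        self.next_lineage = 1

    def step(self, pop: Population) -> tuple[Population, GenerationRecord, dict]:
        cfg = self.config
        n = len(pop)
        sizes = group_sizes_for_pool(n, cfg.mixing, self.rng)
        order = self.rng.permutation(n)
        grouped = pop.take(order)
        evaluation = evaluate_pool_groups(
            grouped, sizes, self.grid, self.env, cfg.dynamics, cfg.payoff, rng=self.rng
        )
        # fitness back in original pool order
        fitness = np.empty(n)
        fitness[order] = evaluation.fitness
        probs = _selection_probabilities(fitness)
        parents = self.rng.choice(n, size=n, p=probs)
        offspring, mutated = mutate_population(
            pop.take(parents), cfg.mutation, cfg.bounds, self.rng, self.next_lineage
        )
        self.next_lineage += int(mutated.sum())
        if cfg.cheat_injection_rate > 0.0:
            k = int(round(cfg.cheat_injection_rate * n))
            if k > 0:
                cheat = make_cheat(cfg.bounds)
                idx = self.rng.choice(n, size=k, replace=False)
                offspring.p[idx] = cheat.p
                offspring.s_th[idx] = cheat.S_Th
                offspring.r[idx] = cheat.r
                offspring.immutable[idx] = True
                offspring.lineage[idx] = CHEAT_LINEAGE
        record = _summarize_pool(-1, pop, evaluation)
        detail = {
            "evaluation": evaluation,
            "order": order,
            "sizes": sizes,
            "parents": parents,
        }
        return offspring, record, detail


def run_generation(
    pop: Population, config: SimulationConfig, rng: np.random.Generator
) -> tuple[Population, GenerationRecord]:
    """Advance one generation; summary describes the *evaluated* pool."""
    if len(pop) != config.pool_size:
        raise ValueError("pool size must match config.pool_size")
    engine = _Engine(config, rng)
    engine.next_lineage = int(pop.lineage.max()) + 1
    offspring, record, _ = engine.step(pop)
    return offspring, replace(record, generation=0)


def run_simulation(
    config: SimulationConfig, seed: int, initial_pool: Population | None = None
) -> SimulationResult:
    """Run the full generational loop; deterministic given (config, seed).

    ``initial_pool`` replaces the uniform founding pool, enabling staged
    protocols (e.g. establish cooperation at low mixing, then challenge the
    evolved pool under high mixing).
    """
    engine = _Engine(config, np.random.default_rng(seed))
    if initial_pool is None:
        pop = Population.uniform(config.pool_size, config.initial_genotype())
    else:
        if len(initial_pool) != config.pool_size:
            raise ValueError("initial_pool size must match config.pool_size")
        pop = initial_pool.take(np.arange(len(initial_pool)))
        engine.next_lineage = int(pop.lineage.max()) + 1
    records: list[GenerationRecord] = []
    detail: dict = {}
    final_pool = pop
    for gen in range(config.generations):
        final_pool = pop
        pop, record, detail = engine.step(pop)
        records.append(replace(record, generation=gen))
    return SimulationResult(
        config=config,
        seed=seed,
        records=records,
        final_pool=final_pool,
        offspring_pool=pop,
        final_eval=detail["evaluation"],
        final_order=detail["order"],
        final_sizes=detail["sizes"],
        parent_indices=detail["parents"],
    )


def summarize_last_k(records: Sequence[GenerationRecord], k: int) -> dict[str, float]:
    """Mean and SD of each recorded quantity over the final ``k`` generations."""
    if k < 1 or k > len(records):
        raise ValueError("need 1 <= k <= len(records)")
    frame = records_to_frame(list(records)[-k:])
    out: dict[str, float] = {"window": float(k)}
    for col in _SUMMARY_FIELDS:
        out[col] = float(frame[col].mean())
        out[col + "_sd"] = float(frame[col].std(ddof=0))
    return out


@dataclass
class ReplicateSet:
    """Replicate summaries plus across-replicate statistics."""

    seeds: list[int]
    summaries: list[dict[str, float]]
    results: list[SimulationResult]

    def stats(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.summaries)
        cols = [c for c in frame.columns if not c.endswith("_sd") and c != "window"]
        return pd.DataFrame(
            {
                "mean": frame[cols].mean(),
                "sd": frame[cols].std(ddof=0) if len(frame) > 1 else 0.0,
            }
        )


def replicate_seeds(master_seed: int, n_reps: int) -> list[int]:
    """Deterministic per-replicate seeds (< 2^31) from one master seed."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n_reps)]


def run_replicates(
    config: SimulationConfig,
    n_reps: int,
    master_seed: int,
    summary_window: int | None = None,
    keep_results: bool = True,
) -> ReplicateSet:
    """Independent replicate runs with seeds derived from ``master_seed``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    k = summary_window if summary_window is not None else config.summary_window
    k = min(k, config.generations)
    seeds = replicate_seeds(master_seed, n_reps)
    summaries = []
    results = []
    for s in seeds:
        res = run_simulation(config, s)
        summaries.append(summarize_last_k(res.records, k))
        if keep_results:
            results.append(res)
    return ReplicateSet(seeds=seeds, summaries=summaries, results=results)
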