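"""Genotypes, mutation and group founding under controlled genetic mixing.

Each individual carries three quorum-sensing traits: basal signal
production rate ``p``, signal response threshold ``S_Th`` and
auto-regulation ratio ``r`` (ratio of maximally induced to basal
production). Every generation a global propagule pool is scattered into
locally interacting sub-populations; the number of founder cells per group
is the genetic-mixing knob (few founders = high relatedness).

Two founder-count laws are available for a mixing intensity ``lambda_g``:

``max_poisson`` (default)
    ``max(Poisson(lambda_g), 1)`` with mean ``lambda_g + exp(-lambda_g)``
    (2.135 founders/group at lambda_g = 2).
``zero_truncated``
    Poisson conditioned on being >= 1, mean
    ``lambda_g / (1 - exp(-lambda_g))`` (4.073 at lambda_g = 4).

A ``fixed_g`` mode founds every group with exactly ``G`` cells (``G = 1``
is the clonal limit).

Scalar operations (:func:`mutate`, :func:`found_groups`) act on
:class:`Genotype` objects; the generational engine uses the column-oriented
:class:`Population` container and the vectorised helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CHEAT_LINEAGE",
    "Genotype",
    "TraitBounds",
    "MutationModel",
    "MixingConfig",
    "Population",
    "sample_founder_count",
    "sample_founder_counts",
    "founder_count_mean",
    "group_sizes_for_pool",
    "found_groups",
    "mutate",
    "mutate_population",
    "make_cheat",
]

#: lineage label shared by all injected constitutive cheats
CHEAT_LINEAGE = -1


@dataclass(frozen=True)
class Genotype:
    """Heritable quorum-sensing strategy of one individual."""

    p: float
    S_Th: float
    r: float = 0.0
    immutable: bool = False
    lineage_id: int = 0

    def __post_init__(self) -> None:
        for name, v in (("p", self.p), ("S_Th", self.S_Th), ("r", self.r)):
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"trait {name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class TraitBounds:
    """Upper bounds of the trait box (all traits live in [0, bound])."""

    p_max: float = 1e-7
    s_max: float = 50.0
    r_max: float = 10.0

    def __post_init__(self) -> None:
        if min(self.p_max, self.s_max, self.r_max) <= 0:
            raise ValueError("trait bounds must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_max, self.s_max, self.r_max])


@dataclass(frozen=True)
class MutationModel:
    """Per-trait mutation law applied at every reproduction event.

    Each unfrozen trait independently mutates with probability ``*_prob``;
    a mutation adds Gaussian noise with SD ``*_scale`` times the trait's
    bound range, reflected back into [0, bound]. Freeze flags reproduce the
    genetic-constraint regimes (signal-evolving / response-evolving);
    ``freeze_r`` defaults to True because auto-regulation evolves only in
    the three-trait simulations.
    """

    p_prob: float = 0.1
    s_prob: float = 0.1
    r_prob: float = 0.1
    p_scale: float = 0.02
    s_scale: float = 0.02
    r_scale: float = 0.02
    freeze_p: bool = False
    freeze_s: bool = False
    freeze_r: bool = True

    def __post_init__(self) -> None:
        for name in ("p_prob", "s_prob", "r_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("p_scale", "s_scale", "r_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MixingConfig:
    """Genetic-mixing regime: how founder counts per group are drawn."""

    lambda_g: float | None = None
    fixed_g: int | None = 1
    law: str = "max_poisson"

    def __post_init__(self) -> None:
        if (self.lambda_g is None) == (self.fixed_g is None):
            raise ValueError("exactly one of lambda_g / fixed_g must be set")
        if self.lambda_g is not None and self.lambda_g <= 0:
            raise ValueError("lambda_g must be > 0")
        if self.fixed_g is not None and self.fixed_g < 1:
            raise ValueError("fixed_g must be >= 1")
        if self.law not in ("max_poisson", "zero_truncated"):
            raise ValueError(f"unknown founder-count law {self.law!r}")


def sample_founder_count(
    lambda_g: float, rng: np.random.Generator, law: str = "max_poisson"
) -> int:
    """Draw the number of founder cells for one sub-population (>= 1)."""
    return int(sample_founder_counts(1, lambda_g, rng, law)[0])


def sample_founder_counts(
    n: int, lambda_g: float, rng: np.random.Generator, law: str = "max_poisson"
) -> np.ndarray:
    """Draw ``n`` founder counts under the configured law."""
    if lambda_g <= 0:
        raise ValueError("lambda_g must be > 0")
    if law == "max_poisson":
        return np.maximum(rng.poisson(lambda_g, size=n), 1)
    if law == "zero_truncated":
        draws = rng.poisson(lambda_g, size=n)
        while True:
            zeros = draws == 0
            if not zeros.any():
                return draws
            draws[zeros] = rng.poisson(lambda_g, size=int(zeros.sum()))
    raise ValueError(f"unknown founder-count law {law!r}")


def founder_count_mean(lambda_g: float, law: str = "max_poisson") -> float:
    """Analytic mean founders/group: lam + e^-lam, or lam/(1 - e^-lam)."""
    if law == "max_poisson":
        return lambda_g + math.exp(-lambda_g)
    if law == "zero_truncated":
        return lambda_g / (1.0 - math.exp(-lambda_g))
    raise ValueError(f"unknown founder-count law {law!r}")


def group_sizes_for_pool(
    pool_size: int, mixing: MixingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sizes of the groups a pool of ``pool_size`` individuals founds.

    Sizes are drawn sequentially until the pool is exhausted; the last group
    absorbs the remainder (always >= 1), so sizes sum exactly to the pool.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if mixing.fixed_g is not None:
        g = mixing.fixed_g
        n_full, rem = divmod(pool_size, g)
        sizes = [g] * n_full
        if rem:
            sizes.append(rem)
        return np.array(sizes, dtype=np.int64)
    sizes_list: list[int] = []
    remaining = pool_size
    while remaining > 0:
        # draw in batches for speed; typical batch covers the pool
        batch = sample_founder_counts(
            max(8, remaining // max(int(mixing.lambda_g), 1)),
            mixing.lambda_g,
            rng,
            mixing.law,
        )
        for s in batch:
            s = int(min(s, remaining))
            sizes_list.append(s)
            remaining -= s
            if remaining == 0:
                break
    return np.array(sizes_list, dtype=np.int64)


def found_groups(
    pool: Sequence[Genotype], mixing: MixingConfig, rng: np.random.Generator
) -> list[list[Genotype]]:
    """Scatter a propagule pool into founder sets, conserving individuals."""
    if len(pool) == 0:
        raise ValueError("pool must be non-empty")
    sizes = group_sizes_for_pool(len(pool), mixing, rng)
    order = rng.permutation(len(pool))
    groups: list[list[Genotype]] = []
    start = 0
    for s in sizes:
        groups.append([pool[i] for i in order[start : start + s]])
        start += s
    return groups


def _reflect(values: np.ndarray, bound: float) -> np.ndarray:
    """Fold values into [0, bound] by reflection at both edges."""
    period = 2.0 * bound
    y = np.mod(values, period)
    return np.where(y > bound, period - y, y)


def mutate(
    parent: Genotype,
    model: MutationModel,
    rng: np.random.Generator,
    bounds: TraitBounds = TraitBounds(),
) -> Genotype:
    """Return the (possibly) mutated offspring of one parent genotype."""
    if parent.immutable:
        return parent
    pop = Population.from_genotypes([parent])
    child, mutated = mutate_population(pop, model, bounds, rng, next_lineage=parent.lineage_id + 1)
    return child.to_genotypes()[0] if mutated[0] else parent


@dataclass
class Population:
    """Column-oriented container for a whole propagule pool."""

    p: np.ndarray
    s_th: np.ndarray
    r: np.ndarray
    immutable: np.ndarray
    lineage: np.ndarray

    def __len__(self) -> int:
        return len(self.p)

    @classmethod
    def uniform(cls, n: int, genotype: Genotype) -> "Population":
        """A pool of ``n`` copies of one founding genotype."""
        return cls(
            p=np.full(n, genotype.p),
            s_th=np.full(n, genotype.S_Th),
            r=np.full(n, genotype.r),
            immutable=np.full(n, genotype.immutable, dtype=bool),
            lineage=np.full(n, genotype.lineage_id, dtype=np.int64),
        )

    @classmethod
    def from_genotypes(cls, genotypes: Iterable[Genotype]) -> "Population":
        gs = list(genotypes)
        return cls(
            p=np.array([g.p for g in gs], dtype=float),
            s_th=np.array([g.S_Th for g in gs], dtype=float),
            r=np.array([g.r for g in gs], dtype=float),
            immutable=np.array([g.immutable for g in gs], dtype=bool),
            lineage=np.array([g.lineage_id for g in gs], dtype=np.int64),
        )

    def to_genotypes(self) -> list[Genotype]:
        return [
            Genotype(
                p=float(self.p[i]),
                S_Th=float(self.s_th[i]),
                r=float(self.r[i]),
                immutable=bool(self.immutable[i]),
                lineage_id=int(self.lineage[i]),
            )
            for i in range(len(self))
        ]

    def take(self, idx: np.ndarray) -> "Population":
        return Population(
            p=self.p[idx].copy(),
            s_th=self.s_th[idx].copy(),
            r=self.r[idx].copy(),
            immutable=self.immutable[idx].copy(),
            lineage=self.lineage[idx].copy(),
        )

    def n_lineages(self) -> int:
        return int(np.unique(self.lineage).size)


def mutate_population(
    pop: Population,
    model: MutationModel,
    bounds: TraitBounds,
    rng: np.random.Generator,
    next_lineage: int,
) -> tuple[Population, np.ndarray]:
    """Mutate a whole pool in place-copy form.

    Returns the mutated population and the boolean mask of individuals whose
    genotype actually changed (these receive fresh lineage ids starting at
    ``next_lineage``).
    """
    n = len(pop)
    mutable = ~pop.immutable
    out = pop.take(np.arange(n))
    any_mut = np.zeros(n, dtype=bool)
    specs = (
        (out.p, model.p_prob, model.p_scale, model.freeze_p, bounds.p_max),
        (out.s_th, model.s_prob, model.s_scale, model.freeze_s, bounds.s_max),
        (out.r, model.r_prob, model.r_scale, model.freeze_r, bounds.r_max),
    )
    for arr, prob, scale, frozen, bound in specs:
        if frozen or prob == 0.0 or scale == 0.0:
            continue
        hit = mutable & (rng.random(n) < prob)
        k = int(hit.sum())
        if k == 0:
            continue
        arr[hit] = _reflect(arr[hit] + rng.normal(0.0, scale * bound, size=k), bound)
        any_mut |= hit
    k = int(any_mut.sum())
    out.lineage[any_mut] = np.arange(next_lineage, next_lineage + k, dtype=np.int64)
    return out, any_mut


def make_cheat(bounds: TraitBounds = TraitBounds()) -> Genotype:
    """Constitutive, immutable cheat: no signal, maximal response threshold."""
    return Genotype(p=0.0, S_Th=bounds.s_max, r=0.0, immutable=True, lineage_id=CHEAT_LINEAGE)
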