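"""Payoff evaluation across the testing-environment density grid.

Every generation each sub-population is scored in a panel of testing
environments that differ only in cell density. For each density ``N`` the
group's equilibrium signal ``S*`` is computed (founders share the density
equally, ``N_g = N/G``), each member decides ON/OFF by comparing ``S*`` to
its own threshold, and payoffs are

    payoff = baseline
             + [N > N_Th] * B_coop * f        (public-good benefit)
             - [ON]       * C_coop            (cost of cooperating)
             - C_sig * p_eff                  (cost of signalling)

where ``f`` is the group's cooperating fraction (weighted by the equal
density shares, so ``f = #ON / G``) and ``p_eff`` is the realised
per-capita production rate — ``p`` without auto-regulation,
``p (1 + r S*/(K + S*))`` with it, so induced signalling is itself costly.
The benefit is a hard step in density: cooperation only pays above the
critical density ``N_Th``. An individual's fitness is its arithmetic mean
payoff over the whole grid.

Cooperation modes: ``qs`` (threshold response, no feedback), ``qs_auto``
(threshold response with auto-regulation), ``constitutive`` (always ON, no
signalling machinery, no signal cost) and ``never`` (baseline strategy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_dynamics import DynamicsParams, SignalEnvironment, equilibrium_auto_array
from .population import Genotype, Population

__all__ = [
    "MODES",
    "DEFAULT_GRID_LOW",
    "DEFAULT_GRID_HIGH",
    "DEFAULT_N_TH",
    "PayoffParams",
    "DensityGrid",
    "GroupEvaluation",
    "build_density_grid",
    "evaluate_group",
    "evaluate_pool_groups",
    "payoff",
    "baseline_payoff",
]

MODES = ("qs", "qs_auto", "constitutive", "never")

DEFAULT_GRID_LOW = 10.0**1.5
DEFAULT_GRID_HIGH = 1e5
#: median of the default 100-environment grid, 5.0016e4 cells/uL
DEFAULT_N_TH = (DEFAULT_GRID_LOW + DEFAULT_GRID_HIGH) / 2.0


@dataclass(frozen=True)
class PayoffParams:
    """Cost/benefit coefficients of the cooperation game.

    ``C_sig`` multiplies the realised per-capita production rate (uM/s);
    the default is calibrated so the clonal evolved optimum sits at basal
    rates of a few 1e-9 uM/s with thresholds of a few uM — interior to the
    trait box and matching the scale of well-tuned density-sensing
    strains. ``N_Th`` defaults to the median of the default density grid.
    """

    C_sig: float = 1e9
    C_coop: float = 100.0
    B_coop: float = 300.0
    N_Th: float = DEFAULT_N_TH
    baseline: float = 1000.0
    mode: str = "qs"

    def __post_init__(self) -> None:
        for name in ("C_sig", "C_coop", "B_coop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (math.isfinite(self.N_Th) and self.N_Th > 0):
            raise ValueError("N_Th must be finite and > 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class DensityGrid:
    """Ordered panel of testing densities (cells/uL)."""

    densities: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("density grid needs at least two densities")
        if not (np.all(np.isfinite(d)) and d[0] > 0 and np.all(np.diff(d) > 0)):
            raise ValueError("densities must be positive, finite and strictly increasing")
        object.__setattr__(self, "densities", d)

    @property
    def count(self) -> int:
        return int(self.densities.size)

    @property
    def median(self) -> float:
        return float(np.median(self.densities))


def build_density_grid(
    low: float = DEFAULT_GRID_LOW,
    high: float = DEFAULT_GRID_HIGH,
    count: int = 100,
) -> DensityGrid:
    """Evenly spaced densities on the linear scale from ``low`` to ``high``.

    With the defaults (100 points from 10^1.5 to 10^5 cells/uL) the grid
    median is (10^1.5 + 10^5)/2 = 5.0016e4 cells/uL, which doubles as the
    default critical density threshold.
    """
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if count < 2:
        raise ValueError("count must be >= 2")
    return DensityGrid(np.linspace(low, high, count))


@dataclass
class GroupEvaluation:
    """Per-member, per-density bookkeeping for one or more groups.

    Members appear in group-contiguous order; ``starts``/``sizes`` delimit
    the groups. ``on`` is the members x densities ON/OFF matrix, ``payoffs``
    the matching payoff matrix, ``fitness`` the per-member grid mean,
    ``coop_fraction`` the per-group, per-density cooperating fraction and
    ``s_star`` the per-group, per-density equilibrium signal.
    """

    on: np.ndarray
    payoffs: np.ndarray
    fitness: np.ndarray
    coop_fraction: np.ndarray
    s_star: np.ndarray
    starts: np.ndarray
    sizes: np.ndarray

    def member_investment(self) -> np.ndarray:
        """Fraction of testing densities at which each member is ON."""
        return self.on.mean(axis=1)


def evaluate_pool_groups(
    pop: Population,
    sizes: np.ndarray,
    grid: DensityGrid,
    env: SignalEnvironment,
    dyn: DynamicsParams,
    pay: PayoffParams,
    rng: np.random.Generator | None = None,
) -> GroupEvaluation:
    """Evaluate a group-contiguous pool on the whole density grid.

    ``pop`` must already be ordered so that the first ``sizes[0]`` members
    form group 0 and so on. ``env`` supplies the loss rates and perception
    noise; its density field is ignored in favour of the grid.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    n = len(pop)
    if int(sizes.sum()) != n:
        raise ValueError("group sizes must sum to the pool size")
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    N = grid.densities  # (D,)
    D = N.size
    loss = env.loss_rate

    if pay.mode in ("qs", "qs_auto"):
        mean_p = np.add.reduceat(pop.p, starts) / sizes  # (n_groups,)
        A = mean_p[:, None] * N[None, :]  # basal load, groups x densities
        if pay.mode == "qs_auto":
            mean_pr = np.add.reduceat(pop.p * pop.r, starts) / sizes
            B = mean_pr[:, None] * N[None, :]
            s_star = equilibrium_auto_array(A, B, dyn.K, loss)
        else:
            s_star = A / loss
        s_member = np.repeat(s_star, sizes, axis=0)  # members x densities
        perceived = s_member
        if env.noise_sd > 0.0:
            if rng is None:
                raise ValueError("rng required when noise_sd > 0")
            perceived = s_member * rng.lognormal(0.0, env.noise_sd, size=s_member.shape)
        on = perceived > pop.s_th[:, None]
        # reduceat on bool would OR, not count — go through int
        coop_fraction = np.add.reduceat(on.astype(np.int64), starts, axis=0) / sizes[:, None]
        f_member = np.repeat(coop_fraction, sizes, axis=0)
        if pay.mode == "qs_auto":
            p_eff = pop.p[:, None] * (1.0 + pop.r[:, None] * s_member / (dyn.K + s_member))
        else:
            p_eff = np.broadcast_to(pop.p[:, None], (n, D))
        payoffs = (
            pay.baseline
            + (N > pay.N_Th)[None, :] * (pay.B_coop * f_member)
            - on * pay.C_coop
            - pay.C_sig * p_eff
        )
    elif pay.mode == "constitutive":
        # always-ON cooperators without signalling machinery; injected
        # immutable cheats remain OFF
        on = np.broadcast_to(~pop.immutable[:, None], (n, D)).copy()
        coop_fraction = np.add.reduceat(on.astype(np.int64), starts, axis=0) / sizes[:, None]
        f_member = np.repeat(coop_fraction, sizes, axis=0)
        s_star = np.zeros((sizes.size, D))
        payoffs = (
            pay.baseline
            + (N > pay.N_Th)[None, :] * (pay.B_coop * f_member)
            - on * pay.C_coop
        )
    elif pay.mode == "never":
        on = np.zeros((n, D), dtype=bool)
        coop_fraction = np.zeros((sizes.size, D))
        s_star = np.zeros((sizes.size, D))
        payoffs = np.full((n, D), pay.baseline)
    else:  # pragma: no cover
        raise ValueError(f"unknown mode {pay.mode!r}")

    return GroupEvaluation(
        on=np.asarray(on),
        payoffs=payoffs,
        fitness=payoffs.mean(axis=1),
        coop_fraction=coop_fraction,
        s_star=s_star,
        starts=starts,
        sizes=sizes,
    )


def evaluate_group(
    founders: list[Genotype],
    grid: DensityGrid,
    env: SignalEnvironment,
    dyn: DynamicsParams = DynamicsParams(),
    pay: PayoffParams = PayoffParams(),
    rng: np.random.Generator | None = None,
) -> GroupEvaluation:
    """Evaluate a single founder set across the density grid."""
    if len(founders) == 0:
        raise ValueError("founder set must be non-empty")
    pop = Population.from_genotypes(founders)
    return evaluate_pool_groups(
        pop, np.array([len(founders)]), grid, env, dyn, pay, rng=rng
    )


def payoff(
    member_on: bool,
    f: float,
    N: float,
    member: Genotype,
    S_star: float,
    pay: PayoffParams,
    dyn: DynamicsParams = DynamicsParams(),
) -> float:
    """Payoff of one member at one testing density (scalar reference form)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("cooperating fraction f must be in [0, 1]")
    if pay.mode == "never":
        return pay.baseline
    if pay.mode == "constitutive":
        return pay.baseline + (N > pay.N_Th) * pay.B_coop * f - member_on * pay.C_coop
    if pay.mode == "qs_auto":
        p_eff = member.p * (1.0 + member.r * S_star / (dyn.K + S_star))
    else:
        p_eff = member.p
    return (
        pay.baseline
        + (N > pay.N_Th) * pay.B_coop * f
        - member_on * pay.C_coop
        - pay.C_sig * p_eff
    )


def baseline_payoff(pay: PayoffParams) -> float:
    """Payoff of the never-signal, never-cooperate strategy (any density)."""
    return pay.baseline
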