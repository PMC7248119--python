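"""Statistical readouts of evolved quorum-sensing populations.

Covers the post-hoc analyses of the simulator's output: ON-fraction
response curves across the density panel, the coordination-line regression
(evolved threshold vs evolved production against the prediction
``S_Th = p N_Th / u``), individual-vs-group assortment of cooperative
investment with an ANCOVA slope comparison, a two-level Price-equation
partition of selection, and the mass-transfer ("diffusion sensing")
spandrel assay for single evolved strains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.stats import f as f_dist

from .core_dynamics import (
    DynamicsParams,
    SignalEnvironment,
    equilibrium_auto,
    mass_transfer_threshold,
)
from .fitness import DensityGrid, GroupEvaluation, PayoffParams, evaluate_pool_groups
from .population import Genotype, Population

__all__ = [
    "AssortmentFit",
    "PriceTerms",
    "SpandrelProfile",
    "on_fraction_curve",
    "constraint_regression",
    "cooperative_investment",
    "assortment_analysis",
    "compare_slopes",
    "price_decomposition",
    "spandrel_assay",
]


@dataclass(frozen=True)
class AssortmentFit:
    """Ordinary least-squares fit of y on x (with intercept)."""

    slope: float
    intercept: float
    r_squared: float
    residual_variance: float
    n: int
    predicted_slope: float | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 points for a fit")


def _ols(x: np.ndarray, y: np.ndarray, predicted_slope: float | None = None) -> AssortmentFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.var(x) == 0.0:
        raise ValueError("degenerate predictor: zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid = y - res.fittedvalues
    r2 = float(res.rsquared)
    return AssortmentFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=min(max(r2, 0.0), 1.0),
        residual_variance=float(np.var(resid, ddof=2)),
        n=int(x.size),
        predicted_slope=predicted_slope,
    )


def on_fraction_curve(
    pop: Population,
    grid: DensityGrid,
    env: SignalEnvironment,
    dyn: DynamicsParams = DynamicsParams(),
    pay: PayoffParams = PayoffParams(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fraction of individuals ON at each testing density, evaluated solo.

    Each individual is placed alone in every environment (its own clonal
    group), matching the converged-population response curves: a tuned
    clonal quorum-sensing population yields a step near the critical
    density, a constitutive population is ON everywhere.
    """
    sizes = np.ones(len(pop), dtype=np.int64)
    ev = evaluate_pool_groups(pop, sizes, grid, env, dyn, pay, rng=rng)
    return ev.on.mean(axis=0)


def constraint_regression(
    p_means: np.ndarray,
    s_th_means: np.ndarray,
    N_Th: float,
    u: float,
) -> AssortmentFit:
    """Regress evolved mean thresholds on evolved mean production rates.

    The coordination game predicts evolved strategies on the line
    ``S_Th = p N_Th / u``; the fit's ``predicted_slope`` field carries the
    parameter-free slope ``N_Th / u`` for comparison with the OLS slope.
    """
    if N_Th <= 0 or u <= 0:
        raise ValueError("need N_Th > 0 and u > 0")
    return _ols(p_means, s_th_means, predicted_slope=N_Th / u)


def cooperative_investment(evaluation: GroupEvaluation) -> tuple[np.ndarray, np.ndarray]:
    """Per-member and matching group-mean cooperative investment.

    Investment is the fraction of testing densities at which a member
    expresses cooperation within its group's signalling context; it lives
    in [0, 1] (1 for an always-ON constitutive individual, 0 for a cheat).
    Returns ``(individual, group_mean_per_individual)`` arrays.
    """
    inv = evaluation.member_investment()
    group_mean = np.add.reduceat(inv, evaluation.starts) / evaluation.sizes
    return inv, np.repeat(group_mean, evaluation.sizes)


def assortment_analysis(
    individual: np.ndarray, group_mean: np.ndarray
) -> AssortmentFit:
    """OLS of group-mean investment on individual investment.

    For internally homogeneous (clonal) groups the slope is exactly 1;
    looser phenotype matching shows up as a shallower slope and larger
    residual variance.
    """
    return _ols(individual, group_mean)


def compare_slopes(
    x_a: np.ndarray,
    y_a: np.ndarray,
    x_b: np.ndarray,
    y_b: np.ndarray,
) -> tuple[float, float]:
    """ANCOVA slope comparison between two regressions.

    Pools both datasets into one OLS with a group indicator and an
    interaction term; returns the F statistic (1 numerator df) and p-value
    for the interaction, i.e. for the null of equal slopes.
    """
    x = np.concatenate([np.asarray(x_a, float), np.asarray(x_b, float)])
    y = np.concatenate([np.asarray(y_a, float), np.asarray(y_b, float)])
    g = np.concatenate([np.zeros(len(x_a)), np.ones(len(x_b))])
    if len(x_a) < 3 or len(x_b) < 3:
        raise ValueError("each group needs >= 3 points")
    X = np.column_stack([np.ones_like(x), x, g, x * g])
    res = sm.OLS(y, X).fit()
    t = float(res.tvalues[3])
    f_stat = t * t
    p_value = float(f_dist.sf(f_stat, 1, int(res.df_resid)))
    return f_stat, p_value


@dataclass(frozen=True)
class PriceTerms:
    """Two-level Price partition of one generation of trait change.

    ``between + within = total`` holds exactly (bookkeeping identity):
    between-group selection is ``Cov_g(W_g, z_g) / W``, within-group change
    is ``E_g[W_g dz_g] / W`` with group expectations weighted by group size
    and within-group offspring means weighted by member fitness.
    """

    between_group: float
    within_group: float
    total: float


def price_decomposition(
    group_ids: np.ndarray,
    fitness: np.ndarray,
    trait: np.ndarray,
    offspring_trait: np.ndarray | None = None,
) -> PriceTerms:
    """Partition selection on ``trait`` into between- and within-group terms.

    Parameters
    ----------
    group_ids : array of group labels, one per parent.
    fitness : realised or expected offspring number of each parent (>= 0).
    trait : parent trait values (e.g. cooperative investment).
    offspring_trait : mean trait of each parent's offspring; defaults to the
        parent's own value (no transmission bias).
    """
    gid = np.asarray(group_ids)
    w = np.asarray(fitness, dtype=float)
    z = np.asarray(trait, dtype=float)
    zp = z if offspring_trait is None else np.asarray(offspring_trait, dtype=float)
    if not (gid.size == w.size == z.size == zp.size):
        raise ValueError("group_ids, fitness and trait arrays must align")
    if np.any(w < 0):
        raise ValueError("fitness must be non-negative")
    w_bar = w.mean()
    if w_bar == 0.0:
        raise ValueError("mean fitness is zero: no offspring to account for")

    _, inverse, counts = np.unique(gid, return_inverse=True, return_counts=True)
    n = w.size
    W_g = np.bincount(inverse, weights=w) / counts
    z_g = np.bincount(inverse, weights=z) / counts
    wz_g = np.bincount(inverse, weights=w * zp)
    weights = counts / n

    between = float(np.sum(weights * W_g * z_g) - w_bar * np.sum(weights * z_g)) / w_bar
    # fitness-weighted offspring mean per group; groups with W_g = 0 leave
    # no offspring and contribute nothing to the within term
    with np.errstate(invalid="ignore", divide="ignore"):
        dz_g = np.where(W_g > 0, wz_g / (counts * np.where(W_g > 0, W_g, 1.0)) - z_g, 0.0)
    within = float(np.sum(weights * W_g * dz_g)) / w_bar
    total = float(np.sum(w * zp) / w.sum() - z.mean())
    return PriceTerms(between_group=between, within_group=within, total=total)


@dataclass(frozen=True)
class SpandrelProfile:
    """Signal and cooperation state of one strain across mass-transfer rates."""

    strain: Genotype
    N: float
    u: float
    m: np.ndarray
    s_star: np.ndarray
    on: np.ndarray
    m_star: float | None


def spandrel_assay(
    strain: Genotype,
    N: float,
    u: float,
    m_max: float = 1e-4,
    count: int = 201,
    dyn: DynamicsParams = DynamicsParams(),
) -> SpandrelProfile:
    """Probe a clonal strain's response to mass-transfer signal loss.

    The density is fixed (quorate) while the loss rate ``m`` sweeps
    ``[0, m_max]``; the equilibrium signal ``S*(m) = pN/(u+m)`` (feedback
    form if the strain auto-regulates) decreases with ``m``, and the strain
    cooperates only while ``m`` stays below the threshold ``m*`` solving
    ``S*(m*) = S_Th``. A density-sensing strain that switches OFF at high
    ``m`` is performing diffusion sensing it never evolved for.
    """
    if m_max <= 0 or count < 2:
        raise ValueError("need m_max > 0 and count >= 2")
    m_grid = np.linspace(0.0, m_max, count)

    def s_at(m: float) -> float:
        env = SignalEnvironment(N=N, u=u, m=m)
        return equilibrium_auto(strain.p * N, strain.p * strain.r * N, dyn, env)

    s_star = np.array([s_at(m) for m in m_grid])
    on = s_star > strain.S_Th
    if strain.p == 0.0:
        m_star = None
    elif strain.S_Th == 0.0:
        m_star = math.inf  # strictly positive signal at any finite loss rate
    elif strain.r == 0.0:
        m_star = mass_transfer_threshold(strain.p, N, u, strain.S_Th)
    elif s_at(0.0) <= strain.S_Th:
        m_star = None
    else:
        # S*(m) is strictly decreasing; expand the bracket until sign change
        hi = max(m_max, u)
        while s_at(hi) > strain.S_Th:
            hi *= 2.0
            if hi > 1e6 * u:  # pragma: no cover - absurd parameter guard
                raise RuntimeError("failed to bracket mass-transfer threshold")
        m_star = float(brentq(lambda m: s_at(m) - strain.S_Th, 0.0, hi))
    return SpandrelProfile(
        strain=strain, N=N, u=u, m=m_grid, s_star=s_star, on=on, m_star=m_star
    )
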