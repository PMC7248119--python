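"""Extracellular signal dynamics for quorum-sensing groups.

A group of cells at stationary density ``N`` secretes an autoinducer-like
signal. Without auto-regulation the signal obeys

    dS/dt = p N - (u + m) S,

where ``p`` is the per-capita basal production rate, ``u`` the environmental
decay rate and ``m`` an optional mass-transfer (diffusion/advection) loss
rate, so the concentration equilibrates to ``S* = pN / (u + m)``. With
positive-feedback auto-regulation (induced production up to ``r`` times the
basal rate, with half-saturation ``K``) the dynamics become

    dS/dt = p (1 + r S / (K + S)) N - (u + m) S.

For a group founded by several genotypes the production terms sum over the
founders; writing ``A = sum_g p_g N_g`` (basal load) and
``B = sum_g p_g r_g N_g`` (feedback load), the equilibrium is the
non-negative root of

    (u + m) S^2 + ((u + m) K - A - B) S - A K = 0.

Cells express their cooperative phenotype only when the equilibrium signal
exceeds their individual response threshold (``S* > S_Th``). All equilibria
here are closed-form; :func:`integrate_signal_ode` provides the explicit
time integration used to cross-check them.

Units follow the source system's bookkeeping: concentrations in uM,
production rates in uM/s per unit cell density, densities in cells/uL, and
loss rates u, m in uL/s (treated throughout as first-order loss
coefficients).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SignalEnvironment",
    "DynamicsParams",
    "SignalState",
    "equilibrium_no_auto",
    "equilibrium_auto",
    "equilibrium_auto_array",
    "integrate_signal_ode",
    "response_state",
    "mass_transfer_threshold",
]


def _require_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class SignalEnvironment:
    """The signalling world a group experiences.

    Parameters
    ----------
    N : float
        Stationary cell density (cells/uL). Must be positive.
    u : float
        Environmental signal decay rate (uL/s). Must be positive.
    m : float
        Additional mass-transfer loss rate (same units as ``u``); zero for a
        closed, well-mixed environment.
    noise_sd : float
        Standard deviation (log scale) of multiplicative log-normal noise
        applied to the perceived signal; zero disables noise.
    """

    N: float
    u: float = 1e-4
    m: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.N) and self.N > 0):
            raise ValueError(f"density N must be finite and > 0, got {self.N!r}")
        if not (math.isfinite(self.u) and self.u > 0):
            raise ValueError(f"decay rate u must be finite and > 0, got {self.u!r}")
        _require_finite_nonneg("mass transfer rate m", self.m)
        _require_finite_nonneg("noise_sd", self.noise_sd)

    @property
    def loss_rate(self) -> float:
        """Total first-order signal loss coefficient u + m."""
        return self.u + self.m


@dataclass(frozen=True)
class DynamicsParams:
    """Auto-regulation response parameters.

    ``K`` is the half-saturation signal concentration (uM) of the induced
    production term. The default sits above the typical evolved working
    range of S* (a few uM): if K is far below that range the feedback is
    saturated at all relevant signal levels and the auto-regulation ratio
    degenerates into a plain multiplier on basal production, losing its
    distinct group-conditional phenotype.
    """

    K: float = 10.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.K) and self.K > 0):
            raise ValueError(f"half-saturation K must be finite and > 0, got {self.K!r}")


@dataclass
class SignalState:
    """Equilibrium signal concentration, optionally with the path to it."""

    S_star: float
    trajectory: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.S_star < 0:
            raise ValueError("equilibrium signal concentration must be >= 0")


def equilibrium_no_auto(production_load: float, env: SignalEnvironment) -> float:
    """Equilibrium signal concentration without auto-regulation.

    ``production_load`` is the total basal production ``sum_g p_g N_g``
    (uM/s) over the group's founder genotypes; the equilibrium is
    ``production_load / (u + m)``, which reduces to S* = pN/u in a closed
    environment.
    """
    _require_finite_nonneg("production_load", production_load)
    return production_load / env.loss_rate


def equilibrium_auto(
    A: float,
    B: float,
    params: DynamicsParams,
    env: SignalEnvironment,
) -> float:
    """Equilibrium signal concentration with positive-feedback auto-regulation.

    Parameters
    ----------
    A : float
        Basal production load ``sum_g p_g N_g`` (uM/s).
    B : float
        Feedback production load ``sum_g p_g r_g N_g`` (uM/s).
    params, env
        Half-saturation constant and loss rates.

    Returns
    -------
    float
        The stable equilibrium reached from ``S = 0``: the unique positive
        root of ``(u+m) S^2 + ((u+m)K - A - B) S - A K = 0`` when ``A > 0``,
        zero when ``A = 0`` (with no basal production the feedback loop is
        never primed), and exactly the no-feedback equilibrium when ``B = 0``.
    """
    _require_finite_nonneg("basal load A", A)
    _require_finite_nonneg("feedback load B", B)
    if B == 0.0:
        # bit-identical reduction to the feedback-free model
        return equilibrium_no_auto(A, env)
    if A == 0.0:
        return 0.0
    loss = env.loss_rate
    K = params.K
    b = loss * K - A - B
    disc = b * b + 4.0 * loss * A * K
    assert disc > 0.0  # product of roots is -AK/loss < 0 whenever A > 0
    return (-b + math.sqrt(disc)) / (2.0 * loss)


def equilibrium_auto_array(
    A: np.ndarray,
    B: np.ndarray,
    K: float,
    loss: float,
) -> np.ndarray:
    """Vectorised :func:`equilibrium_auto` over arrays of group loads."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    b = loss * K - A - B
    disc = b * b + 4.0 * loss * A * K
    root = (-b + np.sqrt(disc)) / (2.0 * loss)
    out = np.where(B == 0.0, A / loss, root)
    return np.where(A == 0.0, 0.0, out)


def integrate_signal_ode(
    A: float,
    B: float,
    params: DynamicsParams,
    env: SignalEnvironment,
    S0: float = 0.0,
    horizon: float | None = None,
    n_points: int = 200,
) -> SignalState:
    """Integrate the signal ODE explicitly and return the endpoint state.

    Exists as the independent non-equilibrium route: the endpoint of the
    trajectory must converge to the closed-form equilibrium. When no
    ``horizon`` is given, integration starts from ``40 / (u + m)`` and the
    window doubles until the endpoint is stationary — near-critical
    feedback (``B`` close to ``(u+m)K``) relaxes much more slowly than the
    bare loss timescale.
    """
    loss = env.loss_rate
    K = params.K
    fixed_horizon = horizon is not None
    if horizon is None:
        horizon = 40.0 / loss
    if horizon <= 0:
        raise ValueError("horizon must be > 0")

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        S = y[0]
        return np.array([A + B * S / (K + S) - loss * S])

    segments: list[np.ndarray] = []
    t0, s0 = 0.0, float(S0)
    span = float(horizon)
    for _ in range(64):
        sol = solve_ivp(
            rhs,
            (t0, t0 + span),
            [s0],
            method="LSODA",
            rtol=1e-12,
            atol=1e-16,
            t_eval=np.linspace(t0, t0 + span, n_points),
        )
        if not sol.success:  # pragma: no cover - stiff failure reporting
            raise RuntimeError(
                f"signal ODE integration failed (A={A}, B={B}, K={K}, loss={loss}): "
                f"{sol.message}"
            )
        segments.append(np.column_stack([sol.t, sol.y[0]]))
        prev, s0 = s0, float(sol.y[0, -1])
        t0 += span
        slope = abs(float(rhs(t0, np.array([s0]))[0]))
        scale = max(abs(s0), 1e-30)
        if fixed_horizon or (abs(s0 - prev) <= 1e-9 * scale and slope <= 1e-9 * loss * scale):
            break
        span *= 2.0
    trajectory = np.concatenate(segments)
    return SignalState(S_star=s0, trajectory=trajectory)


def response_state(
    S_star: float,
    S_Th: float,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
) -> bool:
    """Cooperative phenotype decision: ON iff perceived signal exceeds threshold.

    The comparison is strict (a cell exactly at threshold stays OFF). With
    ``noise_sd > 0`` the perceived signal is ``S* * LogNormal(0, noise_sd)``,
    requiring an ``rng``.
    """
    _require_finite_nonneg("S_star", S_star)
    _require_finite_nonneg("S_Th", S_Th)
    perceived = S_star
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        perceived = S_star * rng.lognormal(0.0, noise_sd)
    return perceived > S_Th


def mass_transfer_threshold(p: float, N: float, u: float, S_Th: float) -> float | None:
    """Critical mass-transfer rate below which a clonal strain turns ON.

    Solves ``pN/(u + m*) = S_Th`` for ``m*``; the strain cooperates at density
    ``N`` for any loss ``m < m*``. Returns ``None`` ("never ON") when even a
    closed environment (``m = 0``) cannot reach the threshold.
    """
    for name, v in (("p", p), ("N", N), ("u", u), ("S_Th", S_Th)):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be finite and > 0, got {v!r}")
    m_star = p * N / S_Th - u
    return m_star if m_star > 0 else None
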