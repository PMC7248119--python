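"""Reusable experiment recipes at desk scale.

Each function assembles configurations, runs replicated simulations and
returns tidy results. The desk-scale study conditions (pool of 500
individuals, 500 generations, traits summarised over the last 50
generations, small replicate counts) are fixed here so that tests, the
command-line interface and the reproduction script all run the same
experiments.

The signalling-cost defaults place the clonal evolved optimum at basal
production of a few 1e-9 uM/s; the cost sweep spans the range over which
the coordination line is traced out. The assortment experiment raises the
public-good benefit so that fixed five-founder groups lie inside the
cooperative window (with a benefit-to-cooperation-cost ratio B/C below the
founder count G, a lone cooperator in a mixed group can never recoup its
expression cost, and cooperation cannot persist at that G).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .analysis import (
    AssortmentFit,
    assortment_analysis,
    compare_slopes,
    constraint_regression,
    cooperative_investment,
    spandrel_assay,
)
from .evolution import (
    SimulationConfig,
    replicate_seeds,
    run_replicates,
    run_simulation,
)
from .fitness import PayoffParams
from .population import Genotype, MixingConfig, MutationModel

__all__ = [
    "DESK_POOL",
    "DESK_GENERATIONS",
    "COST_SWEEP_VALUES",
    "REFERENCE_STRAINS",
    "desk_config",
    "clonal_cost_sweep",
    "mixing_sweep",
    "autoregulation_rescue",
    "assortment_experiment",
    "spandrel_profiles",
]

DESK_POOL = 500
DESK_GENERATIONS = 500

#: signalling-cost sweep (payoff x s/uM), spanning 5e8 .. 1e10
COST_SWEEP_VALUES = tuple(np.linspace(5e8, 1e10, 8))

#: previously evolved strains probed in the mass-transfer assay:
#: clonal, intermediate relatedness (lambda_G = 2) and low relatedness
#: (lambda_G = 4) density sensors
REFERENCE_STRAINS = {
    "clonal": Genotype(p=4.37e-9, S_Th=2.15),
    "intermediate": Genotype(p=9.27e-9, S_Th=4.63),
    "low_relatedness": Genotype(p=8.71e-9, S_Th=7.27),
}


def desk_config(**overrides) -> SimulationConfig:
    """Desk-scale base configuration (clonal, no auto-regulation)."""
    base = SimulationConfig(
        pool_size=DESK_POOL,
        generations=DESK_GENERATIONS,
        mixing=MixingConfig(fixed_g=1),
        payoff=PayoffParams(mode="qs"),
        mutation=MutationModel(),
    )
    return replace(base, **overrides) if overrides else base


#: a converged clonal density sensor is ON at roughly half the testing
#: densities; replicates below this ON-fraction never evolved quorum
#: sensing within the run
ESTABLISHMENT_THRESHOLD = 0.2


def clonal_cost_sweep(
    master_seed: int,
    cost_values: tuple[float, ...] = COST_SWEEP_VALUES,
    reps: int = 3,
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, AssortmentFit]:
    """Clonal evolution across signalling costs + coordination-line fit.

    For each cost the evolved mean production rate and threshold (last-50
    generation window, averaged over replicates) give one point; ordinary
    least squares of threshold on production is compared against the
    predicted constraint slope ``N_Th / u``.

    The coordination line describes populations that evolved quorum
    sensing, so per-cost averages cover the replicates whose final
    cooperation ON-fraction reaches :data:`ESTABLISHMENT_THRESHOLD`; at
    desk scale a rare replicate fails to establish within the run and
    would otherwise contaminate the condition mean with its unevolved
    threshold. If no replicate of a condition establishes, all are used.
    """
    base = config if config is not None else desk_config()
    rows = []
    for i, c in enumerate(cost_values):
        cfg = replace(base, payoff=replace(base.payoff, C_sig=float(c)))
        reps_out = run_replicates(cfg, reps, master_seed + i, keep_results=False)
        kept = [
            s
            for s in reps_out.summaries
            if s["coop_fraction"] >= ESTABLISHMENT_THRESHOLD
        ]
        if not kept:
            kept = reps_out.summaries
        frame = pd.DataFrame(kept)
        rows.append(
            {
                "C_sig": float(c),
                "p_mean": frame["p_mean"].mean(),
                "p_sd": frame["p_mean"].std(ddof=0),
                "s_th_mean": frame["s_th_mean"].mean(),
                "s_th_sd": frame["s_th_mean"].std(ddof=0),
                "payoff_mean": frame["payoff_mean"].mean(),
                "n_established": len(kept),
            }
        )
    table = pd.DataFrame(rows)
    fit = constraint_regression(
        table["p_mean"].to_numpy(),
        table["s_th_mean"].to_numpy(),
        N_Th=base.payoff.N_Th,
        u=base.u,
    )
    return table, fit


def _mixing(lam: float | None) -> MixingConfig:
    if lam is None:
        return MixingConfig(fixed_g=1)
    return MixingConfig(lambda_g=lam, fixed_g=None)


def mixing_sweep(
    master_seed: int,
    lambdas: tuple[float | None, ...] = (None, 2.0, 4.0),
    reps: int = 5,
    mode: str = "qs",
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Evolved strategies under increasing genetic mixing.

    ``None`` denotes the clonal limit (every group founded by one cell).
    Returns one row per mixing condition with across-replicate means and
    SDs of evolved traits, payoff and cooperation.
    """
    base = config if config is not None else desk_config()
    base = replace(base, payoff=replace(base.payoff, mode=mode))
    rows = []
    for i, lam in enumerate(lambdas):
        cfg = replace(base, mixing=_mixing(lam))
        reps_out = run_replicates(cfg, reps, master_seed + i, keep_results=False)
        stats = reps_out.stats()
        row = {"lambda_g": np.nan if lam is None else lam, "clonal": lam is None}
        for key in ("p_mean", "s_th_mean", "r_mean", "payoff_mean", "coop_fraction"):
            row[key] = stats.loc[key, "mean"]
            row[key + "_sd"] = stats.loc[key, "sd"]
        rows.append(row)
    return pd.DataFrame(rows)


def autoregulation_rescue(
    master_seed: int,
    lam: float = 4.0,
    reps: int = 25,
    config: SimulationConfig | None = None,
) -> dict:
    """High-mixing contrast: auto-regulation evolving vs frozen at zero.

    Both arms share the mixing regime and payoff scheme; only the third
    trait's evolvability differs. At this scale the feedback's main effect
    is on the probability that cooperation establishes at all, so the
    replicate count is high and the per-replicate payoffs are returned
    alongside the arm means.
    """
    base = config if config is not None else desk_config()
    base = replace(base, mixing=_mixing(lam))
    arms = {}
    for label, mode, freeze_r, seed_off in (
        ("auto", "qs_auto", False, 0),
        ("no_auto", "qs", True, 101),
    ):
        cfg = replace(
            base,
            payoff=replace(base.payoff, mode=mode),
            mutation=replace(base.mutation, freeze_r=freeze_r),
        )
        reps_out = run_replicates(cfg, reps, master_seed + seed_off, keep_results=False)
        arms[label] = {
            "payoffs": np.array([s["payoff_mean"] for s in reps_out.summaries]),
            "r_means": np.array([s["r_mean"] for s in reps_out.summaries]),
        }
    return {
        "auto": arms["auto"],
        "no_auto": arms["no_auto"],
        "auto_mean": float(arms["auto"]["payoffs"].mean()),
        "no_auto_mean": float(arms["no_auto"]["payoffs"].mean()),
        "baseline": base.payoff.baseline,
    }


def assortment_experiment(
    master_seed: int,
    g: int = 5,
    reps: int = 3,
    b_coop: float = 600.0,
    config: SimulationConfig | None = None,
) -> dict:
    """Individual-vs-group investment assortment at fixed founder count.

    Runs both regulatory architectures at fixed ``G`` founders per group,
    pools last-generation investments across replicates, fits the
    group-mean-on-individual regression for each arm and compares slopes
    by ANCOVA. ``b_coop`` defaults above ``C_coop * g`` so the fixed-G
    regime can sustain cooperation at all.
    """
    base = config if config is not None else desk_config()
    base = replace(base, mixing=MixingConfig(fixed_g=g))
    out: dict = {}
    data = {}
    for label, mode, freeze_r, seed_off in (
        ("no_auto", "qs", True, 0),
        ("auto", "qs_auto", False, 101),
    ):
        cfg = replace(
            base,
            payoff=replace(base.payoff, mode=mode, B_coop=b_coop),
            mutation=replace(base.mutation, freeze_r=freeze_r),
        )
        xs, ys = [], []
        for s in replicate_seeds(master_seed + seed_off, reps):
            res = run_simulation(cfg, s)
            ind, grp = cooperative_investment(res.final_eval)
            xs.append(ind)
            ys.append(grp)
        x, y = np.concatenate(xs), np.concatenate(ys)
        data[label] = (x, y)
        out[label] = assortment_analysis(x, y)
    f_stat, p_value = compare_slopes(*data["no_auto"], *data["auto"])
    out["f_stat"] = f_stat
    out["p_value"] = p_value
    return out


def spandrel_profiles(
    strains: dict[str, Genotype] | None = None,
    N: float = 8.5e4,
    u: float = 1e-4,
    m_max: float = 1e-4,
) -> pd.DataFrame:
    """Mass-transfer thresholds of evolved density-sensing strains.

    Returns one row per strain with its parameters and the critical loss
    rate ``m*`` below which it cooperates at the fixed quorate density.
    """
    strains = strains if strains is not None else REFERENCE_STRAINS
    rows = []
    for name, strain in strains.items():
        prof = spandrel_assay(strain, N=N, u=u, m_max=m_max)
        rows.append(
            {
                "strain": name,
                "p": strain.p,
                "S_Th": strain.S_Th,
                "r": strain.r,
                "m_star": np.nan if prof.m_star is None else prof.m_star,
                "s_star_closed": prof.s_star[0],
                "on_fraction_of_grid": float(prof.on.mean()),
            }
        )
    return pd.DataFrame(rows)
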