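"""Named experiment presets.

Each preset encodes the study conditions of one capability of the
simulator at desk scale: the clonal signalling-cost sweep that traces the
coordination line, the genetic-mixing sweep that produces coercion and
collapse, the auto-regulation contrast at high mixing, the fixed-G
assortment experiment and the mass-transfer spandrel assay of previously
evolved strains. ``--scale`` on the command line (or ``scaled()`` on any
config) down-samples pool and generations from these values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

from .evolution import SimulationConfig
from .experiments import COST_SWEEP_VALUES, desk_config
from .population import MixingConfig

__all__ = ["Preset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class Preset:
    """A named family of runs: one config per labelled condition."""

    name: str
    description: str
    conditions: tuple[tuple[str, SimulationConfig], ...]
    reps: int = 3


def _cost_sweep() -> Preset:
    base = desk_config()
    conds = tuple(
        (f"C_sig={c:.3g}", replace(base, payoff=replace(base.payoff, C_sig=float(c))))
        for c in COST_SWEEP_VALUES
    )
    return Preset(
        name="clonal-cost-sweep",
        description=(
            "Clonal evolution across signalling costs; evolved (p, S_Th) trace "
            "the coordination line S_Th = p N_Th / u"
        ),
        conditions=conds,
        reps=3,
    )


def _mixing_sweep() -> Preset:
    base = desk_config()
    conds = [("clonal", base)]
    for lam in (2.0, 3.0, 4.0):
        conds.append(
            (
                f"lambda_g={lam:g}",
                replace(base, mixing=MixingConfig(lambda_g=lam, fixed_g=None)),
            )
        )
    return Preset(
        name="mixing-sweep",
        description=(
            "Genetic-mixing sweep without auto-regulation: coercive escalation "
            "at moderate mixing, payoff collapse toward baseline at high mixing"
        ),
        conditions=tuple(conds),
        reps=5,
    )


def _auto_mixing() -> Preset:
    base = desk_config()
    conds = []
    for lam in (2.0, 4.0):
        mix = MixingConfig(lambda_g=lam, fixed_g=None)
        conds.append(
            (
                f"lambda_g={lam:g}/auto",
                replace(
                    base,
                    mixing=mix,
                    payoff=replace(base.payoff, mode="qs_auto"),
                    mutation=replace(base.mutation, freeze_r=False),
                ),
            )
        )
        conds.append((f"lambda_g={lam:g}/no-auto", replace(base, mixing=mix)))
    return Preset(
        name="auto-mixing-sweep",
        description=(
            "Auto-regulation evolving vs frozen under genetic mixing; the "
            "feedback aids establishment of cooperation at high mixing"
        ),
        conditions=tuple(conds),
        reps=5,
    )


def _assortment_g5() -> Preset:
    base = desk_config()
    # B/C above the founder count keeps fixed five-founder groups inside
    # the cooperative window
    pay = replace(base.payoff, B_coop=600.0)
    mix = MixingConfig(fixed_g=5)
    conds = (
        ("G=5/no-auto", replace(base, mixing=mix, payoff=pay)),
        (
            "G=5/auto",
            replace(
                base,
                mixing=mix,
                payoff=replace(pay, mode="qs_auto"),
                mutation=replace(base.mutation, freeze_r=False),
            ),
        ),
    )
    return Preset(
        name="assortment-g5",
        description=(
            "Fixed five-founder groups with and without auto-regulation; "
            "individual vs group-mean cooperative investment assortment"
        ),
        conditions=conds,
        reps=3,
    )


def _constitutive_mixing() -> Preset:
    base = desk_config()
    conds = [("clonal", replace(base, payoff=replace(base.payoff, mode="constitutive")))]
    for lam in (2.0, 4.0):
        conds.append(
            (
                f"lambda_g={lam:g}",
                replace(
                    base,
                    mixing=MixingConfig(lambda_g=lam, fixed_g=None),
                    payoff=replace(base.payoff, mode="constitutive"),
                ),
            )
        )
    return Preset(
        name="constitutive-mixing",
        description="Constitutive (always-ON) cooperation across mixing levels",
        conditions=tuple(conds),
        reps=3,
    )


_BUILDERS: dict[str, Callable[[], Preset]] = {
    "clonal-cost-sweep": _cost_sweep,
    "mixing-sweep": _mixing_sweep,
    "auto-mixing-sweep": _auto_mixing,
    "assortment-g5": _assortment_g5,
    "constitutive-mixing": _constitutive_mixing,
}

PRESETS = tuple(_BUILDERS)


def get_preset(name: str) -> Preset:
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}") from None
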