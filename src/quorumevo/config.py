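"""Structured-text configuration for simulation runs.

Configs are TOML with nested sections mirroring the domain types. Unknown
sections or keys are rejected so that typos fail loudly, and every config
round-trips losslessly through :func:`dump_config` / :func:`parse_config`
— the config echo written into an output directory reproduces the run
exactly when re-fed.
"""

from __future__ import annotations

import math
import tomllib
from pathlib import Path

from .core_dynamics import DynamicsParams
from .evolution import SimulationConfig
from .fitness import PayoffParams
from .population import MixingConfig, MutationModel, TraitBounds

__all__ = ["parse_config", "parse_config_text", "dump_config"]

_SCHEMA: dict[str, dict[str, type]] = {
    "simulation": {
        "pool_size": int,
        "generations": int,
        "cheat_injection_rate": float,
        "summary_window": int,
    },
    "mixing": {"lambda_g": float, "fixed_g": int, "law": str},
    "mutation": {
        "p_prob": float,
        "s_prob": float,
        "r_prob": float,
        "p_scale": float,
        "s_scale": float,
        "r_scale": float,
        "freeze_p": bool,
        "freeze_s": bool,
        "freeze_r": bool,
    },
    "payoff": {
        "C_sig": float,
        "C_coop": float,
        "B_coop": float,
        "N_Th": float,
        "baseline": float,
        "mode": str,
    },
    "dynamics": {"K": float},
    "environment": {"u": float, "m": float, "noise_sd": float},
    "grid": {"low": float, "high": float, "count": int},
    "init": {"p": float, "S_Th": float, "r": float},
    "bounds": {"p_max": float, "s_max": float, "r_max": float},
}


def _check(data: dict) -> None:
    for section, content in data.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section [{section}]")
        if not isinstance(content, dict):
            raise ValueError(f"[{section}] must be a table")
        for key in content:
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown key {key!r} in section [{section}]")


def _coerce(section: str, content: dict) -> dict:
    out = {}
    for key, value in content.items():
        want = _SCHEMA[section][key]
        if want is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if not isinstance(value, want):
            raise ValueError(
                f"config key {section}.{key} must be {want.__name__}, got {value!r}"
            )
        out[key] = value
    return out


def parse_config_text(text: str) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from TOML text."""
    data = tomllib.loads(text)
    _check(data)
    sec = {name: _coerce(name, data.get(name, {})) for name in _SCHEMA}

    mix_kwargs = dict(sec["mixing"])
    if "lambda_g" in mix_kwargs:
        mix_kwargs.setdefault("fixed_g", None)
        if mix_kwargs["fixed_g"] is not None:
            raise ValueError("set either mixing.lambda_g or mixing.fixed_g, not both")
    mixing = MixingConfig(**mix_kwargs) if mix_kwargs else MixingConfig(fixed_g=1)

    cfg = SimulationConfig(
        mixing=mixing,
        mutation=MutationModel(**sec["mutation"]),
        payoff=PayoffParams(**sec["payoff"]),
        dynamics=DynamicsParams(**sec["dynamics"]),
        bounds=TraitBounds(**sec["bounds"]),
        **sec["simulation"],
        **{
            {"low": "grid_low", "high": "grid_high", "count": "grid_count"}[k]: v
            for k, v in sec["grid"].items()
        },
        **{{"p": "init_p", "S_Th": "init_s_th", "r": "init_r"}[k]: v for k, v in sec["init"].items()},
        **sec["environment"],
    )
    return cfg


def parse_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a TOML config file."""
    text = Path(path).read_text()
    return parse_config_text(text)


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, float):
        if math.isinf(value) or math.isnan(value):
            raise ValueError(f"cannot serialise non-finite value {value!r}")
        return repr(value)
    return str(value)


def dump_config(config: SimulationConfig) -> str:
    """Serialise a config to TOML (inverse of :func:`parse_config_text`)."""
    mix: dict = {"law": config.mixing.law}
    if config.mixing.fixed_g is not None:
        mix["fixed_g"] = config.mixing.fixed_g
    else:
        mix["lambda_g"] = config.mixing.lambda_g
    sections = {
        "simulation": {
            "pool_size": config.pool_size,
            "generations": config.generations,
            "cheat_injection_rate": config.cheat_injection_rate,
            "summary_window": config.summary_window,
        },
        "mixing": mix,
        "mutation": {
            k: getattr(config.mutation, k) for k in _SCHEMA["mutation"]
        },
        "payoff": {k: getattr(config.payoff, k) for k in _SCHEMA["payoff"]},
        "dynamics": {"K": config.dynamics.K},
        "environment": {"u": config.u, "m": config.m, "noise_sd": config.noise_sd},
        "grid": {"low": config.grid_low, "high": config.grid_high, "count": config.grid_count},
        "init": {"p": config.init_p, "S_Th": config.init_s_th, "r": config.init_r},
        "bounds": {k: getattr(config.bounds, k) for k in _SCHEMA["bounds"]},
    }
    lines = []
    for name, content in sections.items():
        lines.append(f"[{name}]")
        for key, value in content.items():
            lines.append(f"{key} = {_fmt(value)}")
        lines.append("")
    return "\n".join(lines)
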