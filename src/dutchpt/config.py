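"""YAML configuration loading and object construction.

Two key groups are recognised: environment/design keys (clock, stimulus
ranges, session structure) and agent keys (prospect-theory parameters and
the opponent belief).  Unknown keys raise a named error so typos surface
immediately.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .auction_env import ExperimentDesign
from .prospect_agent import OpponentBelief, ProspectParams

__all__ = [
    "load_config",
    "make_design",
    "make_params",
    "make_belief",
    "DESIGN_KEYS",
    "AGENT_KEYS",
]

DESIGN_KEYS = {
    "duration_s",
    "dt_s",
    "start_price_low",
    "start_price_high",
    "unit_mode",
    "unit_low",
    "unit_high",
    "budget",
    "warehouse",
    "n_groups",
    "n_blocks",
    "trials_per_block",
    "seed",
}
AGENT_KEYS = {
    "alpha",
    "beta",
    "lambda",
    "gamma",
    "delta",
    "c",
    "V",
    "mu",
    "sigma",
    "softmax_sign",
    "value_anchor",
    "wait_cost_time",
}


def load_config(path) -> dict:
    """Load and key-validate a YAML config file."""
    cfg = yaml.safe_load(Path(path).read_text())
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    unknown = set(cfg) - DESIGN_KEYS - AGENT_KEYS
    if unknown:
        raise KeyError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return cfg


def make_design(cfg: dict) -> ExperimentDesign:
    kwargs = {}
    if "n_groups" in cfg:
        kwargs["n_groups"] = int(cfg["n_groups"])
    if "n_blocks" in cfg:
        kwargs["n_blocks"] = int(cfg["n_blocks"])
    if "trials_per_block" in cfg:
        kwargs["trials_per_block"] = int(cfg["trials_per_block"])
    if "start_price_low" in cfg or "start_price_high" in cfg:
        kwargs["start_price_range"] = (
            float(cfg.get("start_price_low", 50.0)),
            float(cfg.get("start_price_high", 150.0)),
        )
    if "unit_mode" in cfg:
        kwargs["unit_mode"] = str(cfg["unit_mode"])
    if "unit_low" in cfg or "unit_high" in cfg:
        kwargs["unit_range"] = (
            int(cfg.get("unit_low", 50)),
            int(cfg.get("unit_high", 150)),
        )
    if "budget" in cfg:
        kwargs["budget"] = float(cfg["budget"])
    if "warehouse" in cfg:
        kwargs["warehouse_capacity"] = int(cfg["warehouse"])
    return ExperimentDesign(**kwargs)


def make_params(cfg: dict) -> ProspectParams:
    mapping = {
        "alpha": "alpha",
        "beta": "beta",
        "lambda": "lam",
        "gamma": "gamma",
        "delta": "delta",
        "c": "c",
        "V": "V",
        "softmax_sign": "softmax_sign",
        "value_anchor": "value_anchor",
        "wait_cost_time": "wait_cost_time",
    }
    kwargs = {dst: cfg[src] for src, dst in mapping.items() if src in cfg}
    return ProspectParams(**kwargs)


def make_belief(cfg: dict, n_opponents: int = 2) -> OpponentBelief:
    kwargs = {"n_opponents": n_opponents}
    if "mu" in cfg:
        kwargs["mu"] = float(cfg["mu"])
    if "sigma" in cfg:
        kwargs["sigma"] = float(cfg["sigma"])
    if "duration_s" in cfg:
        kwargs["duration"] = float(cfg["duration_s"])
    return OpponentBelief(**kwargs)
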