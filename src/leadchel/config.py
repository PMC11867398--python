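"""Configuration loading, validation, and object construction.

A run is configured by one YAML document merged over the packaged defaults
(``data/defaults.yaml``).  Validation is structural: keys unknown to the
defaults are rejected with a list of the offending paths, so typos fail
fast rather than silently running the base case.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Any

import yaml

from .cohort import CohortSpec
from .econ import (CostInputs, DiscountRates, ProductivityInputs,
                   UtilityInputs)
from .model import ModelInputs, SurvivalInputs, SurvivalParamSet
from .strategy import InterventionCosting


class ConfigError(ValueError):
    pass


def default_config() -> dict:
    text = resources.files("leadchel").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def _merge(base: dict, override: dict, path: str = "") -> tuple[dict, list[str]]:
    out = dict(base)
    bad: list[str] = []
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            # survival_params is a free-form optional block
            if path == "" and key == "survival_params":
                out[key] = value
                continue
            bad.append(here)
            continue
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key], worse = _merge(base[key], value, here)
            bad += worse
        else:
            out[key] = value
    return out, bad


def load_config(path: str | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults merged with a user YAML file and/or an override dict."""
    cfg = default_config()
    for layer in (_read_yaml(path) if path else None, overrides):
        if layer:
            cfg, bad = _merge(cfg, layer)
            if bad:
                raise ConfigError(f"unknown configuration keys: {bad}")
    return cfg


def _read_yaml(path: str) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"configuration file {path} is not a mapping")
    return data


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def cohort_spec(cfg: dict, seed: int) -> CohortSpec:
    c = cfg["cohort"]
    boundaries = c.get("tertile_boundaries")
    return CohortSpec(
        n_patients=int(c["n_patients"]),
        lead_median=float(c["lead_median"]),
        lead_iqr=tuple(c["lead_iqr"]),
        tertile_boundaries=tuple(boundaries) if boundaries else None,
        gf_params_per_group={g: tuple(v) for g, v in
                             c["gf_params_per_group"].items()},
        dwfg_params=tuple(c["dwfg_params"]),
        dwgf_params=tuple(c["dwgf_params"]),
        max_followup=float(c["max_followup"]),
        seed=seed,
    )


def survival_inputs_from_config(block: dict) -> SurvivalInputs:
    """Build survival inputs from an externally supplied parameter block."""
    def one(d: dict) -> SurvivalParamSet:
        return SurvivalParamSet(
            family=d["family"],
            params={k: float(v) for k, v in d["params"].items()},
            se={k: float(v) for k, v in d.get("se", {}).items()},
            ci={k: (float(v[0]), float(v[1]))
                for k, v in d.get("ci", {}).items()},
        )
    return SurvivalInputs(
        gf={g: one(d) for g, d in block["gf"].items()},
        dwfg=one(block["dwfg"]),
        dwgf=one(block["dwgf"]),
    )


def model_inputs(cfg: dict, survival: SurvivalInputs) -> ModelInputs:
    m = cfg["model"]
    return ModelInputs(
        survival=survival,
        costs=CostInputs(**{**cfg["costs"],
                            "modality_mix": tuple(cfg["costs"]["modality_mix"])}),
        utilities=UtilityInputs(**cfg["utilities"]),
        productivity=ProductivityInputs(**cfg["productivity"]),
        rates=DiscountRates(**cfg["discounting"]),
        intervention_costing=InterventionCosting(**cfg["intervention_costing"]),
        group_mix={g: float(v) for g, v in m["group_mix"].items()},
        p_retransplant_base=float(m["p_retransplant_base"]),
        age_decline_start=float(m["age_decline_start"]),
        age_decline_zero=float(m["age_decline_zero"]),
        p_primary_nonfunction=float(m["p_primary_nonfunction"]),
        baseline_age=float(m["baseline_age"]),
        horizon=int(m["horizon"]),
        cohort_size=float(m["cohort_size"]),
    )


def manifest(cfg: dict, seeds: dict[str, int]) -> dict[str, Any]:
    import numpy
    import scipy

    from . import __version__
    return {
        "config_hash": config_hash(cfg),
        "seeds": seeds,
        "versions": {"leadchel": __version__,
                     "numpy": numpy.__version__,
                     "scipy": scipy.__version__},
    }
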