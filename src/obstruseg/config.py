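"""Global configuration: every tunable default in one place, overridable
from a YAML file."""

from __future__ import annotations

import copy
import logging

import yaml

DEFAULTS: dict = {
    "phantom": {
        "size": 96,
        "noise_sd": 0.05,
        "background_level": 0.25,
        "air_level": 0.05,
        "fluid_level": 0.9,
        "airfluid_fraction": 0.35,
    },
    "blocks": {"block_size": 16, "overlap_step": 8, "vote": "mean"},
    "features": {"entropy_bins": 32, "glcm_levels": 8},
    "bpnn": {
        "n_hidden": 6,
        "learning_rate": 0.5,
        "max_epochs": 200,
        "error_goal": 1e-3,
        "momentum": 0.0,
    },
    "ga": {
        "population_size": 40,
        "max_generations": 100,
        "n_fitness_groups": 4,
        "gmm_offspring_fraction": 0.3,
        "gmm_components": 2,
        "crossover_rate": 0.8,
        "mutation_rate": 0.05,
        "mutation_sd": 0.1,
        "selection_pressure": 1.8,
        "plateau_window": 20,
        "plateau_tol": 1e-6,
        "elitism_count": 1,
    },
    "graphcut": {"lambda": 2.0, "sigma": 0.1, "enabled": True},
    "edge": {"low": 0.05, "high": 0.15, "fill": True},
    "evaluate": {"k_folds": 5, "hidden_counts": [2, 3, 4, 5, 6, 7, 8]},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Defaults, deep-merged with an optional YAML override file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, override)


def setup_logging(seed=None, level=logging.INFO) -> None:
    """ISO-timestamped log lines carrying the active seed."""
    tag = f" [seed={seed}]" if seed is not None else ""
    logging.basicConfig(
        level=level,
        format=f"%(asctime)s{tag} %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
        force=True,
    )
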