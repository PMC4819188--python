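"""Structured text configuration for descriptors, encoding, GA and SVMs."""

from __future__ import annotations

from pathlib import Path

import yaml

from .chemio import registry_names

DEFAULT_CONFIG: dict = {
    "descriptors": {
        # active descriptor pool before feature selection: full registry
        "active": registry_names(),
    },
    "receptor": {
        "lambda": 20,
        "w": 0.05,
        "scale_path": None,  # None -> bundled T-scale
        "impute_unknown": False,
    },
    "ga": {
        "W": 0.007,
        "population_size": 40,
        "generations": 30,
        "elitism_count": 1,
        "crossover_rate": 0.9,
        "r_max": 0.95,
        "cv_folds": 5,
        "stagnation_limit": 10,
        "fitness_metric": "q2",
    },
    "svm": {
        "bitterant": {"C": 32.0, "gamma": 0.015625, "cv_folds": 5},
        "pair": {"C": 8.0, "gamma": 0.125, "cv_folds": 5},
    },
    "pipeline": {
        "atom_limit": 200,
        "bitter_threshold": 0.5,
        "fingerprint_bits": 1024,
        "fingerprint_max_path": 7,
    },
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, recursively filling gaps with the defaults."""
    cfg = _deep_copy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(cfg, user)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def _deep_copy(d: dict) -> dict:
    return {k: _deep_copy(v) if isinstance(v, dict) else (list(v) if isinstance(v, list) else v) for k, v in d.items()}


def _deep_update(base: dict, patch: dict) -> None:
    for k, v in patch.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
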