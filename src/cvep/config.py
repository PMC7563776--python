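"""YAML-driven configuration with documented defaults.

A config file may override any subset of the sections below; unknown keys
are rejected to catch typos.  All CLI subcommands accept ``--config``.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

DEFAULT_CONFIG: dict[str, Any] = {
    "io": {
        # file-column -> canonical score name/id remapping
        "column_map": {},
        # extra ClinVar significance strings -> class code
        "clinvar_map": {},
    },
    "preprocess": {
        "downsample_factor": 7,       # uncertain-significance thinning
        "downsample_target": 0,       # class code to thin
        "balance_mode": "weight",     # weight | replicate
        "drop_rows_without_scores": True,
        "seed": 0,
    },
    "learners": {
        "GLM": {"regularization": 1e-4, "max_iter": 1000},
        "GBM": {
            "ntrees": 150, "max_depth": 6, "learn_rate": 0.1,
            "sample_rate": 0.8, "min_rows": 20,
        },
        "DRF": {
            "ntrees": 150, "max_depth": 20, "sample_rate": 0.632,
            "min_rows": 1, "col_sample": "sqrt",
        },
        # default grids for `grid_search`; the tuned values behind the
        # original models were never published, so these are package
        # defaults rather than claims
        "grids": {
            "GLM": {"regularization": [1e-5, 1e-4, 1e-3]},
            "GBM": {"ntrees": [100, 150], "max_depth": [4, 6], "learn_rate": [0.1]},
            "DRF": {"ntrees": [100, 150], "max_depth": [12, 20]},
        },
    },
    "ensemble": {
        "folds": 5,
        "seed": 0,
        "mode": "categorical",        # categorical | continuous
        "chunk_size": 10000,
    },
    "synthetic": {
        "n": 1000,
        "correlation": 0.3,
        "class_noise": 0.05,
        "missingness": [23, 40],
        "indispensability_enrichment": 6.0,
        "aaf_ultrarare_mass": 0.85,
        "aaf_anticorrelation": True,
        "genes": 200,
        "seed": 0,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in out:
            # extensible leaf tables accept arbitrary keys
            if path in ("io.column_map", "io.clinvar_map", "learners.grids"):
                out[key] = value
                continue
            raise KeyError(f"unknown config key {where!r}")
        if isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _merge(out[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Defaults merged with an optional YAML override file."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return _merge(DEFAULT_CONFIG, override)
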