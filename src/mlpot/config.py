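"""YAML run configuration: strict parsing, defaults, round-trip emission.

The config vocabulary mirrors the hyperparameter names used throughout the
framework (embedding_dimension, num_layers, num_rbf, cutoff,
max_num_neighbors, vector_cutoff, ...).  Unknown keys are rejected with a
field-level message; every run emits its fully-resolved config beside its
checkpoints so it can be reproduced exactly.
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["RunConfig", "ConfigError", "parse_config", "emit_config", "load_config"]


class ConfigError(ValueError):
    pass


_MODEL_DEFAULTS = {
    "model": "tensornet",
    "embedding_dimension": 128,
    "num_layers": 2,
    "num_rbf": 32,
    "cutoff": 4.5,
    "trainable_rbf": False,
    "max_num_neighbors": 32,
    "max_z": 100,
    "vector_cutoff": True,
    "derivative": True,
    "hidden_channels": 64,
    "reduce_op": "sum",
    "seed": 0,
    "precision": 64,
}

_DATASET_DEFAULTS = {
    "format": "custom",  # custom | hdf5
    "coordglob": None,
    "embedglob": None,
    "energyglob": None,
    "forceglob": None,
    "path": None,
    "train_size": 0.8,
    "val_size": 0.1,
    "test_size": 0.1,
    "split_seed": 0,
    "split_file": None,
}

_TRAINING_DEFAULTS = {
    "epochs": 100,
    "batch_size": 32,
    "learning_rate": 1e-2,
    "energy_weight": 1.0,
    "force_weight": 0.0,
    "ema_alpha": 0.05,
    "seed": 0,
    "lr_factor": 0.5,
    "lr_patience": 20,
    "lr_min": 1e-5,
}

_OUTPUT_DEFAULTS = {
    "log_dir": "logs",
    "checkpoint_dir": "checkpoints",
}

_PRIOR_KEYS = {
    "atomref": {"table", "trainable"},
    "coulomb": {"switching_distance", "k"},
    "zbl": {"cutoff", "k"},
    "d2": {"s6", "d", "c6_conversion"},
}

_SECTIONS = {
    "model": _MODEL_DEFAULTS,
    "dataset": _DATASET_DEFAULTS,
    "training": _TRAINING_DEFAULTS,
    "output": _OUTPUT_DEFAULTS,
}


class RunConfig(dict):
    """Fully-resolved run configuration (a plain nested dict, validated)."""


def _merge_section(name: str, defaults: dict, given: dict) -> dict:
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{name}'; "
            f"valid keys: {sorted(defaults)}"
        )
    out = dict(defaults)
    out.update(given)
    return out


def parse_config(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - (set(_SECTIONS) | {"priors"})
    if unknown:
        raise ConfigError(
            f"unknown section(s) {sorted(unknown)}; valid sections: "
            f"{sorted(set(_SECTIONS) | {'priors'})}"
        )
    cfg = RunConfig()
    for name, defaults in _SECTIONS.items():
        given = raw.get(name, {}) or {}
        if not isinstance(given, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        cfg[name] = _merge_section(name, defaults, given)
    priors = raw.get("priors", []) or []
    if not isinstance(priors, list):
        raise ConfigError("section 'priors' must be a list")
    cfg["priors"] = []
    for i, p in enumerate(priors):
        if not isinstance(p, dict) or "kind" not in p:
            raise ConfigError(f"priors[{i}] must be a mapping with a 'kind' key")
        kind = p["kind"]
        if kind not in _PRIOR_KEYS:
            raise ConfigError(
                f"priors[{i}]: unknown kind {kind!r}; valid: {sorted(_PRIOR_KEYS)}"
            )
        unknown = set(p) - _PRIOR_KEYS[kind] - {"kind"}
        if unknown:
            raise ConfigError(
                f"priors[{i}] ({kind}): unknown key(s) {sorted(unknown)}"
            )
        cfg["priors"].append(copy.deepcopy(p))
    _validate_values(cfg)
    return cfg


def _validate_values(cfg: RunConfig) -> None:
    m = cfg["model"]
    if m["model"] not in ("tensornet", "equivariant_transformer", "graph_network"):
        raise ConfigError(f"model.model: unknown model {m['model']!r}")
    if m["precision"] not in (32, 64):
        raise ConfigError("model.precision must be 32 or 64")
    if m["cutoff"] <= 0:
        raise ConfigError("model.cutoff must be positive")
    t = cfg["training"]
    if t["energy_weight"] < 0 or t["force_weight"] < 0:
        raise ConfigError("training weights must be non-negative")
    if t["energy_weight"] == 0 and t["force_weight"] == 0:
        raise ConfigError("at least one of energy_weight/force_weight must be > 0")
    d = cfg["dataset"]
    if d["format"] not in ("custom", "hdf5"):
        raise ConfigError(f"dataset.format: unknown format {d['format']!r}")
    if d["format"] == "custom":
        for key in ("coordglob", "embedglob", "energyglob"):
            if not d[key]:
                raise ConfigError(f"dataset.{key} is required for format 'custom'")
    elif not d["path"]:
        raise ConfigError("dataset.path is required for format 'hdf5'")


def emit_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(dict(cfg), sort_keys=True)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)
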