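"""Run configuration: a single YAML file with one section per pipeline stage.

``validate_config`` type- and range-checks every field against the schema,
fills defaults, and returns the normalized nested dict; violations are
collected and reported together with their dotted key paths (e.g.
``train.lr``).  The normalized snapshot is persisted into the run directory
by the pipeline so each run carries its exact configuration.
"""

from __future__ import annotations

import copy
import dataclasses
from pathlib import Path
from typing import Any, Callable

import yaml

from .phantom import PHASES

_POS = ("must be > 0", lambda v: v > 0)
_NONNEG = ("must be >= 0", lambda v: v >= 0)
_FRAC = ("must lie in (0, 1)", lambda v: 0 < v < 1)
_PROP = ("must lie in [0, 1]", lambda v: 0 <= v <= 1)


def _phases_ok(v) -> bool:
    return 1 <= len(v) <= 4 and all(p in PHASES for p in v) and len(set(v)) == len(v)


# key -> (default, type(s), (message, predicate) | None)
SCHEMA: dict[str, dict[str, tuple[Any, Any, tuple[str, Callable[[Any], bool]] | None]]] = {
    "phantom": {
        "n_patients": (120, int, _POS),
        "mvi_fraction": (1.0 / 3.0, float, _PROP),
        "volume_shape": ([64, 64, 64], list, ("must be three sides >= 48", lambda v: len(v) == 3 and all(isinstance(s, int) and s >= 48 for s in v))),
        "tumor_radius_range": ([8.0, 13.0], list, ("must be an ordered positive pair", lambda v: len(v) == 2 and 0 < v[0] <= v[1])),
        "margin_irregularity_amp": (2.5, (int, float), _NONNEG),
        "ap_ring_contrast": (40.0, (int, float), _NONNEG),
        "hbp_ring_contrast": (50.0, (int, float), _NONNEG),
        "ring_thickness": (2, int, _POS),
        "noise_sd": (10.0, (int, float), _NONNEG),
        "seed": (0, int, None),
    },
    "split": {
        "test_fraction": (0.2, float, _FRAC),
        "n_folds": (5, int, ("must be >= 2", lambda v: v >= 2)),
        "seed": (0, int, None),
    },
    "network": {
        "phases": (list(PHASES), list, ("must be 1-4 distinct phases among " + ", ".join(PHASES), _phases_ok)),
        "conv_channels": ([6, 16, 16], list, ("must be three positive channel counts", lambda v: len(v) == 3 and all(isinstance(c, int) and c > 0 for c in v))),
        "fc_feature_dim_per_phase": (32, int, _POS),
        "dropout_rate": (0.5, (int, float), ("must lie in [0, 1)", lambda v: 0 <= v < 1)),
        "attention_gamma_init": (0.0, (int, float), None),
        "attention_d_qk": (2, int, _POS),
    },
    "train": {
        "batch_size": (16, int, _POS),
        "epochs": (50, int, _POS),
        "max_iterations": (501, int, _POS),
        "lr": (0.004, (int, float), _POS),
        "momentum": (0.9, (int, float), _NONNEG),
        "weight_decay": (0.0001, (int, float), _NONNEG),
        "loss_weights": (None, (list, type(None)), ("must be positive numbers", lambda v: v is None or all(w > 0 for w in v))),
        "fused_head_weight": (1.0, (int, float), _NONNEG),
        "early_stop_patience": (5, int, _POS),
        "eval_interval": (None, (int, type(None)), ("must be > 0", lambda v: v is None or v > 0)),
        "seed": (0, int, None),
    },
    "evaluate": {
        "n_boot": (2000, int, _POS),
        "threshold": ("youden", (str, float), ("must be 'youden' or a probability", lambda v: v == "youden" or 0 <= float(v) <= 1)),
        "dca_grid": ([0.01, 0.60, 0.01], list, ("must be [start, stop, step] in (0,1)", lambda v: len(v) == 3 and 0 < v[0] <= v[1] < 1 and v[2] > 0)),
    },
    "explain": {
        "layer": ("collaborative_attention", str, ("must be self_attention or collaborative_attention", lambda v: v in ("self_attention", "collaborative_attention"))),
        "shell_inner": (2, int, _NONNEG),
        "shell_outer": (2, int, _NONNEG),
        "n_examples": (4, int, _POS),
    },
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


def default_config() -> dict[str, dict[str, Any]]:
    return {sec: {k: copy.deepcopy(d) for k, (d, _, _) in fields.items()} for sec, fields in SCHEMA.items()}


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load + validate a YAML config; missing file sections fall back to defaults.

    Raises :class:`ConfigError` listing every violation with its key path.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError([f"top level must be a mapping of sections, got {type(loaded).__name__}"])
        raw = loaded
    if overrides:
        for sec, kv in overrides.items():
            raw.setdefault(sec, {}).update(kv)

    errors: list[str] = []
    for sec in raw:
        if sec not in SCHEMA:
            errors.append(f"{sec}: unknown section (choose from {sorted(SCHEMA)})")
    cfg = default_config()
    for sec, fields in SCHEMA.items():
        given = raw.get(sec, {})
        if not isinstance(given, dict):
            errors.append(f"{sec}: must be a mapping")
            continue
        for key in given:
            if key not in fields:
                errors.append(f"{sec}.{key}: unknown key")
        for key, (default, types, check) in fields.items():
            if key not in given:
                continue
            v = given[key]
            ok_types = types if isinstance(types, tuple) else (types,)
            if isinstance(v, bool) or not isinstance(v, ok_types):
                if not (float in ok_types and isinstance(v, int) and not isinstance(v, bool)):
                    errors.append(f"{sec}.{key}: expected {'/'.join(t.__name__ for t in ok_types)}, got {v!r}")
                    continue
            if check is not None and not check[1](v):
                errors.append(f"{sec}.{key}: {check[0]} (got {v!r})")
                continue
            cfg[sec][key] = copy.deepcopy(v)
    if errors:
        raise ConfigError(errors)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
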