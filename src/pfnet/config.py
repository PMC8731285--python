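"""Run configuration: defaults, YAML loading, and resolved-config dumps.

Every pipeline run resolves one nested configuration (paths, windowing,
wavelet options, model variant and widths, training schedule, seed) and
freezes a copy next to its outputs, so any result can be regenerated
from the artifact directory alone.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

#: Defaults reproduce the reference experimental profile where one is
#: stated (200 ms windows, 10 ms step, rest excluded, batch 1000,
#: 28 epochs, lr 0.1 dropped 10x at epochs 16 and 24).
DEFAULTS = {
    "paths": {"data_dir": "data", "output_dir": "out"},
    "windowing": {"window_ms": 200.0, "step_ms": 10.0, "exclude_rest": True},
    "dwpt": {"mode": "periodization", "order": "natural"},
    "model": {
        "variant": "full",
        "maps": 64,
        "fc_feature": 512,
        "fc_knowledge": 1024,
        "fc_fusion": 512,
        "standardize": True,
        "loss_mode": "per_head",
    },
    "train": {
        "batch_size": 1000,
        "epochs": 28,
        "lr_initial": 0.1,
        "lr_drop_epochs": [16, 24],
        "lr_drop_factor": 10.0,
        "dropout_pretrain": 0.5,
        "dropout_train": 0.65,
        "finetune_epochs": None,
    },
    "eval": {"variants": ["full", "FLonly", "DKonly"]},
    "synthetic": {},
    "seed": 0,
}

#: Desk-scale overrides: same topology, smaller widths and schedule.
DESK_SCALE = {
    "windowing": {"step_ms": 100.0},
    "model": {"maps": 16, "fc_feature": 128, "fc_knowledge": 128, "fc_fusion": 64},
    "train": {
        "batch_size": 64,
        "epochs": 10,
        "lr_drop_epochs": [6, 9],
        "finetune_epochs": 6,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def resolve_config(config_path=None, desk_scale=False, overrides=None) -> dict:
    """Layer DEFAULTS <- (desk-scale profile) <- YAML file <- overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if desk_scale:
        cfg = _merge(cfg, DESK_SCALE)
    if config_path is not None:
        loaded = yaml.safe_load(Path(config_path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{config_path}: expected a mapping at top level")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def freeze_config(cfg: dict, out_dir) -> Path:
    """Write the fully resolved config next to the run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
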