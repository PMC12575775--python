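"""YAML-driven pipeline runner.

A config file is a mapping with an optional master ``seed`` and a ``stages``
list; each stage entry names a stage and its keyword arguments.  Stages run
in order; a run log (config hash, package version, per-stage seeds) is
written next to the config.  Reruns with the same config and seed are
bit-reproducible for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError
from . import stages as _stages

_STAGE_FUNCS = {
    "phantom": _stages.stage_phantom,
    "train-ddpm": _stages.stage_train_ddpm,
    "repaint": _stages.stage_repaint,
    "augment": _stages.stage_augment,
    "evaluate-seg": _stages.stage_evaluate_seg,
    "ef": _stages.stage_ef,
    "survey-stats": _stages.stage_survey_stats,
}

_STAGE_KEYS = {
    "phantom": {"out", "n", "preset", "seed", "image_size", "anatomy_scale"},
    "train-ddpm": {"data", "out", "seed", "config"},
    "repaint": {
        "ckpt",
        "image",
        "mask",
        "out",
        "seed",
        "jump_length",
        "n_resample",
        "sampling_steps",
    },
    "augment": {
        "data",
        "ckpt",
        "out",
        "n_aug",
        "seed",
        "no_repaint",
        "layout",
        "sampling_steps",
        "jump_length",
        "n_resample",
    },
    "evaluate-seg": {"pred", "ref", "label", "out", "hd_percentile"},
    "ef": {"a2c", "a4c", "out", "n_discs"},
    "survey-stats": {"responses", "out", "p0"},
}

_SEEDED_STAGES = {"phantom", "train-ddpm", "repaint", "augment"}
_TOP_KEYS = {"seed", "stages"}


def _validate(cfg) -> list:
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    stages = cfg.get("stages")
    if not isinstance(stages, list) or not stages:
        raise ConfigError("config must define a non-empty 'stages' list")
    for i, entry in enumerate(stages):
        if not isinstance(entry, dict) or "stage" not in entry:
            raise ConfigError(f"stage {i} must be a mapping with a 'stage' key")
        name = entry["stage"]
        if name not in _STAGE_FUNCS:
            raise ConfigError(f"stage {i}: unknown stage {name!r}")
        unknown = set(entry) - _STAGE_KEYS[name] - {"stage"}
        if unknown:
            raise ConfigError(
                f"stage {i} ({name}): unknown keys {sorted(unknown)}"
            )
    return stages


def run_config(config_path, write_log: bool = True):
    """Execute the stages of a YAML config; returns the per-stage results."""
    config_path = Path(config_path)
    text = config_path.read_text()
    cfg = yaml.safe_load(text)
    stage_list = _validate(cfg)
    master_seed = int(cfg.get("seed", 0))

    results = []
    log = {
        "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "package_version": __version__,
        "master_seed": master_seed,
        "stages": [],
    }
    for i, entry in enumerate(stage_list):
        name = entry["stage"]
        kwargs = {k: v for k, v in entry.items() if k != "stage"}
        if name in _SEEDED_STAGES and "seed" not in kwargs:
            kwargs["seed"] = master_seed + i
        results.append(_STAGE_FUNCS[name](**kwargs))
        log["stages"].append({"stage": name, "seed": kwargs.get("seed")})
    if write_log:
        log_path = config_path.with_suffix(config_path.suffix + ".runlog.json")
        log_path.write_text(json.dumps(log, indent=1, sort_keys=True))
    return results
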