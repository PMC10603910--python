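"""YAML configuration: ``model:`` and ``train:`` blocks validated into
:class:`~secpnet.nets.NetworkConfig` and :class:`~secpnet.training.TrainPlan`."""

from __future__ import annotations

from pathlib import Path

import yaml

from .nets import NetworkConfig
from .training import TrainPlan

__all__ = ["load_config", "model_config_from_dict", "train_plan_from_dict"]

_MODEL_KEYS = {
    "num_classes",
    "in_channels",
    "depth",
    "stage_channels",
    "se_reduction",
    "batch_norm",
    "upsample_mode",
}
_TRAIN_KEYS = {
    "epochs_total",
    "lr0",
    "momentum",
    "weight_decay",
    "batch_size",
    "stages",
    "loss_base",
    "finetune_lr_scale",
    "plateau_patience",
    "plateau_rel_tol",
    "stage_epochs",
    "seed",
}


def model_config_from_dict(d: dict) -> NetworkConfig:
    unknown = set(d) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"unknown model config keys: {sorted(unknown)}")
    if "stage_channels" in d:
        d = {**d, "stage_channels": tuple(d["stage_channels"])}
    return NetworkConfig(**d)


def train_plan_from_dict(d: dict) -> tuple:
    """Returns (TrainPlan, seed); seed defaults to 0 when absent."""
    unknown = set(d) - _TRAIN_KEYS
    if unknown:
        raise ValueError(f"unknown train config keys: {sorted(unknown)}")
    d = dict(d)
    seed = int(d.pop("seed", 0))
    if "stages" in d:
        d["stages"] = tuple(d["stages"])
    return TrainPlan(**d), seed


def load_config(path):
    """Parse a YAML config file into its validated blocks.

    Returns a dict with keys ``model`` (NetworkConfig or None), ``train``
    ((TrainPlan, seed) or None) and ``raw`` (the full parsed document, so
    callers can read extra blocks such as ``phantom:``).
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")
    return {
        "model": model_config_from_dict(doc["model"]) if "model" in doc else None,
        "train": train_plan_from_dict(doc["train"]) if "train" in doc else None,
        "raw": doc,
    }
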