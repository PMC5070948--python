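"""YAML configuration: overrides for task, neuron-model and eye parameters.

A config file has optional top-level sections ``task``, ``neuron``,
``eye`` and ``seed``; each section holds field overrides applied on top
of the corresponding dataclass defaults, e.g.::

    task:
      iti_mean: 2.0
    neuron:
      baseline_rate: 7.0
    eye:
      intensity_threshold: 230
    seed: 7
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .eyeblink import EyeConfig
from .synthetic.neurons import NeuronModelParams
from .synthetic.tasks import TaskSpec


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must hold a mapping of sections")
    return cfg


def apply_task_overrides(spec: TaskSpec, cfg: dict) -> TaskSpec:
    overrides = cfg.get("task", {})
    return replace(spec, **overrides) if overrides else spec


def neuron_params_from_config(cfg: dict) -> NeuronModelParams | None:
    overrides = cfg.get("neuron")
    if not overrides:
        return None
    return NeuronModelParams(**overrides)


def eye_config_from_config(cfg: dict) -> EyeConfig:
    overrides = cfg.get("eye", {})
    if "delay_window" in overrides:
        overrides = dict(overrides, delay_window=tuple(overrides["delay_window"]))
    return EyeConfig(**overrides)
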