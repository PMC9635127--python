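"""Single-file model checkpoints: weights plus the embedded config."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .model import ModelConfig, Weights, weight_shapes


def save_checkpoint(path: str | Path, weights: Weights, config: ModelConfig) -> None:
    """Write weights and config to one portable ``.npz`` file."""
    meta = json.dumps(asdict(config))
    np.savez(path, __config__=np.array(meta), **weights)


def load_checkpoint(path: str | Path) -> tuple[Weights, ModelConfig]:
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig(**json.loads(str(data["__config__"])))
        weights = {k: data[k] for k in data.files if k != "__config__"}
    expected = weight_shapes(config)
    if set(weights) != set(expected):
        raise ValueError("checkpoint tensors do not match the embedded config")
    for k, shape in expected.items():
        if weights[k].shape != shape:
            raise ValueError(f"checkpoint tensor {k} has shape {weights[k].shape}, "
                             f"expected {shape}")
    return weights, config
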