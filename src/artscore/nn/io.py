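"""HDF5 model serialization.

A model file holds one JSON attribute ``config`` (enough to rebuild the
architecture) and one dataset per named parameter, plus batch-norm
running statistics.  Round-tripping reproduces bitwise-identical
predictions.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .layers import BatchNorm2d, Module


def save_model(path: str | Path, model: Module, config: dict) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(config)
        g = f.create_group("params")
        for name, p in model.named_parameters():
            g.create_dataset(name, data=p.data)
        rb = f.create_group("running")
        for i, m in enumerate(model.modules()):
            if isinstance(m, BatchNorm2d):
                rb.create_dataset(f"{i}.mean", data=m.running_mean)
                rb.create_dataset(f"{i}.var", data=m.running_var)


def read_config(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        return json.loads(f.attrs["config"])


def load_weights(path: str | Path, model: Module) -> Module:
    """Load parameters into a freshly built model of the same config."""
    with h5py.File(path, "r") as f:
        g = f["params"]
        for name, p in model.named_parameters():
            data = np.asarray(g[name])
            if data.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: file {data.shape}, "
                    f"model {p.data.shape}"
                )
            p.data = data
        rb = f["running"]
        for i, m in enumerate(model.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(rb[f"{i}.mean"])
                m.running_var = np.asarray(rb[f"{i}.var"])
    return model
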