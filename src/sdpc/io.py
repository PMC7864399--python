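"""Serialization: networks and states to HDF5, run configs from YAML/JSON.

Checkpoints store every layer's atoms plus the layer specs and seed as
attributes, so a saved network round-trips exactly. Config files mirror
the model's parameter table: kernel sizes, strides, sparsity penalties,
the fixed-point threshold, epochs, learning rates and momentum. Unknown
keys are rejected before any compute.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .learning import TrainConfig
from .network import (ActivityMap, Dictionary, InferenceConfig, LayerSpec,
                      NetworkState, SDPCNetwork)

__all__ = ["save_network", "load_network", "save_state", "load_state",
           "load_run_config", "RunConfig", "ConfigError"]


def save_network(path: str | Path, network: SDPCNetwork, seed: int | None = None,
                 extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_layers"] = network.n_layers
        if seed is not None:
            f.attrs["seed"] = seed
        for key, val in (extra_attrs or {}).items():
            f.attrs[key] = val
        for i, (spec, d) in enumerate(zip(network.specs, network.dictionaries)):
            g = f.create_group(f"layer{i}")
            g.create_dataset("atoms", data=d.atoms)
            g.attrs["kernel_size"] = spec.kernel_size
            g.attrs["stride"] = spec.stride
            g.attrs["lambda_sparsity"] = spec.lambda_sparsity


def load_network(path: str | Path) -> SDPCNetwork:
    with h5py.File(path, "r") as f:
        specs, dicts = [], []
        for i in range(int(f.attrs["n_layers"])):
            g = f[f"layer{i}"]
            atoms = np.asarray(g["atoms"])
            specs.append(LayerSpec(
                n_features=atoms.shape[0], n_channels=atoms.shape[1],
                kernel_size=tuple(int(k) for k in g.attrs["kernel_size"]),
                stride=int(g.attrs["stride"]),
                lambda_sparsity=float(g.attrs["lambda_sparsity"])))
            dicts.append(Dictionary(atoms, layer_index=i))
    return SDPCNetwork(specs, dicts)


def save_state(path: str | Path, state: NetworkState,
               config: InferenceConfig | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_iterations"] = state.n_iterations
        f.attrs["converged"] = state.converged
        f.attrs["losses"] = state.losses
        if config is not None:
            f.attrs["feedback_strength"] = config.feedback_strength
            f.attrs["fixed_point_threshold"] = config.fixed_point_threshold
            f.attrs["rng_seed"] = config.rng_seed
        for i, (act, res) in enumerate(zip(state.activities, state.residuals)):
            g = f.create_group(f"layer{i}")
            g.create_dataset("activity", data=act.values)
            g.create_dataset("residual", data=res)


def load_state(path: str | Path) -> NetworkState:
    with h5py.File(path, "r") as f:
        n = sum(1 for k in f.keys() if k.startswith("layer"))
        activities = [ActivityMap(np.asarray(f[f"layer{i}"]["activity"]), i)
                      for i in range(n)]
        residuals = [np.asarray(f[f"layer{i}"]["residual"]) for i in range(n)]
        return NetworkState(
            activities=activities, residuals=residuals,
            losses=list(f.attrs["losses"]),
            n_iterations=int(f.attrs["n_iterations"]),
            converged=list(bool(c) for c in f.attrs["converged"]))


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

class ConfigError(ValueError):
    """A run config is malformed; the message names the offending keys."""


_LAYER_KEYS = {"n_features", "n_channels", "kernel_size", "stride", "lambda_sparsity"}
_TRAIN_KEYS = {"epochs", "learning_rates", "momentum", "batch_size", "rng_seed"}
_INFER_KEYS = {"feedback_strength", "fixed_point_threshold", "max_iterations",
               "acceleration", "step_size_mode"}
_TOP_KEYS = {"layers", "training", "inference", "seed"}


class RunConfig:
    """Validated parameter blocks for a reproducible run."""

    def __init__(self, layers: list[LayerSpec], training: TrainConfig,
                 inference: InferenceConfig, seed: int = 0):
        self.layers = layers
        self.training = training
        self.inference = inference
        self.seed = seed

    def build_network(self, rng_seed: int | None = None) -> SDPCNetwork:
        return SDPCNetwork(self.layers, rng_seed=self.seed if rng_seed is None else rng_seed)


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _require(block: dict, keys: set, where: str) -> None:
    missing = keys - set(block)
    if missing:
        raise ConfigError(f"missing key(s) in {where}: {sorted(missing)}")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML or JSON run config."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "config root")
    _require(data, {"layers"}, "config root")
    layers = []
    for i, block in enumerate(data["layers"]):
        _reject_unknown(block, _LAYER_KEYS, f"layers[{i}]")
        _require(block, {"n_features", "kernel_size", "lambda_sparsity"}, f"layers[{i}]")
        ks = block["kernel_size"]
        if isinstance(ks, int):
            ks = (ks, ks)
        layers.append(LayerSpec(
            n_features=int(block["n_features"]),
            n_channels=int(block.get("n_channels",
                                     layers[-1].n_features if layers else 1)),
            kernel_size=tuple(int(k) for k in ks),
            stride=int(block.get("stride", 1)),
            lambda_sparsity=float(block["lambda_sparsity"])))
    tr = dict(data.get("training", {}))
    _reject_unknown(tr, _TRAIN_KEYS, "training")
    if "learning_rates" in tr:
        tr["learning_rates"] = tuple(float(v) for v in tr["learning_rates"])
    training = TrainConfig(**tr)
    inf = dict(data.get("inference", {}))
    _reject_unknown(inf, _INFER_KEYS, "inference")
    inference = InferenceConfig(**inf)
    return RunConfig(layers, training, inference, seed=int(data.get("seed", 0)))
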