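"""Model checkpoints: config + weights in a single NPZ archive.

Each fitted Results object saves its parameter arrays plus a JSON header
(format version, config, bookkeeping) and reloads to an object that scores
identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from ._autograd import Tensor
from ._nn import Dense

FORMAT_VERSION = 1


def _save(path, kind: str, config, arrays: dict[str, np.ndarray],
          extra: dict | None = None) -> None:
    header = {"format_version": FORMAT_VERSION, "kind": kind,
              "config": asdict(config), "extra": extra or {}}
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def _load(path, kind: str) -> tuple[dict, dict[str, np.ndarray]]:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        if header["kind"] != kind:
            raise ValueError(f"checkpoint is a {header['kind']!r} model, "
                             f"expected {kind!r}")
        arrays = {k: z[k] for k in z.files if k != "__header__"}
    return header, arrays


def save_atat(results, path) -> None:
    _save(path, "atat", results.config,
          {k: v.data for k, v in results.params.items()},
          {"train_history": results.train_history})


def load_atat(path):
    from .atat import ATATConfig, ATATResults

    header, arrays = _load(path, "atat")
    params = {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}
    return ATATResults(ATATConfig(**header["config"]), params,
                       header["extra"]["train_history"])


def save_encoder(results, path) -> None:
    _save(path, "global_encoder", results.config,
          {k: v.data for k, v in results.params.items()},
          {"train_history": results.train_history})


def load_encoder(path):
    from .features import GlobalEncoderConfig, GlobalEncoderResults

    header, arrays = _load(path, "global_encoder")
    params = {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}
    return GlobalEncoderResults(GlobalEncoderConfig(**header["config"]),
                                params, header["extra"]["train_history"])


def save_hds(results, path) -> None:
    arrays = {"mean": results.mean, "sd": results.sd}
    for i, layer in enumerate(results.layers):
        arrays[f"W{i}"] = layer.W.data
        arrays[f"b{i}"] = layer.b.data
    _save(path, "hds", results.config, arrays,
          {"feature_cols": results.feature_cols,
           "train_history": results.train_history})


def load_hds(path):
    from .hds import HDSConfig, HDSResults

    header, arrays = _load(path, "hds")
    cfg = header["config"]
    cfg["hidden"] = tuple(cfg["hidden"])
    n_layers = sum(1 for k in arrays if k.startswith("W"))
    layers = []
    rng = np.random.default_rng(0)  # shapes overwritten below
    for i in range(n_layers):
        layer = Dense(rng, *arrays[f"W{i}"].shape)
        layer.W = Tensor(arrays[f"W{i}"], requires_grad=True)
        layer.b = Tensor(arrays[f"b{i}"], requires_grad=True)
        layers.append(layer)
    return HDSResults(HDSConfig(**cfg), header["extra"]["feature_cols"],
                      arrays["mean"], arrays["sd"], layers,
                      header["extra"]["train_history"])
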