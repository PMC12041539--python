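"""Single-file versioned checkpoints (.npz with a JSON metadata entry).

Round trips are bit-exact: weights are stored as float64 arrays under their
hierarchical parameter names. The metadata records the format version, the
training seed and a config snapshot; a version mismatch or a corrupt file
raises ``ValueError``.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass

import numpy as np

from .nn import Module

FORMAT_VERSION = 1

__all__ = [
    "Checkpoint",
    "write_checkpoint",
    "read_checkpoint",
    "save_pretrainer",
    "load_pretrainer",
    "save_classifier",
    "load_classifier",
]


@dataclass
class Checkpoint:
    weights: dict[str, np.ndarray]
    config: dict
    seed: int | None
    version: int


def write_checkpoint(model: Module, path, config: dict | None = None,
                     seed: int | None = None) -> None:
    meta = {
        "version": FORMAT_VERSION,
        "seed": seed,
        "config": config or {},
    }
    arrays = {f"w:{name}": arr for name, arr in model.state_dict().items()}
    arrays["__meta__"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def read_checkpoint(path) -> Checkpoint:
    try:
        with np.load(path, allow_pickle=False) as data:
            if "__meta__" not in data:
                raise ValueError(f"{path}: not a specgin checkpoint (no metadata)")
            meta = json.loads(str(data["__meta__"]))
            weights = {
                key[2:]: data[key] for key in data.files if key.startswith("w:")
            }
    except (zipfile.BadZipFile, OSError, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupt or unreadable checkpoint: {path}") from exc
    if meta.get("version") != FORMAT_VERSION:
        raise ValueError(
            f"checkpoint version {meta.get('version')} is not supported "
            f"(expected {FORMAT_VERSION})"
        )
    return Checkpoint(
        weights=weights, config=meta.get("config", {}),
        seed=meta.get("seed"), version=meta["version"],
    )


def _clean_params(params: dict) -> dict:
    return {
        k: v for k, v in params.items()
        if isinstance(v, (int, float, str, bool, type(None)))
    }


def save_pretrainer(estimator, path) -> None:
    """Persist a fitted SpectralGraphAutoencoder."""
    config = _clean_params(estimator.get_params())
    config["__kind__"] = "pretrainer"
    config["loss_trace"] = getattr(estimator, "loss_trace_", [])
    write_checkpoint(estimator.encoder_, path, config=config,
                     seed=estimator.random_state)


def load_pretrainer(path):
    from .pretrain import SpectralGraphAutoencoder
    from .spectral import ChebEncoder

    ckpt = read_checkpoint(path)
    config = dict(ckpt.config)
    if config.pop("__kind__", None) != "pretrainer":
        raise ValueError(f"{path} is not a pre-trainer checkpoint")
    trace = config.pop("loss_trace", [])
    est = SpectralGraphAutoencoder(**config)
    est.encoder_ = ChebEncoder(np.random.default_rng(0), init="scaled")
    est.encoder_.load_state_dict(ckpt.weights)
    est.encoder_.eval()
    est.loss_trace_ = trace
    est.n_skipped_ = 0
    return est


def save_classifier(estimator, path) -> None:
    """Persist a fitted dual-branch estimator (classifier or regressor)."""
    config = _clean_params(estimator.get_params())
    config["__kind__"] = "dual_branch"
    config["task_mode"] = estimator._task_mode
    config["n_tasks_fitted"] = estimator.n_tasks_
    write_checkpoint(estimator.model_, path, config=config,
                     seed=estimator.random_state)


def load_classifier(path):
    from .model import (
        DualBranchGraphClassifier,
        DualBranchGraphRegressor,
        DualBranchModel,
    )

    ckpt = read_checkpoint(path)
    config = dict(ckpt.config)
    if config.pop("__kind__", None) != "dual_branch":
        raise ValueError(f"{path} is not a dual-branch checkpoint")
    task_mode = config.pop("task_mode")
    n_tasks = config.pop("n_tasks_fitted")
    cls = (
        DualBranchGraphClassifier if task_mode == "classification"
        else DualBranchGraphRegressor
    )
    est = cls(**config)
    est.model_ = DualBranchModel(
        np.random.default_rng(0), n_tasks=n_tasks,
        epsilon_self=config.get("epsilon_self", 0.0),
        learn_epsilon=config.get("learn_epsilon", False),
        task_mode=task_mode,
    )
    est.model_.load_state_dict(ckpt.weights)
    est.model_.eval()
    est.n_tasks_ = n_tasks
    return est
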