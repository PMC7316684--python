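"""VGG-style convolutional pseudo-landmark regressor.

The network maps a normalized 92x48 patch to twelve values — the six
pseudo-landmark coordinates in normalized patch units.  Architecture grammar:
``blocks`` convolutional blocks of ``convs_per_block`` 3x3 ReLU convolutions,
each block ending in a 2x2 pooling layer; channels double per block starting
from ``base_channels``; fully connected ReLU layers (with optional dropout)
feed a linear 12-output head.  Training minimizes the mean squared error with
Adam (or SGD+Nesterov) under a staircase learning-rate schedule: the initial
rate's exponent decreases by one every ``lr_drop_every`` epochs.  The best
checkpoint is selected by validation loss.

A direct-regression ("end-to-end") variant with 5 pose outputs uses the same
grammar via ``out_dim=5``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nnet import Adam, Conv2D, Dense, Dropout, Flatten, Pool2D, ReLU, Sequential, SGDNesterov, mse_loss

__all__ = [
    "ArchConfig",
    "TrainConfig",
    "TrainedModel",
    "build_regressor",
    "train_regressor",
    "predict",
    "save_model",
    "load_model",
    "learning_rate",
]

PATCH_SHAPE = (48, 92)  # rows, cols of the input patch


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters (the VGG-fashion design space)."""

    blocks: int = 3
    convs_per_block: int = 2
    base_channels: int = 32
    fc_layers: int = 2
    fc_hidden: int = 256
    pooling: str = "average"
    dropout_rate: float = 0.5
    out_dim: int = 12

    def __post_init__(self) -> None:
        if self.blocks < 1 or self.convs_per_block < 1 or self.fc_layers < 1:
            raise ValueError("blocks, convs_per_block and fc_layers must be >= 1")
        if self.pooling not in ("max", "average"):
            raise ValueError("pooling must be 'max' or 'average'")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        h, w = PATCH_SHAPE
        if (h >> self.blocks) == 0 or (w >> self.blocks) == 0:
            raise ValueError(
                f"{self.blocks} pooling stages collapse the {w}x{h} patch"
            )

    @property
    def n_weight_layers(self) -> int:
        return self.blocks * self.convs_per_block + self.fc_layers

    @property
    def block_channels(self) -> list[int]:
        return [self.base_channels * 2**b for b in range(self.blocks)]

    @classmethod
    def reference(cls) -> "ArchConfig":
        """The full-scale 13-weight-layer configuration (VGG-like reading:
        five 2-conv blocks plus three fully connected layers)."""
        return cls(blocks=5, convs_per_block=2, fc_layers=3)

    @classmethod
    def desk(cls, **overrides) -> "ArchConfig":
        """Small CPU-trainable configuration with the same design grammar."""
        defaults = dict(blocks=3, convs_per_block=1, fc_layers=2,
                        dropout_rate=0.0)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (staircase schedule, MSE, best-val checkpoint)."""

    lr_initial: float = 5e-3
    lr_drop_every: int = 35
    max_epochs: int = 80
    batch_size: int = 64
    loss: str = "mse"
    optimizer: str = "adam"
    seed: int = 0
    variations_per_image: int = 20

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "sgd_nesterov"):
            raise ValueError("optimizer must be 'adam' or 'sgd_nesterov'")
        if self.loss != "mse":
            raise ValueError("only the mse loss is supported")


def learning_rate(cfg: TrainConfig, epoch: int) -> float:
    """lr(epoch) = lr_initial * 10**(-floor(epoch / lr_drop_every))."""
    return cfg.lr_initial * 10.0 ** (-(epoch // cfg.lr_drop_every))


@dataclass
class TrainedModel:
    """A network plus its configs and training history."""

    net: Sequential
    arch: ArchConfig
    train_cfg: TrainConfig | None = None
    history: list[dict] = field(default_factory=list)
    best_epoch: int | None = None


def build_regressor(arch: ArchConfig = ArchConfig(), rng_seed: int = 0) -> TrainedModel:
    """Instantiate an untrained network from an architecture config.

    Two builds with the same seed produce identical initial weights.
    """
    rng = np.random.default_rng(rng_seed)
    layers: list = []
    h, w = PATCH_SHAPE
    c_in = 1
    for c_out in arch.block_channels:
        for _ in range(arch.convs_per_block):
            layers.append(Conv2D(c_in, c_out, rng))
            layers.append(ReLU())
            c_in = c_out
        layers.append(Pool2D(arch.pooling))
        h, w = h // 2, w // 2
        if h == 0 or w == 0:
            raise ValueError("patch pooled away; reduce blocks")
    layers.append(Flatten())
    n_in = h * w * c_in
    for _ in range(arch.fc_layers - 1):
        layers.append(Dense(n_in, arch.fc_hidden, rng))
        layers.append(ReLU())
        if arch.dropout_rate > 0:
            layers.append(Dropout(arch.dropout_rate))
        n_in = arch.fc_hidden
    head = Dense(n_in, arch.out_dim, rng)
    # small-scale head init: predictions start near the output bias (set to
    # the target mean by the trainer), avoiding a destabilizing first epoch
    head.params[0] *= 0.1
    layers.append(head)
    first_conv = next(l for l in layers if isinstance(l, Conv2D))
    first_conv.is_input_layer = True  # nothing below needs its input gradient
    return TrainedModel(net=Sequential(layers), arch=arch)


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


def train_regressor(
    model: TrainedModel,
    dataset: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    cfg: TrainConfig,
    epochs: int | None = None,
) -> TrainedModel:
    """Train in place; returns the model restored to its best-val checkpoint.

    ``dataset`` is ``(X_train, Y_train, X_val, Y_val)`` with X of shape
    (n, 48, 92) or (n, 48, 92, 1); the split must be disjoint by source
    image (the caller's responsibility — see ``pipeline.build_patch_dataset``).
    The output head's bias is initialized to the training-target mean, which
    centers the regression before the first step.
    """
    x_tr, y_tr, x_val, y_val = (np.asarray(a, dtype=np.float32) for a in dataset)
    if x_tr.ndim == 3:
        x_tr = x_tr[..., None]
    if x_val.ndim == 3:
        x_val = x_val[..., None]
    if len(x_tr) == 0:
        raise ValueError("empty training set")
    n_epochs = cfg.max_epochs if epochs is None else epochs

    head = [l for l in model.net.layers if l.params][-1]
    head.params[1][...] = y_tr.mean(axis=0)

    opt_cls = Adam if cfg.optimizer == "adam" else SGDNesterov
    opt = opt_cls(model.net.params, lr=learning_rate(cfg, 0))
    rng = np.random.default_rng(cfg.seed)

    best_val = math.inf
    best_weights = model.net.get_weights()
    model.history = []
    for epoch in range(n_epochs):
        opt.lr = learning_rate(cfg, epoch)
        order = rng.permutation(len(x_tr))
        running, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = model.net.forward(x_tr[idx], training=True, rng=rng)
            loss, dloss = mse_loss(pred, y_tr[idx])
            if not math.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}"
                )
            model.net.backward(dloss)
            opt.step(model.net.grads)
            running += loss
            n_batches += 1
        val_loss = evaluate_loss(model, x_val, y_val) if len(x_val) else math.nan
        model.history.append(
            {"epoch": epoch, "lr": opt.lr,
             "train_loss": running / max(n_batches, 1), "val_loss": val_loss}
        )
        if len(x_val) and val_loss < best_val:
            best_val = val_loss
            best_weights = model.net.get_weights()
            model.best_epoch = epoch
    if len(x_val):
        model.net.set_weights(best_weights)
    else:
        model.best_epoch = n_epochs - 1
    model.train_cfg = cfg
    return model


def evaluate_loss(model: TrainedModel, x: np.ndarray, y: np.ndarray,
                  batch_size: int = 256) -> float:
    pred = predict(model, x, batch_size=batch_size)
    return float(np.mean((pred - np.asarray(y, dtype=np.float32)) ** 2))


def predict(model: TrainedModel, patches: np.ndarray,
            batch_size: int = 256) -> np.ndarray:
    """Batched deterministic inference (dropout disabled)."""
    x = np.asarray(patches, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[..., None]
    if x.shape[1:3] != PATCH_SHAPE:
        raise ValueError(f"expected {PATCH_SHAPE} patches, got {x.shape[1:3]}")
    outs = [model.net.forward(x[s : s + batch_size], training=False)
            for s in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Weights as .npz, JSON sidecar with configs, history also as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"),
             **{f"w{i}": w for i, w in enumerate(model.net.get_weights())})
    if model.history:
        import pandas as pd

        pd.DataFrame(model.history).to_csv(
            path.with_name(path.stem + "_history.csv"), index=False)
    sidecar = {
        "schema_version": 1,
        "arch": dataclasses.asdict(model.arch),
        "train_cfg": dataclasses.asdict(model.train_cfg) if model.train_cfg else None,
        "history": model.history,
        "best_epoch": model.best_epoch,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = build_regressor(ArchConfig(**sidecar["arch"]))
    with np.load(path.with_suffix(".npz")) as data:
        model.net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    if sidecar["train_cfg"]:
        model.train_cfg = TrainConfig(**sidecar["train_cfg"])
    model.history = sidecar["history"]
    model.best_epoch = sidecar["best_epoch"]
    return model
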