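"""Declarative sub-model architectures and their training procedure.

Eight presets are shipped: four convolutional stacks (CNN1-CNN4) and four
dense stacks (DNN1-DNN4).  All end in a two-unit sigmoid head trained with
binary cross-entropy against two-column one-hot labels; prediction is the
argmax of the two units with ties broken toward class 0 (unit 1 = true
site).  Optimization is Adam under an inverse-time-decay learning-rate
schedule, batches of 32, at most 30 epochs, with early stopping on
validation loss and best-weight restoration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import OneHotBatch
from .errors import ArchitectureError, DegenerateDataError, InputShapeError
from . import nn

# Hyper-parameter search-space ranges the presets were originally selected
# from (documented constants; no search is run here).
CNN_SEARCH_SPACE = {
    "filters": (8, 400, 8),
    "kernel_size": (1, 9, 2),
    "dropout": (0.05, 0.30, 0.05),
    "max_pool_size": (1, 9, 2),
}
DNN_SEARCH_SPACE = {
    "units": (32, 704, 32),
    "kernel_regularizers": (0.0025, 0.025, 0.036),
    "dropout": (0.05, 0.50, 0.50),
}

_KINDS = ("conv1d", "maxpool1d", "flatten", "dropout", "dense")


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ArchitectureError(
                f"unknown layer kind {self.kind!r}; expected one of {_KINDS}"
            )
        p = self.params
        if self.kind == "conv1d" and (p["filters"] < 1 or p["kernel_size"] < 1):
            raise ArchitectureError("conv1d filters/kernel_size must be positive")
        if self.kind == "maxpool1d" and p["pool_size"] < 1:
            raise ArchitectureError("maxpool1d pool_size must be positive")
        if self.kind == "dropout" and not 0.0 < p["rate"] < 1.0:
            raise ArchitectureError("dropout rate must lie in (0, 1)")
        if self.kind == "dense" and p["units"] < 1:
            raise ArchitectureError("dense units must be positive")


def conv(filters: int, kernel_size: int) -> LayerSpec:
    return LayerSpec("conv1d", {"filters": filters, "kernel_size": kernel_size})


def maxpool(pool_size: int) -> LayerSpec:
    return LayerSpec("maxpool1d", {"pool_size": pool_size})


def flatten() -> LayerSpec:
    return LayerSpec("flatten")


def dropout(rate: float) -> LayerSpec:
    return LayerSpec("dropout", {"rate": rate})


def dense(units, activation="relu", l2=0.0, initializer="glorot_uniform") -> LayerSpec:
    return LayerSpec(
        "dense",
        {"units": units, "activation": activation, "l2": l2, "initializer": initializer},
    )


@dataclass(frozen=True)
class SubModelSpec:
    name: str
    layers: tuple[LayerSpec, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ArchitectureError("a sub-model needs at least one layer")
        last = self.layers[-1]
        if not (
            last.kind == "dense"
            and last.params["units"] == 2
            and last.params["activation"] == "sigmoid"
        ):
            raise ArchitectureError(
                "the final layer must be dense(2, sigmoid); "
                f"got {last.kind} {last.params}"
            )
        first = self.layers[0]
        if self.name.startswith("CNN") and first.kind != "conv1d":
            raise ArchitectureError(f"{self.name} must start with a conv1d layer")
        if self.name.startswith("DNN") and first.kind != "flatten":
            raise ArchitectureError(f"{self.name} must start with a flatten layer")

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "layers": [asdict(layer) for layer in self.layers]},
            indent=2,
        )


def _rn(units: int) -> LayerSpec:
    return dense(units, initializer="random_normal")


_PRESETS: dict[str, tuple[LayerSpec, ...]] = {
    "CNN1": (conv(72, 5), conv(144, 7), conv(168, 7), flatten(), dropout(0.20),
             dense(2, "sigmoid")),
    "CNN2": (conv(136, 3), conv(72, 4), maxpool(7), conv(272, 7), maxpool(3),
             flatten(), dropout(0.35), dense(2, "sigmoid")),
    "CNN3": (conv(208, 9), maxpool(6), conv(120, 5), maxpool(3), flatten(),
             dropout(0.20), dense(2, "sigmoid")),
    "CNN4": (conv(250, 5), conv(250, 5), conv(250, 5), maxpool(3), flatten(),
             dropout(0.20), dense(2, "sigmoid")),
    "DNN1": (flatten(), dense(704), dense(224), dropout(0.1), dense(512),
             dropout(0.15), dense(2, "sigmoid")),
    "DNN2": (flatten(), dense(704), dense(224), dense(128), dropout(0.15),
             dense(2, "sigmoid")),
    "DNN3": (flatten(), dense(256), dense(352), dense(32), dense(352),
             dropout(0.15), dense(2, "sigmoid")),
    # DNN4 uses the random-normal kernel initializer throughout.
    "DNN4": (flatten(), _rn(250), _rn(250), _rn(250), dropout(0.25),
             dense(2, "sigmoid", initializer="random_normal")),
}

SUBMODEL_NAMES = tuple(_PRESETS)


def preset_spec(name: str) -> SubModelSpec:
    """Return the published layer stack for one of CNN1-4 / DNN1-4."""
    try:
        layers = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(_PRESETS)}"
        ) from None
    return SubModelSpec(name=name, layers=layers)


@dataclass(frozen=True)
class LRSchedule:
    """Inverse time decay: rate(step) = initial / (1 + decay_rate * step / decay_steps)."""

    initial_rate: float
    decay_steps: int
    decay_rate: float

    def __post_init__(self) -> None:
        if self.initial_rate <= 0 or self.decay_steps <= 0 or self.decay_rate <= 0:
            raise ArchitectureError("all schedule parameters must be positive")

    def __call__(self, step: int) -> float:
        return inverse_time_decay(self, step)


#: Published schedules: convolutional and dense sub-models decay differently.
CNN_SCHEDULE = LRSchedule(initial_rate=0.001, decay_steps=140, decay_rate=0.1)
DNN_SCHEDULE = LRSchedule(initial_rate=0.002, decay_steps=80, decay_rate=1.4)


def inverse_time_decay(schedule: LRSchedule, step: int) -> float:
    """Closed-form learning rate at an optimizer update step (step 0 = first)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return schedule.initial_rate / (
        1.0 + schedule.decay_rate * step / schedule.decay_steps
    )


def default_schedule(name: str) -> LRSchedule:
    return CNN_SCHEDULE if name.startswith("CNN") else DNN_SCHEDULE


@dataclass
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 30
    schedule: LRSchedule = CNN_SCHEDULE
    early_stop_patience: int = 3
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ArchitectureError("batch_size must be >= 1")
        if not 0.0 < self.validation_fraction < 0.5:
            raise ArchitectureError("validation_fraction must lie in (0, 0.5)")


_LAYER_BUILDERS = {
    "conv1d": lambda p: nn.Conv1D(p["filters"], p["kernel_size"]),
    "maxpool1d": lambda p: nn.MaxPooling1D(p["pool_size"]),
    "flatten": lambda p: nn.Flatten(),
    "dropout": lambda p: nn.Dropout(p["rate"]),
    "dense": lambda p: nn.Dense(
        p["units"],
        activation=p.get("activation", "relu"),
        l2=p.get("l2", 0.0),
        initializer=p.get("initializer", "glorot_uniform"),
    ),
}


def build_submodel(spec: SubModelSpec, window_length: int, seed: int = 0) -> nn.Network:
    """Instantiate a trainable network for N x L x 4 one-hot input.

    Raises an architecture error when the pooling stack collapses the
    sequence length to zero for the given window length.
    """
    layers = [_LAYER_BUILDERS[ls.kind](ls.params) for ls in spec.layers]
    try:
        net = nn.Network(layers, input_shape=(window_length, 4), seed=seed)
    except ArchitectureError as exc:
        raise ArchitectureError(
            f"{spec.name} is incompatible with window length {window_length}: {exc}"
        ) from exc
    net.name = spec.name
    return net


def _one_hot_labels(labels: np.ndarray) -> np.ndarray:
    y = np.zeros((len(labels), 2), dtype=np.float32)
    y[np.arange(len(labels)), labels.astype(int)] = 1.0
    return y


def _stratified_split(labels, fraction, rng):
    """Indices (train, val) with per-class proportional allocation."""
    val_idx = []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        cls_idx = rng.permutation(cls_idx)
        n_val = max(1, int(round(fraction * len(cls_idx))))
        val_idx.append(cls_idx[:n_val])
    val_idx = np.concatenate(val_idx)
    mask = np.ones(len(labels), dtype=bool)
    mask[val_idx] = False
    return np.flatnonzero(mask), np.sort(val_idx)


def train_submodel(
    model: nn.Network,
    batch: OneHotBatch,
    labels: np.ndarray,
    config: TrainConfig,
) -> tuple[nn.Network, dict[str, list[float]]]:
    """Train in place with Adam + early stopping; returns (model, history).

    A stratified ``validation_fraction`` of the data is held out to monitor
    validation loss; training stops once it fails to improve for
    ``early_stop_patience`` consecutive epochs and the best weights are
    restored.  ``max_epochs == 0`` returns the untouched model with an
    empty history.
    """
    x = batch.tensor
    labels = np.asarray(labels)
    if len(labels) != len(x):
        raise InputShapeError(
            f"{len(labels)} labels for {len(x)} records"
        )
    history: dict[str, list[float]] = {"loss": [], "val_loss": []}
    if config.max_epochs == 0:
        return model, history
    if np.unique(labels).size < 2:
        raise DegenerateDataError("training labels contain a single class")

    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _stratified_split(labels, config.validation_fraction, rng)
    x_train, y_train = x[train_idx], _one_hot_labels(labels[train_idx])
    x_val, y_val = x[val_idx], _one_hot_labels(labels[val_idx])

    optimizer = nn.Adam(schedule=config.schedule)
    best_val = np.inf
    best_weights = model.get_weights()
    stale = 0
    n_train = len(x_train)
    for _ in range(config.max_epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            out = model.forward(xb, training=True, rng=rng)
            epoch_loss += nn.bce_loss(out, yb) * len(sel)
            model.backward(nn.bce_grad(out, yb))
            optimizer.update(model.params, model.grads)
        history["loss"].append(epoch_loss / n_train)

        val_out = model.predict_proba(x_val)
        val_loss = nn.bce_loss(val_out, y_val) + model.l2_penalty()
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = model.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break
    model.set_weights(best_weights)
    return model, history


def save_model(model: nn.Network, spec: SubModelSpec, path) -> None:
    """Serialize weights (npz) and architecture (json) under one directory."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "spec.json").write_text(spec.to_json())
    (path / "meta.json").write_text(
        json.dumps({"window_length": model.input_shape[0]})
    )
    np.savez(path / "weights.npz", *model.get_weights())


def load_model(path) -> tuple[nn.Network, SubModelSpec]:
    """Inverse of :func:`save_model`."""
    from pathlib import Path

    path = Path(path)
    doc = json.loads((path / "spec.json").read_text())
    spec = SubModelSpec(
        name=doc["name"],
        layers=tuple(LayerSpec(d["kind"], d["params"]) for d in doc["layers"]),
    )
    meta = json.loads((path / "meta.json").read_text())
    model = build_submodel(spec, meta["window_length"], seed=0)
    with np.load(path / "weights.npz") as data:
        model.set_weights([data[k] for k in data.files])
    return model, spec


def predict_binary(model: nn.Network, batch: OneHotBatch) -> np.ndarray:
    """Hard 0/1 predictions: argmax of the two output units, ties toward 0."""
    if batch.window_length != model.input_shape[0]:
        raise InputShapeError(
            f"batch window length {batch.window_length} != model input "
            f"length {model.input_shape[0]}"
        )
    proba = model.predict_proba(batch.tensor)
    return (proba[:, 1] > proba[:, 0]).astype(np.int64)
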