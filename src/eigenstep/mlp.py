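"""One-hidden-layer dense softmax classifier trained with Adam.

Architecture: input -> fully connected (ReLU, inverted dropout) -> fully
connected -> softmax, trained on categorical cross-entropy for a fixed
number of epochs with no early stopping.  The operating defaults are a
512-node hidden layer, dropout 0.5, batch size 32, 100 epochs, learning
rate 0.001 and a stratified validation split of 0.25.

At this scale (tens of thousands of parameters) the network is implemented
directly over numpy: a single seeded generator drives initialization,
shuffling, and dropout masks, so a fixed seed fixes the trained weights
bit-for-bit on one platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .datatypes import ValidationError
from .eigen import FeatureMatrix


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of the classifier.

    ``input_dim`` is normally sized by the upstream feature selection; when
    left ``None`` it is inferred from the training matrix.  Adam's moment
    parameters follow the conventional 0.9/0.999 with epsilon 1e-8.
    """

    input_dim: int | None = None
    hidden_dim: int = 512
    output_dim: int = 4
    dropout_rate: float = 0.5
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    validation_split: float = 0.25
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.input_dim is not None and self.input_dim < 1:
            raise ValidationError("input_dim must be >= 1")
        if self.hidden_dim < 1 or self.output_dim < 1:
            raise ValidationError("layer dims must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if not 0 < self.validation_split < 1:
            raise ValidationError("validation_split must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")


@dataclass
class MLPModel:
    w1: np.ndarray  # (input_dim, hidden_dim)
    b1: np.ndarray
    w2: np.ndarray  # (hidden_dim, output_dim)
    b2: np.ndarray
    config: MLPConfig

    @property
    def input_dim(self) -> int:
        return self.w1.shape[0]

    def n_parameters(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def count_parameters(input_dim: int, hidden_dim: int, output_dim: int) -> int:
    """Trainable-parameter count of the two-layer architecture.

    input_dim*hidden_dim + hidden_dim (first layer plus biases) plus
    hidden_dim*output_dim + output_dim (second layer plus biases); e.g.
    (100, 512, 4) -> 51,712 + 2,052 = 53,764.
    """
    if input_dim < 1 or hidden_dim < 1 or output_dim < 1:
        raise ValidationError("all dimensions must be >= 1")
    return input_dim * hidden_dim + hidden_dim + hidden_dim * output_dim + output_dim


def _softmax(z: np.ndarray) -> np.ndarray:
    shifted = z - z.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    return expz / expz.sum(axis=1, keepdims=True)


def _as_array(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.scores
    arr = np.asarray(features, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"features must be 2-D, got shape {arr.shape}")
    return arr


def _forward(model: MLPModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hidden = np.maximum(x @ model.w1 + model.b1, 0.0)
    return hidden, _softmax(hidden @ model.w2 + model.b2)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


def _stratified_split(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (train, val) with per-class proportions preserved."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        members = rng.permutation(members)
        n_val = int(np.floor(fraction * len(members)))
        val_idx.extend(members[:n_val])
        train_idx.extend(members[n_val:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def _init_model(config: MLPConfig, rng: np.random.Generator) -> MLPModel:
    """Scaled-uniform initialization sized by fan-in."""
    d, h, o = config.input_dim, config.hidden_dim, config.output_dim
    lim1 = np.sqrt(6.0 / d)
    lim2 = np.sqrt(6.0 / h)
    return MLPModel(
        w1=rng.uniform(-lim1, lim1, size=(d, h)),
        b1=np.zeros(h),
        w2=rng.uniform(-lim2, lim2, size=(h, o)),
        b2=np.zeros(o),
        config=config,
    )


def train(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    config: MLPConfig = MLPConfig(),
) -> tuple[MLPModel, TrainHistory]:
    """Train the classifier for a fixed number of epochs.

    A stratified ``validation_split`` fraction is held out for monitoring
    only (it never influences the weights — there is no early stopping).
    Inverted dropout scales the surviving hidden activations by
    1/(1 - rate) during training and is disabled at inference.
    """
    x = _as_array(features)
    y = np.asarray(labels, dtype=np.int64)
    if len(x) != len(y):
        raise ValidationError(f"{len(x)} rows but {len(y)} labels")
    if config.input_dim is None:
        config = replace(config, input_dim=x.shape[1])
    if x.shape[1] != config.input_dim:
        raise ValidationError(
            f"feature width {x.shape[1]} != configured input_dim {config.input_dim}"
        )
    if y.min() < 0 or y.max() >= config.output_dim:
        raise ValidationError(
            f"labels must lie in [0, {config.output_dim})"
        )

    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _stratified_split(y, config.validation_split, rng)
    classes_present = np.unique(y)
    missing = set(classes_present.tolist()) - set(np.unique(y[train_idx]).tolist())
    if missing:
        raise ValidationError(
            f"classes {sorted(missing)} absent from the training portion after the "
            f"{config.validation_split} split; use a smaller split or another seed"
        )
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    model = _init_model(config, rng)
    params = [model.w1, model.b1, model.w2, model.b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0
    keep = 1.0 - config.dropout_rate
    history = TrainHistory()

    for _ in range(config.epochs):
        order = rng.permutation(len(x_tr))
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = x_tr[batch], y_tr[batch]

            pre1 = xb @ model.w1 + model.b1
            hidden = np.maximum(pre1, 0.0)
            if config.dropout_rate > 0:
                mask = (rng.random(hidden.shape) < keep) / keep
                hidden_dropped = hidden * mask
            else:
                mask = None
                hidden_dropped = hidden
            probs = _softmax(hidden_dropped @ model.w2 + model.b2)

            # backprop of mean cross-entropy
            delta_out = probs.copy()
            delta_out[np.arange(len(yb)), yb] -= 1.0
            delta_out /= len(yb)
            grad_w2 = hidden_dropped.T @ delta_out
            grad_b2 = delta_out.sum(axis=0)
            delta_hidden = delta_out @ model.w2.T
            if mask is not None:
                delta_hidden = delta_hidden * mask
            delta_hidden[pre1 <= 0] = 0.0
            grad_w1 = xb.T @ delta_hidden
            grad_b1 = delta_hidden.sum(axis=0)

            t += 1
            grads = [grad_w1, grad_b1, grad_w2, grad_b2]
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = config.beta1 * m[i] + (1 - config.beta1) * g
                v[i] = config.beta2 * v[i] + (1 - config.beta2) * g * g
                m_hat = m[i] / (1 - config.beta1**t)
                v_hat = v[i] / (1 - config.beta2**t)
                p -= config.learning_rate * m_hat / (np.sqrt(v_hat) + config.epsilon)

        # epoch metrics in inference mode (dropout off)
        _, tr_probs = _forward(model, x_tr)
        history.train_loss.append(_cross_entropy(tr_probs, y_tr))
        history.train_accuracy.append(float(np.mean(tr_probs.argmax(axis=1) == y_tr)))
        if len(x_val):
            _, val_probs = _forward(model, x_val)
            history.val_loss.append(_cross_entropy(val_probs, y_val))
            history.val_accuracy.append(
                float(np.mean(val_probs.argmax(axis=1) == y_val))
            )
        else:
            history.val_loss.append(float("nan"))
            history.val_accuracy.append(float("nan"))

    return model, history


def predict(
    model: MLPModel, features: FeatureMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class indices and softmax probabilities, dropout disabled."""
    x = _as_array(features)
    if x.shape[1] != model.input_dim:
        raise ValidationError(
            f"feature width {x.shape[1]} != model input_dim {model.input_dim}"
        )
    _, probs = _forward(model, x)
    return probs.argmax(axis=1), probs


def save_mlp(model: MLPModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("w1", "b1", "w2", "b2"):
        np.save(directory / f"{name}.npy", getattr(model, name))
    cfg = {k: v for k, v in model.config.__dict__.items()}
    (directory / "config.json").write_text(json.dumps(cfg, indent=2))


def load_mlp(directory: str | Path) -> MLPModel:
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    arrays = {n: np.load(directory / f"{n}.npy") for n in ("w1", "b1", "w2", "b2")}
    return MLPModel(config=MLPConfig(**cfg), **arrays)
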