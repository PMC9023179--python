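"""MLP classification core: seeded NumPy feed-forward networks trained with
mini-batch Adam on softmax cross-entropy.

Accuracy is the fraction of records whose argmax score matches the one-hot
target (ties broken toward the lowest class index); loss is mean
cross-entropy. Dropout, when enabled, is inverted dropout applied after
each hidden activation during training only, so ``p=0`` is exactly a
dropout-free network.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda z, a: a * (1.0 - a),
    ),
}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Fully connected architecture: input -> L hidden layers of H units -> 4 outputs."""

    hidden_layers: int
    width: int
    dropout: float = 0.0
    input_dim: int = 24
    output_dim: int = 4
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.width < 1:
            raise ValueError("hidden_layers and width must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def name(self) -> str:
        return f"{self.hidden_layers}-{self.width}"

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return (self.input_dim, *([self.width] * self.hidden_layers), self.output_dim)

    def parameter_count(self) -> int:
        dims = self.layer_dims
        return sum(d_in * d_out + d_out for d_in, d_out in zip(dims[:-1], dims[1:]))


@dataclass(frozen=True)
class TrainConfig:
    """Adam optimizer settings: defaults lr 0.001, batch 100."""

    learning_rate: float = 1e-3
    batch_size: int = 100
    epochs: int = 200
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")


@dataclass
class MLPModel:
    """Weights/biases per layer plus the architecture and training history."""

    arch: ArchitectureSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    history: list[float] = field(default_factory=list)

    def parameter_count(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)


def build_mlp(arch: ArchitectureSpec, seed: int = 0) -> MLPModel:
    """Build a model with He (fan-in scaled) seeded initialization."""
    rng = np.random.default_rng(seed)
    dims = arch.layer_dims
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return MLPModel(arch, weights, biases)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(
    model: MLPModel,
    X: np.ndarray,
    rng: np.random.Generator | None = None,
):
    """Forward pass; with ``rng`` given, applies inverted dropout after each
    hidden activation. Returns (probabilities, cache for backprop)."""
    act, _ = _ACTIVATIONS[model.arch.activation]
    p = model.arch.dropout
    a = X
    cache = []
    n_hidden = model.arch.hidden_layers
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ w + b
        if i < n_hidden:
            h = act(z)
            mask = None
            if rng is not None and p > 0.0:
                mask = (rng.random(h.shape) >= p) / (1.0 - p)
                h = h * mask
            cache.append((a, z, h, mask))
            a = h
        else:
            probs = _softmax(z)
            cache.append((a, z, probs, None))
    return probs, cache


def predict_proba(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Class scores (nonnegative, rows sum to 1) without dropout."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.arch.input_dim:
        raise ValueError(
            f"inputs must have width {model.arch.input_dim}, got shape {X.shape}"
        )
    probs, _ = _forward(model, X)
    return probs


def predict_classes(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Argmax class in {1..4} per record; ties go to the lowest class index."""
    return predict_proba(model, X).argmax(axis=1) + 1


def evaluate(model: MLPModel, dataset) -> tuple[float, float]:
    """(accuracy, mean cross-entropy loss) on an encoded dataset."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    probs = predict_proba(model, dataset.X)
    pred = probs.argmax(axis=1)
    truth = dataset.Y.argmax(axis=1)
    accuracy = float((pred == truth).mean())
    loss = float(-np.mean(np.log(probs[np.arange(len(probs)), truth] + 1e-12)))
    return accuracy, loss


@dataclass
class TrialResult:
    """Accuracy/loss on the three datasets plus training wall-clock and seed."""

    test_accuracy: float
    test_loss: float
    train_accuracy: float
    train_loss: float
    validation_accuracy: float
    validation_loss: float
    runtime_s: float
    seed: int

    def accuracy(self, which: str) -> float:
        return getattr(self, f"{which}_accuracy")


def train(
    model: MLPModel,
    train_set,
    config: TrainConfig,
    test_set=None,
    validation_set=None,
) -> TrialResult:
    """Train in place with mini-batch Adam on cross-entropy.

    Shuffling and dropout masks are drawn from one generator seeded by
    ``config.seed``, consumed epoch by epoch, so training for E epochs is a
    prefix of training for 2E epochs with the same seed. The last partial
    mini-batch is used, not dropped. Per-epoch mean training loss is
    appended to ``model.history``.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    X, Y = train_set.X, train_set.Y.astype(float)
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    _, act_grad = _ACTIVATIONS[model.arch.activation]
    n_hidden = model.arch.hidden_layers

    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    step = 0
    t0 = time.perf_counter()

    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            probs, cache = _forward(model, xb, rng=rng)
            batch_loss = -np.mean(
                np.log(np.sum(probs * yb, axis=1) + 1e-12)
            )
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {_epoch}, batch start {start}"
                )
            epoch_loss += batch_loss * len(idx)

            # backprop: softmax + cross-entropy gives dZ = (P - Y) / B
            dz = (probs - yb) / len(idx)
            grads_w: list[np.ndarray] = [None] * len(model.weights)
            grads_b: list[np.ndarray] = [None] * len(model.biases)
            for layer in range(len(model.weights) - 1, -1, -1):
                a_in, z, _a_out, mask = cache[layer]
                grads_w[layer] = a_in.T @ dz
                grads_b[layer] = dz.sum(axis=0)
                if layer > 0:
                    da = dz @ model.weights[layer].T
                    a_prev_in, z_prev, a_prev_out, mask_prev = cache[layer - 1]
                    if mask_prev is not None:
                        da = da * mask_prev
                        pre_drop = np.divide(
                            a_prev_out,
                            mask_prev,
                            out=np.zeros_like(a_prev_out),
                            where=mask_prev != 0,
                        )
                    else:
                        pre_drop = a_prev_out
                    dz = da * act_grad(z_prev, pre_drop)

            step += 1
            lr_t = (
                config.learning_rate
                * np.sqrt(1.0 - config.beta2**step)
                / (1.0 - config.beta1**step)
            )
            for i in range(len(model.weights)):
                m_w[i] = config.beta1 * m_w[i] + (1 - config.beta1) * grads_w[i]
                v_w[i] = config.beta2 * v_w[i] + (1 - config.beta2) * grads_w[i] ** 2
                model.weights[i] -= lr_t * m_w[i] / (np.sqrt(v_w[i]) + config.eps)
                m_b[i] = config.beta1 * m_b[i] + (1 - config.beta1) * grads_b[i]
                v_b[i] = config.beta2 * v_b[i] + (1 - config.beta2) * grads_b[i] ** 2
                model.biases[i] -= lr_t * m_b[i] / (np.sqrt(v_b[i]) + config.eps)
        model.history.append(epoch_loss / n)

    runtime = time.perf_counter() - t0
    train_acc, train_loss = evaluate(model, train_set)
    test_acc, test_loss = (
        evaluate(model, test_set) if test_set is not None and len(test_set) else (np.nan, np.nan)
    )
    val_acc, val_loss = (
        evaluate(model, validation_set)
        if validation_set is not None and len(validation_set)
        else (np.nan, np.nan)
    )
    return TrialResult(
        test_accuracy=test_acc,
        test_loss=test_loss,
        train_accuracy=train_acc,
        train_loss=train_loss,
        validation_accuracy=val_acc,
        validation_loss=val_loss,
        runtime_s=runtime,
        seed=config.seed,
    )


def save_model(model: MLPModel, path: str) -> None:
    """Serialize parameters plus an architecture manifest for exact reload."""
    arrays = {}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    manifest = {
        "hidden_layers": model.arch.hidden_layers,
        "width": model.arch.width,
        "dropout": model.arch.dropout,
        "input_dim": model.arch.input_dim,
        "output_dim": model.arch.output_dim,
        "activation": model.arch.activation,
        "history": model.history,
    }
    np.savez(path, manifest=json.dumps(manifest), **arrays)


def load_model(path: str) -> MLPModel:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        history = manifest.pop("history")
        arch = ArchitectureSpec(**manifest)
        n_layers = arch.hidden_layers + 1
        weights = [data[f"w{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
    return MLPModel(arch, weights, biases, history)
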