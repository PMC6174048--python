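"""Drowsiness scorer: a small feed-forward network trained by backprop.

Architecture is fixed by design: two inputs (window-averaged upper and
lower dark-pixel ratios), three hidden layers with the tansig (hyperbolic
tangent sigmoid) activation, and one logistic output so the drowsiness
level lives in [0, 1].  Training is plain full-batch gradient descent on
mean squared error — no momentum, no adaptive steps — with seeded
uniform(-0.5, 0.5) initialization.  Inputs are z-scored with statistics
from the training split; the standardization constants travel with the
model so inference needs nothing else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, TrainingError


def tansig(x: np.ndarray) -> np.ndarray:
    """Hyperbolic tangent sigmoid, ``2/(1+exp(-2x)) - 1`` == tanh(x)."""
    return np.tanh(x)


def logistic(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic sigmoid."""
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class MLPParams:
    """Weights, biases and input standardization of the scorer."""

    layer_sizes: list[int]
    weights: list[np.ndarray]           # weights[l]: (n_in, n_out)
    biases: list[np.ndarray]            # biases[l]: (n_out,)
    input_mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    input_std: np.ndarray = field(default_factory=lambda: np.ones(2))
    hidden_activation: str = "tansig"
    output_activation: str = "logistic"

    def validate(self) -> None:
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ParameterError("weights inconsistent with layer_sizes")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (self.layer_sizes[l], self.layer_sizes[l + 1]):
                raise ParameterError(f"weight {l} has shape {w.shape}")
            if b.shape != (self.layer_sizes[l + 1],):
                raise ParameterError(f"bias {l} has shape {b.shape}")
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ParameterError("non-finite parameters")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 1000
    learning_rate: float = 0.05
    train_fraction: float = 0.7
    seed: int = 0
    hidden_sizes: tuple[int, int, int] = (10, 10, 10)

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ParameterError("epochs must be >= 0")
        if not 0.0 < self.train_fraction < 1.0:
            raise ParameterError("train_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")


@dataclass(frozen=True)
class EvalReport:
    mse: float
    accuracy_pct: float
    n: int


def init_params(
    layer_sizes: list[int], seed: int = 0
) -> MLPParams:
    """Seeded uniform(-0.5, 0.5) weights and biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(rng.uniform(-0.5, 0.5, size=(n_in, n_out)))
        biases.append(rng.uniform(-0.5, 0.5, size=n_out))
    return MLPParams(list(layer_sizes), weights, biases)


def forward(
    params: MLPParams, X: np.ndarray, return_cache: bool = False
):
    """Network output in [0, 1] for a (n, 2) batch or a single 2-vector.

    With ``return_cache=True`` also returns the per-layer activations
    (post-nonlinearity), which backprop reuses.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != params.layer_sizes[0]:
        raise ParameterError(
            f"expected {params.layer_sizes[0]} inputs, got {X.shape[1]}"
        )
    if not np.isfinite(X).all():
        raise ParameterError("non-finite inputs")
    a = (X - params.input_mean) / params.input_std
    cache = [a]
    last = len(params.weights) - 1
    for l, (w, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ w + b
        a = logistic(z) if l == last else tansig(z)
        cache.append(a)
    out = a[:, 0]
    if single:
        out = float(out[0])
    return (out, cache) if return_cache else out


def mse_loss(params: MLPParams, X: np.ndarray, targets: np.ndarray) -> float:
    y = forward(params, X)
    return float(np.mean((np.asarray(y) - np.asarray(targets)) ** 2))


def gradients(
    params: MLPParams, X: np.ndarray, targets: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact backprop gradients of the batch-mean squared error."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(targets, dtype=float).reshape(-1)
    if X.shape[0] == 0:
        raise ParameterError("batch must be nonempty")
    if X.shape[0] != t.shape[0]:
        raise ParameterError("inputs and targets disagree in length")
    y, cache = forward(params, X, return_cache=True)
    n = X.shape[0]
    # output layer: logistic, dL/dy = 2 (y - t) / n, y' = y (1 - y)
    delta = (2.0 / n) * (y - t)[:, None] * (cache[-1] * (1.0 - cache[-1]))
    gw = [np.empty_like(w) for w in params.weights]
    gb = [np.empty_like(b) for b in params.biases]
    for l in range(len(params.weights) - 1, -1, -1):
        gw[l] = cache[l].T @ delta
        gb[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ params.weights[l].T) * (1.0 - cache[l] ** 2)
    return gw, gb


def split_dataset(
    dataset: np.ndarray, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic seeded shuffle, then an exact floor(n*fraction) split."""
    dataset = np.asarray(dataset)
    n = dataset.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 records to split")
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction))
    return dataset[order[:n_train]], dataset[order[n_train:]]


def train(
    dataset: np.ndarray, config: TrainConfig = TrainConfig()
) -> tuple[MLPParams, list[float]]:
    """Full-batch gradient descent for exactly ``config.epochs`` steps.

    ``dataset`` is (n, 3): two features then the target label.  Returns
    the trained parameters and the per-epoch training MSE (recorded after
    each update; length equals ``epochs``).  ``epochs=0`` returns the
    seeded initialization untouched.
    """
    dataset = np.asarray(dataset, dtype=float)
    if dataset.ndim != 2 or dataset.shape[1] != 3:
        raise ParameterError("dataset must be (n, 3): two features + label")
    X, t = dataset[:, :2], dataset[:, 2]
    sizes = [2, *config.hidden_sizes, 1]
    params = init_params(sizes, seed=config.seed)
    params.input_mean = X.mean(axis=0)
    std = X.std(axis=0)
    params.input_std = np.where(std > 0, std, 1.0)
    history: list[float] = []
    lr = config.learning_rate
    for epoch in range(config.epochs):
        gw, gb = gradients(params, X, t)
        for l in range(len(params.weights)):
            params.weights[l] -= lr * gw[l]
            params.biases[l] -= lr * gb[l]
        loss = mse_loss(params, X, t)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        history.append(loss)
    return params, history


def evaluate(
    params: MLPParams, dataset: np.ndarray, decision_threshold: float = 0.5
) -> EvalReport:
    """MSE of the continuous output plus thresholded accuracy in percent."""
    dataset = np.asarray(dataset, dtype=float)
    if dataset.shape[0] == 0:
        raise ParameterError("dataset must be nonempty")
    X, t = dataset[:, :2], dataset[:, 2]
    y = np.asarray(forward(params, X))
    mse = float(np.mean((y - t) ** 2))
    acc = float(
        np.mean((y >= decision_threshold) == (t >= decision_threshold)) * 100.0
    )
    return EvalReport(mse=mse, accuracy_pct=acc, n=int(dataset.shape[0]))


def save_model(params: MLPParams, path: str | Path) -> Path:
    """Serialize to JSON (row-major weights + standardization constants)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "layer_sizes": params.layer_sizes,
        "weights": [w.tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
        "input_mean": params.input_mean.tolist(),
        "input_std": params.input_std.tolist(),
        "hidden_activation": params.hidden_activation,
        "output_activation": params.output_activation,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_model(path: str | Path) -> MLPParams:
    payload = json.loads(Path(path).read_text())
    params = MLPParams(
        layer_sizes=list(payload["layer_sizes"]),
        weights=[np.array(w, dtype=float) for w in payload["weights"]],
        biases=[np.array(b, dtype=float) for b in payload["biases"]],
        input_mean=np.array(payload["input_mean"], dtype=float),
        input_std=np.array(payload["input_std"], dtype=float),
        hidden_activation=payload.get("hidden_activation", "tansig"),
        output_activation=payload.get("output_activation", "logistic"),
    )
    params.validate()
    return params
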