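"""Small feed-forward regression network with tanh hidden layers.

This mirrors the second modeling route applied to the fermentation data: a
fully connected network (here 3 inputs -> 4 -> 5 -> 1 output) with
hyperbolic-tangent hidden activations and a linear output, trained by
full-batch gradient descent on mean squared error plus a squared-magnitude
weight penalty, with a holdback fraction of the runs reserved for
validation.  Several seeded restarts are run and the network with the
highest validation R2 is kept — an automated counterpart of trial-and-error
retraining.

Inputs are taken in coded design units; the response is standardized on the
training subset before optimization and predictions are mapped back to the
original scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .design import DesignMatrix, ResponseTable
from .metrics import compute_metrics

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "MLPModel",
    "initialize_network",
    "train_network",
    "predict_network",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture: input width, ordered hidden widths, output width."""

    input_size: int = 3
    hidden: tuple[int, ...] = (4, 5)
    output_size: int = 1

    def __post_init__(self) -> None:
        widths = (self.input_size, *self.hidden, self.output_size)
        if any(w < 1 for w in widths):
            raise ValueError(f"all layer widths must be >= 1, got {widths}")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_size, *self.hidden, self.output_size)

    @property
    def n_parameters(self) -> int:
        sizes = self.layer_sizes
        return sum(sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1))


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``tours`` is the number of full-batch gradient steps; ``penalty_lambda``
    scales the squared-weight penalty (weights only, not biases) on the
    standardized response scale.  ``holdback_fraction`` of runs is reserved
    for validation unless an explicit ``validation_mask`` (or a labelled
    response table) is supplied.
    """

    tours: int = 10_000
    learning_rate: float = 0.1
    penalty_lambda: float = 0.01
    holdback_fraction: float = 0.45
    validation_mask: np.ndarray | None = None
    seed: int = 0
    restarts: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.holdback_fraction < 1.0:
            raise ValueError("holdback_fraction must be in (0, 1)")
        if self.penalty_lambda < 0:
            raise ValueError("penalty_lambda must be >= 0")
        if self.restarts < 1 or self.tours < 1:
            raise ValueError("restarts and tours must be >= 1")


@dataclass
class MLPModel:
    """Network weights plus the scaling needed for real-unit prediction."""

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    factor_names: list[str] | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0
    history: np.ndarray | None = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Scaled forward pass on coded inputs; returns standardized output."""
        a = np.asarray(X, dtype=float)
        n_hidden = len(self.spec.hidden)
        for layer, (W, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ W + b
            if layer < n_hidden:
                a = np.tanh(a)
        return a

    def to_json(self) -> str:
        doc = {
            "layer_sizes": list(self.spec.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "factor_names": self.factor_names,
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "final_loss": None if self.history is None else float(self.history[-1]),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        doc = json.loads(text)
        sizes = doc["layer_sizes"]
        spec = NetworkSpec(sizes[0], tuple(sizes[1:-1]), sizes[-1])
        return cls(
            spec=spec,
            weights=[np.asarray(w, dtype=float) for w in doc["weights"]],
            biases=[np.asarray(b, dtype=float) for b in doc["biases"]],
            factor_names=doc.get("factor_names"),
            y_mean=doc.get("y_mean", 0.0),
            y_sd=doc.get("y_sd", 1.0),
        )


def initialize_network(spec: NetworkSpec, seed: int) -> MLPModel:
    """Seeded small-random initialization (sd 1/sqrt(fan_in) per layer)."""
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(spec=spec, weights=weights, biases=biases)


def loss_and_gradients(
    model: MLPModel, X: np.ndarray, t: np.ndarray, penalty_lambda: float
):
    """Penalized MSE and its gradients w.r.t. every weight and bias.

    Loss = mean((pred - t)^2) + lambda * sum of squared weights.  Gradients
    come from standard backpropagation through the tanh layers; this is the
    function whose correctness the finite-difference tests pin down.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float).reshape(len(X), -1)
    n_hidden = len(model.spec.hidden)
    n = len(X)

    # overflow here signals divergence, which the trainer reports explicitly
    with np.errstate(over="ignore", invalid="ignore"):
        activations = [X]
        a = X
        for layer, (W, b) in enumerate(zip(model.weights, model.biases)):
            z = a @ W + b
            a = np.tanh(z) if layer < n_hidden else z
            activations.append(a)
        pred = activations[-1]
        err = pred - t
        loss = float(np.mean(err**2)) + penalty_lambda * sum(
            float(np.sum(W**2)) for W in model.weights
        )

        dW = [None] * len(model.weights)
        db = [None] * len(model.biases)
        delta = 2.0 * err / n  # d loss / d output
        for layer in range(len(model.weights) - 1, -1, -1):
            a_prev = activations[layer]
            dW[layer] = a_prev.T @ delta + 2.0 * penalty_lambda * model.weights[layer]
            db[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ model.weights[layer].T) * (1.0 - activations[layer] ** 2)
    return loss, dW, db


def _holdback_split(n: int, config: TrainConfig, responses: ResponseTable) -> np.ndarray:
    """Boolean validation mask from, in order of precedence: an explicit
    config mask, subset labels on the response table, or a seeded draw."""
    if config.validation_mask is not None:
        mask = np.asarray(config.validation_mask, dtype=bool).ravel()
        if len(mask) != n:
            raise ValueError("validation_mask length mismatch")
    elif responses.subset is not None:
        mask = responses.mask("validation")
    else:
        rng = np.random.default_rng(config.seed)
        n_val = int(round(config.holdback_fraction * n))
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_val, replace=False)] = True
    if mask.all() or not mask.any():
        raise ValueError("holdback split must leave both subsets nonempty")
    return mask


def train_network(
    model_or_spec,
    design: DesignMatrix,
    responses: ResponseTable,
    config: TrainConfig,
):
    """Train on coded inputs; keep the restart with the best validation R2.

    Returns ``(model, metrics)`` where metrics maps
    training/validation/overall to :class:`~keraopt.metrics.Metrics` of the
    kept network on the original response scale.
    """
    if isinstance(model_or_spec, NetworkSpec):
        spec = model_or_spec
    else:
        spec = model_or_spec.spec
    X = design.coded
    y = responses.response
    n = len(y)
    if X.shape[1] != spec.input_size:
        raise ValueError(
            f"design has {X.shape[1]} factors but the network expects {spec.input_size}"
        )
    val_mask = _holdback_split(n, config, responses)
    train_mask = ~val_mask
    if train_mask.sum() < 2:
        raise ValueError("training set must contain more than one run")

    y_mean = float(y[train_mask].mean())
    y_sd = float(y[train_mask].std(ddof=0))
    if y_sd == 0.0:
        y_sd = 1.0
    t = ((y - y_mean) / y_sd).reshape(-1, 1)

    best = None
    best_val_r2 = -np.inf
    seeds = np.random.SeedSequence(config.seed).generate_state(config.restarts)
    for restart_seed in seeds:
        net = initialize_network(spec, int(restart_seed))
        net.factor_names = design.factor_names
        net.y_mean, net.y_sd = y_mean, y_sd
        history = np.empty(config.tours)
        for tour in range(config.tours):
            loss, dW, db = loss_and_gradients(
                net, X[train_mask], t[train_mask], config.penalty_lambda
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training diverged (non-finite loss); reduce learning_rate"
                )
            history[tour] = loss
            for layer in range(len(net.weights)):
                net.weights[layer] -= config.learning_rate * dW[layer]
                net.biases[layer] -= config.learning_rate * db[layer]
        net.history = history
        pred = predict_network(net, design)
        val_metrics = compute_metrics(y, pred, mask=val_mask)
        score = -np.inf if val_metrics.r2 is None else val_metrics.r2
        if score > best_val_r2:
            best_val_r2 = score
            best = net

    pred = predict_network(best, design)
    metrics = {
        "training": compute_metrics(y, pred, mask=train_mask),
        "validation": compute_metrics(y, pred, mask=val_mask),
        "overall": compute_metrics(y, pred),
    }
    return best, metrics


def predict_network(model: MLPModel, design: DesignMatrix) -> np.ndarray:
    """Deterministic forward pass on a design, descaled to response units."""
    if model.factor_names is not None and design.factor_names != model.factor_names:
        raise ValueError(
            f"design factors {design.factor_names} do not match the network's "
            f"training factors {model.factor_names}"
        )
    out = model.forward(design.coded)
    return out.ravel() * model.y_sd + model.y_mean
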