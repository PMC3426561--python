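"""Feed-forward tanh networks trained by Levenberg--Marquardt.

The classifier is a small multilayer perceptron: 20 or 21 inputs (percent
composition, optionally pI), one or two hidden layers, and a single output
unit, with the hyperbolic-tangent squashing function on every layer, so
outputs live in (-1, 1) and are compared against the +1/-1 class labels.

Training minimizes mean squared residual with the Levenberg--Marquardt
update  dw = (J'J + mu*I)^{-1} J'e,  where J is the Jacobian of per-sample
outputs with respect to all weights and e = target - output. The damping
parameter mu interpolates between Gauss--Newton (mu -> 0) and small-step
gradient descent (large mu): a step is accepted only if the training MSE
decreases, otherwise mu is escalated and the step retried; mu is relaxed
after every accepted step. A held-out validation set stops training once
its MSE fails to strictly decrease for ``max_fail`` consecutive epochs, and
the weights from the best-validation epoch are returned.

Inputs are min-max scaled per feature to [-1, 1] using the training data
only; the fitted scaling travels with the model.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

MODEL_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a serialized model cannot be loaded."""


@dataclass
class TrainingConfig:
    """Levenberg--Marquardt and early-stopping settings.

    Defaults follow the classical toolbox values for this trainer:
    mu starts at 1e-3, grows by 10 on a rejected step, shrinks by 0.1 on an
    accepted one, and training halts if mu would exceed ``mu_max``. The
    validation monitor tolerates ``max_fail`` = 6 consecutive epochs without
    strict improvement. ``goal_mse`` = 0 means "train until stopped".
    """

    max_epochs: int = 1000
    max_fail: int = 6
    mu_init: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    goal_mse: float = 0.0
    init: str = "nguyen-widrow"  # or "uniform"

    def __post_init__(self) -> None:
        if self.max_fail < 1:
            raise ValueError("max_fail must be >= 1")
        if self.mu_init <= 0:
            raise ValueError("mu_init must be positive")
        if not (self.mu_increase > 1.0 > self.mu_decrease > 0.0):
            raise ValueError("need mu_increase > 1 > mu_decrease > 0")


@dataclass
class TrainingTrace:
    """Per-epoch record of a training run."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1  # index into the per-epoch lists

    @property
    def n_epochs(self) -> int:
        return len(self.train_mse)


class MaxFailMonitor:
    """Validation-based early stopping with a consecutive-failure budget.

    An epoch "fails" when the validation MSE does not strictly decrease
    below the best seen so far (equality counts as failure). The counter
    resets on strict improvement; :meth:`update` returns True once
    ``max_fail`` consecutive failures have accumulated.
    """

    def __init__(self, max_fail: int = 6):
        if max_fail < 1:
            raise ValueError("max_fail must be >= 1")
        self.max_fail = max_fail
        self.best = np.inf
        self.best_epoch = -1
        self.fails = 0
        self._epoch = -1

    def update(self, val_mse: float) -> bool:
        self._epoch += 1
        if val_mse < self.best:
            self.best = val_mse
            self.best_epoch = self._epoch
            self.fails = 0
        else:
            self.fails += 1
        return self.fails >= self.max_fail


@dataclass
class MLPModel:
    """A trained (or initialized) tanh multilayer perceptron.

    ``weights[l]`` has shape (units_out, units_in); tanh is applied on every
    layer including the output. ``x_min``/``x_max`` hold the per-feature
    min-max scaling fitted on training inputs; features with min == max are
    passed through unscaled.
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_min: np.ndarray
    x_max: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = self.layer_sizes
        if len(sizes) < 2 or sizes[-1] != 1:
            raise ValueError("need at least input and a single output unit")
        if len(self.weights) != len(sizes) - 1:
            raise ValueError("one weight matrix per layer required")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l + 1], sizes[l]) or b.shape != (sizes[l + 1],):
                raise ValueError(f"layer {l}: weight shape {w.shape} inconsistent with sizes {sizes}")
        if self.x_min.shape != (sizes[0],) or self.x_max.shape != (sizes[0],):
            raise ValueError("input scaling must provide one (min, max) per input feature")

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    # -- parameter flattening -------------------------------------------------

    def get_params(self) -> np.ndarray:
        return np.concatenate([np.concatenate([w.ravel(), b]) for w, b in zip(self.weights, self.biases)])

    def set_params(self, theta: np.ndarray) -> None:
        pos = 0
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[l] = theta[pos: pos + w.size].reshape(w.shape).copy()
            pos += w.size
            self.biases[l] = theta[pos: pos + b.size].copy()
            pos += b.size
        if pos != theta.size:
            raise ValueError("parameter vector size mismatch")

    # -- forward pass ---------------------------------------------------------

    def scale_inputs(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} input features, got {X.shape[1]}")
        span = self.x_max - self.x_min
        ok = span > 0
        Xs = X.copy()
        Xs[:, ok] = 2.0 * (X[:, ok] - self.x_min[ok]) / span[ok] - 1.0
        return Xs

    def _activations(self, X: np.ndarray) -> list[np.ndarray]:
        a = self.scale_inputs(X)
        acts = [a]
        for w, b in zip(self.weights, self.biases):
            a = np.tanh(a @ w.T + b)
            acts.append(a)
        return acts

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network output in (-1, 1) for each row of ``X`` (pure function)."""
        squeeze = np.asarray(X).ndim == 1
        out = self._activations(X)[-1][:, 0]
        return float(out[0]) if squeeze else out


def init_model(
    layer_sizes: Sequence[int],
    training_inputs: np.ndarray,
    seed: int = 0,
    config: Optional[TrainingConfig] = None,
    meta: Optional[dict] = None,
) -> MLPModel:
    """Create a model with scaling fitted to the training inputs.

    Scaling maps each feature's training min to -1 and max to +1. Weights
    use seeded Nguyen--Widrow initialization (uniform(-0.5, 0.5) behind the
    ``init="uniform"`` config switch); the same seed gives bit-identical
    weights.
    """
    config = config or TrainingConfig()
    X = np.atleast_2d(np.asarray(training_inputs, dtype=float))
    sizes = list(layer_sizes)
    if X.shape[1] != sizes[0]:
        raise ValueError(f"training inputs have {X.shape[1]} features, layer_sizes expect {sizes[0]}")
    if X.shape[0] < 2:
        raise ValueError("need at least two training inputs to fit scaling")
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    if np.any(x_min == x_max):
        warnings.warn("constant input feature(s); scaling degenerates to identity there", stacklevel=2)

    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, units in zip(sizes[:-1], sizes[1:]):
        if config.init == "uniform":
            w = rng.uniform(-0.5, 0.5, size=(units, fan_in))
            b = rng.uniform(-0.5, 0.5, size=units)
        else:
            # Nguyen-Widrow: random directions scaled to magnitude
            # 0.7 * units**(1/fan_in), biases spread across the input range.
            w = rng.uniform(-1.0, 1.0, size=(units, fan_in))
            beta = 0.7 * units ** (1.0 / fan_in)
            norms = np.linalg.norm(w, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            w = beta * w / norms
            if units == 1:
                b = rng.uniform(-beta, beta, size=1)
            else:
                b = beta * np.linspace(-1.0, 1.0, units) * np.sign(w[:, 0])
        weights.append(w)
        biases.append(b)
    return MLPModel(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        x_min=x_min.copy(),
        x_max=x_max.copy(),
        meta={"seed": seed, "init": config.init, **(meta or {})},
    )


# ---------------------------------------------------------------------------
# Levenberg--Marquardt machinery

def mse(model: MLPModel, X: np.ndarray, y: np.ndarray) -> float:
    r = np.asarray(y, dtype=float) - model.forward(X)
    return float(np.mean(r * r))


def output_jacobian(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """d(output_i)/d(theta_j) for every sample, shape (n, n_params).

    Computed by a vectorized backward pass: delta at the output layer is
    tanh'(z) = 1 - a^2, and propagates as delta_{l-1} = (delta_l W_l) *
    (1 - a_{l-1}^2). Weight blocks are outer products delta x activation.
    """
    acts = model._activations(X)
    n = acts[0].shape[0]
    delta = 1.0 - acts[-1] ** 2  # (n, 1)
    blocks: list[np.ndarray] = []
    for l in range(len(model.weights) - 1, -1, -1):
        a_prev = acts[l]
        dW = np.einsum("nu,ni->nui", delta, a_prev).reshape(n, -1)
        blocks.append(np.concatenate([dW, delta], axis=1))  # weights then biases
        if l > 0:
            delta = (delta @ model.weights[l]) * (1.0 - a_prev ** 2)
    J = np.concatenate(blocks[::-1], axis=1)
    return J


def lm_step(model: MLPModel, X: np.ndarray, y: np.ndarray, mu: float) -> tuple[np.ndarray, float]:
    """One damped Gauss--Newton proposal at damping ``mu``.

    Returns the candidate parameter vector theta + (J'J + mu I)^{-1} J'e and
    the training MSE it would achieve. Acceptance is the caller's business
    (see :func:`train`): a proposal is only adopted when the MSE decreases.
    """
    y = np.asarray(y, dtype=float)
    J = output_jacobian(model, X)
    e = y - model.forward(X)
    A = J.T @ J + mu * np.eye(J.shape[1])
    step = np.linalg.solve(A, J.T @ e)
    theta = model.get_params()
    candidate = theta + step
    model.set_params(candidate)
    new_mse = mse(model, X, y)
    model.set_params(theta)  # restore; caller decides
    return candidate, new_mse


def train(
    model: MLPModel,
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    config: Optional[TrainingConfig] = None,
) -> tuple[MLPModel, TrainingTrace]:
    """Train in place by LM with validation early stopping.

    Each epoch computes one Jacobian and escalates mu until a proposal
    lowers the training MSE (accepted steps therefore form a strictly
    decreasing MSE sequence). Stops on ``max_fail`` consecutive epochs
    without strict validation improvement, on ``max_epochs``, on reaching
    ``goal_mse``, or if mu overflows ``mu_max``. The returned model carries
    the weights of the epoch with minimum validation MSE.
    """
    config = config or TrainingConfig()
    train_X, val_X = np.atleast_2d(train_X), np.atleast_2d(val_X)
    train_y, val_y = np.asarray(train_y, dtype=float), np.asarray(val_y, dtype=float)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if val_X.shape[0] == 0:
        raise ValueError("empty validation set: validation-based stopping is mandatory")

    trace = TrainingTrace()
    monitor = MaxFailMonitor(config.max_fail)
    mu = config.mu_init
    best_theta = model.get_params()
    current_mse = mse(model, train_X, train_y)

    for _ in range(config.max_epochs):
        accepted = False
        while mu <= config.mu_max:
            candidate, new_mse = lm_step(model, train_X, train_y, mu)
            if new_mse < current_mse:
                model.set_params(candidate)
                current_mse = new_mse
                mu = max(mu * config.mu_decrease, np.finfo(float).tiny)
                accepted = True
                break
            mu *= config.mu_increase
        if not accepted:
            trace.stop_reason = "mu_overflow"
            break

        val = mse(model, val_X, val_y)
        trace.train_mse.append(current_mse)
        trace.val_mse.append(val)
        prev_best = monitor.best
        stop = monitor.update(val)
        if val < prev_best:  # strict improvement: these weights are the new best
            best_theta = model.get_params()
        if current_mse <= config.goal_mse:
            trace.stop_reason = "goal"
            break
        if stop:
            trace.stop_reason = "max_fail"
            break
    else:
        trace.stop_reason = "max_epochs"

    trace.best_epoch = monitor.best_epoch
    model.set_params(best_theta)
    model.meta["stop_reason"] = trace.stop_reason
    model.meta["best_epoch"] = trace.best_epoch
    return model, trace


# ---------------------------------------------------------------------------
# Serialization

def _payload(model: MLPModel) -> dict:
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "layer_sizes": model.layer_sizes,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "x_min": model.x_min.tolist(),
        "x_max": model.x_max.tolist(),
        "meta": model.meta,
    }


def _digest(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def save_model(model: MLPModel, path: str | Path) -> None:
    """Write a self-describing JSON model file with an integrity digest."""
    payload = _payload(model)
    Path(path).write_text(json.dumps({"checksum": _digest(payload), **payload}, indent=1))


def load_model(path: str | Path) -> MLPModel:
    """Lossless inverse of :func:`save_model`; rejects tampered/old files."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not a model file ({exc})") from exc
    version = raw.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(f"{path}: format version {version!r} != {MODEL_FORMAT_VERSION}")
    checksum = raw.pop("checksum", None)
    if checksum != _digest(raw):
        raise ModelFormatError(f"{path}: checksum mismatch — file corrupted or edited")
    return MLPModel(
        layer_sizes=list(raw["layer_sizes"]),
        weights=[np.array(w, dtype=float) for w in raw["weights"]],
        biases=[np.array(b, dtype=float) for b in raw["biases"]],
        x_min=np.array(raw["x_min"], dtype=float),
        x_max=np.array(raw["x_max"], dtype=float),
        meta=dict(raw["meta"]),
    )
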