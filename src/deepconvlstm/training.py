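"""Supervised training of the convolutional-recurrent classifiers.

Mini-batch gradient descent on the cross-entropy loss with the RMSProp
per-parameter step-size rule, orthogonal weight initialisation, inverted
dropout on the inputs of the dense/recurrent layers, and early stopping
on the validation sample-weighted F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import evaluate
from .network import (
    BASELINE,
    RECURRENT,
    ModelParameters,
    _backward,
    _forward_cached,
)
from .preprocessing import WindowBatch

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "OptimizerState",
    "TrainingHistory",
    "cross_entropy_loss",
    "rmsprop_step",
    "orthogonal_init",
    "dropout_apply",
    "compute_gradients",
    "train",
]

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyper-parameters.

    Defaults follow the standard recipe for this architecture family:
    learning rate 1e-3, RMSProp decay rho = 0.9, mini-batches of 100
    windows, dropout probability 0.5 on the inputs of every dense or
    recurrent layer. ``patience`` counts epochs without a validation-F1
    improvement before stopping.
    """

    learning_rate: float = 1e-3
    rmsprop_decay: float = 0.9
    batch_size: int = 100
    dropout_p: float = 0.5
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    rmsprop_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_p < 1:
            raise ValueError("require 0 <= dropout_p < 1")
        if not 0 < self.rmsprop_decay < 1:
            raise ValueError("require 0 < rmsprop_decay < 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class OptimizerState:
    """RMSProp accumulated squared-gradient cache, one array per parameter."""

    cache: dict[str, np.ndarray]

    @classmethod
    def zeros_like(cls, m: ModelParameters) -> "OptimizerState":
        return cls(cache={name: np.zeros_like(a) for name, a in m.arrays()})


@dataclass
class TrainingHistory:
    """Per-epoch training loss and validation weighted F1."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = -np.inf

    def append(self, epoch: int, loss: float, f1: float) -> None:
        self.epochs.append(epoch)
        self.train_loss.append(loss)
        self.val_f1.append(f1)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttrain_loss\tval_f1\n")
            for e, l, f in zip(self.epochs, self.train_loss, self.val_f1):
                fh.write(f"{e}\t{l:.6f}\t{f:.6f}\n")


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class over a batch."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    p_true = probs[np.arange(len(labels)), labels]
    if (p_true < PROB_FLOOR).any():
        logger.warning("true-class probability clamped at %g", PROB_FLOOR)
        p_true = np.maximum(p_true, PROB_FLOOR)
    return float(-np.log(p_true).mean())


def rmsprop_step(
    m: ModelParameters,
    grads: dict[str, np.ndarray],
    state: OptimizerState,
    cfg: TrainingConfig,
) -> None:
    """In-place RMSProp update.

    cache <- rho * cache + (1 - rho) * g**2;
    theta <- theta - lr * g / sqrt(cache + eps).
    """
    rho, lr, eps = cfg.rmsprop_decay, cfg.learning_rate, cfg.rmsprop_epsilon
    for name, arr in m.arrays():
        g = grads[name]
        c = state.cache[name]
        c *= rho
        c += (1.0 - rho) * g * g
        arr -= lr * g / np.sqrt(c + eps)


def orthogonal_init(shape, seed_or_rng) -> np.ndarray:
    """Orthogonally initialised weight matrix.

    For a 2-D shape the rows (if wide) or columns (if tall) are
    orthonormal. 1-D shapes (biases, peephole vectors) return zeros.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    shape = tuple(shape)
    if len(shape) == 1:
        return np.zeros(shape)
    if len(shape) != 2:
        raise ValueError("orthogonal_init expects a 1-D or 2-D shape")
    from .network import _orthogonal

    return _orthogonal(rng, shape)


def dropout_apply(
    a: np.ndarray,
    p: float,
    training: bool,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inverted dropout: zero each element with probability p in training.

    Survivors are scaled by 1/(1-p) so the expected activation is
    unchanged and inference needs no compensation; in inference mode (or
    with p = 0) the input is returned unchanged.
    """
    if not 0 <= p < 1:
        raise ValueError("require 0 <= p < 1")
    if not training or p == 0.0:
        return a
    if rng is None:
        raise ValueError("training-mode dropout needs a random generator")
    mask = (rng.random(a.shape) >= p) / (1.0 - p)
    return a * mask


def _dropout_masks(
    m: ModelParameters,
    batch_size: int,
    p: float,
    rng: np.random.Generator | None,
) -> list | None:
    """Pre-draw the three dropout masks (inputs of hidden layers 1, 2
    and of the softmax layer) for one forward/backward pass."""
    if p == 0.0 or rng is None:
        return None
    spec = m.spec
    n = spec.n_hidden
    scale = 1.0 / (1.0 - p)
    if spec.variant == RECURRENT:
        t_len = spec.final_map_len
        shapes = [
            (batch_size, t_len, spec.recurrent_input_width),
            (batch_size, t_len, n),
            (batch_size, n),
        ]
    else:
        shapes = [
            (batch_size, spec.flattened_width),
            (batch_size, n),
            (batch_size, n),
        ]
    return [(rng.random(s) >= p) * scale for s in shapes]


def compute_gradients(
    m: ModelParameters,
    batch: WindowBatch,
    dropout_p: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and exact gradients on one mini-batch.

    Reverse-mode differentiation of the mean cross-entropy at the
    final-time-step prediction, with respect to every trainable scalar.
    With ``dropout_p > 0`` the same freshly drawn dropout masks are used
    in the forward and backward passes.
    """
    masks = _dropout_masks(m, len(batch), dropout_p, rng)
    probs, cache = _forward_cached(m, batch.sequences, dropout_masks=masks)
    loss = cross_entropy_loss(probs, batch.labels)
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite loss {loss}; max |prob|="
            f"{np.abs(probs).max():.3g}"
        )
    grads = _backward(m, cache, batch.labels)
    return loss, grads


def _clone_arrays(m: ModelParameters) -> dict[str, np.ndarray]:
    return {name: arr.copy() for name, arr in m.arrays()}


def _restore_arrays(m: ModelParameters, snapshot: dict[str, np.ndarray]) -> None:
    for name, arr in m.arrays():
        arr[...] = snapshot[name]


def train(
    model: ModelParameters,
    train_batch: WindowBatch,
    val_batch: WindowBatch,
    cfg: TrainingConfig,
) -> TrainingHistory:
    """Train in place; return the per-epoch history.

    Each epoch shuffles the training windows (seeded), sweeps
    mini-batches of ``cfg.batch_size`` (keeping the last partial batch),
    applies one RMSProp update per mini-batch, then scores the
    validation set by weighted F1. Training stops after
    ``cfg.patience`` epochs without a validation improvement, or at
    ``cfg.max_epochs``; the best-epoch parameters are restored.
    """
    if len(train_batch) < 1:
        raise ValueError("need at least one training window")
    rng = np.random.default_rng(cfg.seed)
    opt = OptimizerState.zeros_like(model)
    history = TrainingHistory()
    best_snapshot = _clone_arrays(model)
    epochs_since_best = 0

    n = len(train_batch)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            mini = WindowBatch(
                sequences=train_batch.sequences[idx],
                labels=train_batch.labels[idx],
                starts=train_batch.starts[idx],
            )
            try:
                loss, grads = compute_gradients(
                    model, mini, dropout_p=cfg.dropout_p, rng=rng
                )
            except FloatingPointError:
                logger.error("divergent loss at epoch %d; aborting", epoch)
                history.best_epoch = max(history.best_epoch, 0)
                _restore_arrays(model, best_snapshot)
                return history
            rmsprop_step(model, grads, opt, cfg)
            losses.append(loss)

        report = evaluate(model, val_batch)
        val_f1 = report.weighted_f1
        history.append(epoch, float(np.mean(losses)), val_f1)
        logger.info(
            "epoch %d: loss %.4f, val F1 %.4f", epoch, history.train_loss[-1], val_f1
        )
        if val_f1 > history.best_val_f1:
            history.best_val_f1 = val_f1
            history.best_epoch = epoch
            best_snapshot = _clone_arrays(model)
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best > cfg.patience:
                break

    _restore_arrays(model, best_snapshot)
    return history
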