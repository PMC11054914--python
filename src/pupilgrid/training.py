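"""Mini-batch SGD with cross-entropy loss, L2 weight decay and a staged
learning-rate schedule.

The default :class:`TrainConfig` is the protocol the classifiers were tuned
with: eta = 0.1 for 20 epochs, 0.01 for 10, 0.001 for 5, 0.0001 for 3
(38 epochs total), mini-batches of 10, weight decay lambda = 0.1, and an
80/10/10 train/validation/test split.

Weight decay is the classic L2 form ``lambda/(2 n_train) * sum(w^2)`` added
to the cost, realized in the update as the multiplicative shrinkage
``w <- (1 - eta*lambda/n_train) w - eta * grad``; biases are exempt.
Gradients are averaged (not summed) over the mini-batch so eta keeps its
meaning regardless of batch size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .dataio import LabeledSample, coord_to_class
from .errors import ConfigError, CountError, RangeError
from .netspec import NetworkSpec
from .network import (
    NetworkParams,
    backward_batch,
    forward_batch,
    init_params,
)

#: The staged schedule used for both classifier families: (eta, epochs).
DEFAULT_SCHEDULE = ((0.1, 20), (0.01, 10), (0.001, 5), (0.0001, 3))


@dataclass
class TrainConfig:
    schedule: tuple = DEFAULT_SCHEDULE
    batch_size: int = 10
    lam: float = 0.1
    split: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    early_stop_patience: Optional[int] = None

    def validate(self) -> None:
        if not self.schedule:
            raise ConfigError("schedule must contain at least one stage")
        for eta, epochs in self.schedule:
            if eta <= 0:
                raise ConfigError(f"learning rate must be > 0, got {eta}")
            if epochs < 1:
                raise ConfigError(f"epochs must be >= 1, got {epochs}")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.lam < 0:
            raise ConfigError("lambda must be >= 0")
        if abs(sum(self.split) - 1.0) > 1e-9 or any(f < 0 for f in self.split):
            raise ConfigError(f"split fractions {self.split} must sum to 1")

    @property
    def total_epochs(self) -> int:
        return sum(e for _, e in self.schedule)


@dataclass
class EpochRecord:
    epoch: int
    eta: float
    train_cost: float
    val_accuracy: float
    test_accuracy: float


@dataclass
class TrainHistory:
    records: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_rows(self) -> list:
        return [
            {
                "epoch": r.epoch,
                "eta": r.eta,
                "train_cost": r.train_cost,
                "val_accuracy": r.val_accuracy,
                "test_accuracy": r.test_accuracy,
            }
            for r in self.records
        ]


# ---------------------------------------------------------------------------
# target extractors: map a LabeledSample to its 0-based class index
# ---------------------------------------------------------------------------

def lowres_target(sample: LabeledSample) -> int:
    """Row-major position class (0-based) on the sample's own pixel grid."""
    h, w = sample.image.shape
    return coord_to_class(sample.annotation, w, h) - 1


def x_target(sample: LabeledSample) -> int:
    return sample.annotation.cx


def y_target(sample: LabeledSample) -> int:
    return sample.annotation.cy


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

def split_dataset(samples: Sequence, fractions: tuple, seed: int):
    """Disjoint, exhaustive (train, val, test) partition.

    Validation and test sizes are ``round(n * f)`` (ties up); the remainder
    goes to the training set.  The shuffle is seeded.
    """
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ConfigError(f"fractions {fractions} must sum to 1")
    n = len(samples)
    if n < 3:
        raise ConfigError(f"need at least 3 samples to split, got {n}")
    n_val = int(math.floor(n * f_val + 0.5))
    n_test = int(math.floor(n * f_test + 0.5))
    n_train = n - n_val - n_test
    if n_train < 1 or n_val < 0 or n_test < 0:
        raise ConfigError(f"degenerate split {fractions} for n={n}")
    order = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:n_train + n_val]]
    test = [samples[i] for i in order[n_train + n_val:]]
    return train, val, test


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

def cross_entropy(p: np.ndarray, target_class: int) -> float:
    """``-ln p[target]`` with p clamped at 1e-12."""
    p = np.asarray(p)
    if target_class < 0 or target_class >= p.shape[-1]:
        raise RangeError(f"target class {target_class} out of range")
    return float(-np.log(max(float(p[target_class]), 1e-12)))


def regularized_cost(
    data_cost: float, params: NetworkParams, lam: float, n_train: int
) -> float:
    """Data cost plus ``lambda/(2 n_train) * sum(w^2)`` (biases excluded)."""
    if lam == 0:
        return data_cost
    sq = sum(float(np.sum(w * w)) for w in params.weight_arrays())
    return data_cost + lam / (2.0 * n_train) * sq


# ---------------------------------------------------------------------------
# SGD
# ---------------------------------------------------------------------------

def _stack_batch(batch, target_extractor):
    X = np.stack([s.image for s in batch])
    t = np.array([target_extractor(s) for s in batch], dtype=np.intp)
    return X, t


def sgd_step(
    params: NetworkParams,
    mini_batch: Sequence,
    eta: float,
    lam: float,
    n_train: int,
    target_extractor: Callable = lowres_target,
) -> float:
    """One in-place SGD update from a mini-batch of LabeledSamples.

    Weights shrink by ``(1 - eta*lam/n_train)`` before the gradient step;
    biases are not decayed.  Returns the batch-mean cross-entropy (before
    the update), which :func:`train` accumulates into the epoch cost.
    """
    if len(mini_batch) == 0:
        raise CountError("mini-batch must be non-empty")
    X, t = _stack_batch(mini_batch, target_extractor)
    probs, caches = forward_batch(params, X, cache=True)
    loss = float(
        -np.mean(np.log(np.maximum(probs[np.arange(len(t)), t], 1e-12)))
    )
    grads = backward_batch(params, caches, probs, t)
    decay = 1.0 - eta * lam / n_train
    for p, g in zip(params.layers, grads):
        if p is None:
            continue
        p["W"] *= decay
        p["W"] -= eta * g["W"]
        p["b"] -= eta * g["b"]
    return loss


def exact_accuracy(
    params: NetworkParams,
    samples: Sequence,
    target_extractor: Callable,
    batch_size: int = 64,
) -> float:
    """Fraction of samples whose argmax class equals the target class."""
    if not samples:
        return float("nan")
    hits = 0
    for i in range(0, len(samples), batch_size):
        X, t = _stack_batch(samples[i:i + batch_size], target_extractor)
        probs = forward_batch(params, X)
        hits += int(np.sum(probs.argmax(axis=1) == t))
    return hits / len(samples)


def train(
    spec: NetworkSpec,
    target_extractor: Callable,
    data: tuple,
    config: TrainConfig,
    verbose: bool = False,
):
    """Run the staged SGD protocol; returns ``(params, TrainHistory)``.

    ``data`` is a ``(train, val, test)`` triple of LabeledSample lists.
    Each epoch re-shuffles the training set.  With early stopping enabled
    (``config.early_stop_patience``) training halts once validation
    accuracy has not improved for that many epochs, and the best-validation
    parameters are returned; otherwise the final-epoch parameters are.
    """
    config.validate()
    train_set, val_set, test_set = data
    if not train_set:
        raise ConfigError("training set is empty")
    n_train = len(train_set)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    params = init_params(spec, seed=int(np.random.SeedSequence(
        [config.seed, 0]).generate_state(1)[0] % (2**31)))

    history = TrainHistory()
    best_val = -1.0
    best_params = None
    stall = 0
    epoch_no = 0
    stop = False
    for eta, n_epochs in config.schedule:
        if stop:
            break
        for _ in range(n_epochs):
            epoch_no += 1
            order = rng.permutation(n_train)
            costs = []
            for i in range(0, n_train, config.batch_size):
                batch = [train_set[j] for j in order[i:i + config.batch_size]]
                costs.append(
                    sgd_step(params, batch, eta, config.lam, n_train,
                             target_extractor)
                )
            val_acc = exact_accuracy(params, val_set, target_extractor)
            test_acc = exact_accuracy(params, test_set, target_extractor)
            history.records.append(
                EpochRecord(epoch_no, eta, float(np.mean(costs)),
                            val_acc, test_acc)
            )
            if verbose:
                print(
                    f"epoch {epoch_no:3d}  eta={eta:<7g} "
                    f"cost={np.mean(costs):.4f}  val={val_acc:.3f}  "
                    f"test={test_acc:.3f}"
                )
            if config.early_stop_patience is not None:
                if val_acc > best_val:
                    best_val = val_acc
                    best_params = params.copy()
                    stall = 0
                else:
                    stall += 1
                    if stall >= config.early_stop_patience:
                        stop = True
                        break
    if config.early_stop_patience is not None and best_params is not None:
        return best_params, history
    return params, history
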