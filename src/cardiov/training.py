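"""Patient-wise splitting and the two-phase optimization protocol.

The ordinal head is harder to optimize from scratch than a plain softmax,
so training runs in two phases: phase 1 fits the backbone under a four-way
softmax cross-entropy objective (temporary 4-wide dense layer); phase 2
swaps in the 3-wide ordinal head (re-initialized — its shape differs) and
fine-tunes under the cumulative binary cross-entropy. The ablation heads
(four-class softmax; scalar regression under squared error) train in a
single phase of the same total epoch budget.

Optimization is Adam with L2 weight decay; the learning rate is multiplied
by 0.3 when the validation loss plateaus, and training stops early after
three reductions bring no improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn, ordinal
from .model import CardioVNet
from .nn import Tensor

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "TrainHistory",
    "TrainingDivergedError",
    "split_patients",
    "train",
    "build_ablation_head",
    "head_predictions",
    "bce_with_logits",
    "softmax_cross_entropy",
    "mse_loss",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 256
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.3
    plateau_patience: int = 3
    min_lr: float = 1e-5
    max_lr_reductions: int = 3
    weight_decay: float = 1e-4
    phase1_epochs: int = 10
    phase2_epochs: int = 10
    seed: int = 0
    head: str = "ordinal"

    def __post_init__(self):
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size and learning_rate must be positive")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr_decay_factor must be in (0, 1)")


@dataclass
class TrainHistory:
    epoch: list[int] = field(default_factory=list)
    phase: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: getattr(self, k) for k in
                             ("epoch", "phase", "train_loss", "val_loss",
                              "val_mae", "lr")})


def split_patients(metadata: pd.DataFrame, spec: SplitSpec | None = None):
    """Partition record ids into patient-disjoint train/val/test lists.

    Fractions apply to *patients* (every record of a patient lands in the
    same split), mirroring a subject-wise 80/10/10 protocol.
    """
    spec = spec or SplitSpec()
    if "patient_id" not in metadata.columns:
        raise ValueError("metadata must carry a patient_id column")
    patients = metadata["patient_id"].astype(str)
    unique = patients.unique()
    if len(unique) < 3:
        raise ValueError(f"need at least 3 patients to form 3 splits, "
                         f"got {len(unique)}")
    rng = np.random.default_rng(spec.seed)
    order = np.array(sorted(unique))
    rng.shuffle(order)
    f_train, f_val, _ = spec.fractions
    n = len(order)
    cut1 = int(round(n * f_train))
    cut2 = int(round(n * (f_train + f_val)))
    cut1 = min(max(cut1, 1), n - 2)
    cut2 = min(max(cut2, cut1 + 1), n - 1)
    groups = (set(order[:cut1]), set(order[cut1:cut2]), set(order[cut2:]))
    return tuple(
        [rid for rid, p in patients.items() if p in g] for g in groups)


# ---------------------------------------------------------------------------
# losses (autodiff graph builders)

def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean multi-task binary cross-entropy, computed stably from logits:
    BCE = softplus(z) - y*z."""
    y = np.asarray(targets, dtype=np.float64)
    return (nn.softplus(logits) - logits * y).mean()


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean four-way cross-entropy from logits (log-sum-exp stabilized)."""
    labels = np.asarray(labels, dtype=int)
    m = logits.data.max(axis=1, keepdims=True)  # constant shift
    lse = nn.log(nn.exp(logits - m).sum(axis=1)) + Tensor(m[:, 0])
    picked = logits[np.arange(len(labels)), labels]
    return (lse - picked).mean()


def mse_loss(outputs: Tensor, values: np.ndarray) -> Tensor:
    y = np.asarray(values, dtype=np.float64).reshape(-1, 1)
    diff = outputs - y
    return (diff * diff).mean()


def build_ablation_head(network: CardioVNet, head: str,
                        seed: int | None = None) -> CardioVNet:
    """Swap the prediction layer for an ablation objective:
    ``classification`` (4 logits, softmax cross-entropy) or ``regression``
    (1 output, squared error against the numeric critical value)."""
    if head not in ("classification", "regression"):
        raise ValueError(f"unknown ablation head {head!r}")
    return network.set_head(head, seed=seed)


# ---------------------------------------------------------------------------

def _loss_and_targets(head: str, phase: int):
    if head == "ordinal" and phase == 2:
        return lambda z, y: bce_with_logits(z, ordinal.encode_cumulative(y))
    if head == "regression":
        return mse_loss
    return softmax_cross_entropy  # classification, or ordinal phase 1


def _predictions_from_logits(head: str, z: np.ndarray):
    if head == "ordinal":
        probs = ordinal.class_probs(ordinal.cumulative_probs(z))
        return ordinal.predict(z), probs
    if head == "classification":
        e = np.exp(z - z.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        return probs.argmax(axis=1), probs
    return z[:, 0], None  # regression: raw continuous output, no probabilities


def head_predictions(network: CardioVNet, x: np.ndarray,
                     batch_size: int = 64):
    """Eval-mode predictions for any head.

    Returns ``(pred, probs)``: integer critical values (continuous for the
    regression head) and per-class probabilities (None for regression).
    """
    z = network.predict_logits(x, batch_size=batch_size)
    return _predictions_from_logits(network.config.head, z)


def _validate(network, x, y, loss_fn) -> tuple[float, float]:
    z = network.predict_logits(x)
    loss = float(loss_fn(Tensor(z), y).data)
    pred, _ = _predictions_from_logits(network.config.head, z)
    mae = float(np.mean(np.abs(np.asarray(pred, dtype=float) - y)))
    return loss, mae


def _run_phase(network, xtr, ytr, xval, yval, config, phase, epochs,
               history, rng):
    loss_fn = _loss_and_targets(config.head, phase)
    opt = nn.Adam(network.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    sched = nn.ReduceLROnPlateau(opt, factor=config.lr_decay_factor,
                                 patience=config.plateau_patience,
                                 min_lr=config.min_lr,
                                 max_reductions=config.max_lr_reductions)
    n = len(xtr)
    for _ in range(epochs):
        network.train()
        order = rng.permutation(n)
        batch_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs more than one sample
            xb = np.asarray(xtr[idx], dtype=network.dtype)
            loss = loss_fn(network.forward(xb), ytr[idx])
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {len(history.epoch) + 1}, "
                    f"lr={opt.lr:g}, phase={phase}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        val_loss, val_mae = _validate(network, xval, yval, loss_fn)
        history.epoch.append(len(history.epoch) + 1)
        history.phase.append(phase)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(val_loss)
        history.val_mae.append(val_mae)
        history.lr.append(opt.lr)
        sched.step(val_loss)
        if sched.should_stop:
            break


def train(network: CardioVNet, train_set, val_set,
          config: TrainConfig | None = None) -> TrainHistory:
    """Fit the network; ``train_set``/``val_set`` are (signals, labels) with
    signals (N, leads, samples) and integer critical-value labels.

    For the ordinal head, phase 1 trains under a temporary 4-way softmax and
    phase 2 under the ordinal objective; the other heads run a single phase
    with the combined epoch budget. Deterministic given ``config.seed`` and
    the network's initialization seed.
    """
    config = config or TrainConfig()
    xtr, ytr = train_set
    xval, yval = val_set
    if len(xtr) == 0:
        raise ValueError("empty training split")
    ytr = np.asarray(ytr)
    yval = np.asarray(yval)
    ss = np.random.SeedSequence(config.seed)
    batch_seed, head_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                             for s in ss.spawn(2))
    rng = np.random.default_rng(batch_seed)
    history = TrainHistory(manifest={
        "train_config": config.__dict__ | {},
        "model_config": network.config.to_dict(),
        "n_train": int(len(xtr)), "n_val": int(len(xval)),
        "batch_seed": batch_seed, "head_seed": head_seed,
    })
    if config.head == "ordinal":
        network.set_head("classification", seed=head_seed)
        _run_phase(network, xtr, ytr, xval, yval, config, 1,
                   config.phase1_epochs, history, rng)
        network.set_head("ordinal", seed=head_seed + 1)
        _run_phase(network, xtr, ytr, xval, yval, config, 2,
                   config.phase2_epochs, history, rng)
    else:
        network.set_head(config.head, seed=head_seed)
        _run_phase(network, xtr, ytr, xval, yval, config, 1,
                   config.phase1_epochs + config.phase2_epochs, history, rng)
    return history
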