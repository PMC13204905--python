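"""Seeded training loop for the hybrid classifier.

Per step: weighted random sampling of a mini-batch -> forward -> weighted
cross-entropy loss -> zero-grads -> backward -> global-norm gradient
clipping -> AdamW step with layer-wise learning rates -> SGDR scheduler
step (per epoch).  Validation weighted F1 is monitored every epoch, early
stopping uses patience P with equality counted as non-improvement, and the
best checkpoint (earliest argmax of validation F1) is restored on stop.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .evaluation import confusion, metrics_from_confusion
from .nn.layers import Param, softmax
from .nn.model import ModelConfig, RTAFNet
from .nn.optim import AdamW, clip_gradients, sgdr_factor
from .preprocess import AF, NONAF, Window

__all__ = [
    "TrainConfig", "TrainHistory",
    "make_class_weights", "wce_loss", "make_sampler",
    "layerwise_param_groups", "sgdr_lr", "early_stopper", "train",
]

CLASSES = (NONAF, AF)  # index 0 = NonAF, index 1 = AF (positive class)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (Algorithm inputs).

    ``lr_multipliers`` maps parameter roles to multiples of ``base_lr``:
    the backbone trains at the base rate, attention modules at 1.5x and the
    classifier head at 2.0x.
    """

    base_lr: float = 5e-4
    lr_multipliers: dict = field(default_factory=lambda: {
        "backbone": 1.0, "attention": 1.5, "classifier": 2.0,
    })
    batch_size: int = 64
    max_epochs: int = 150
    clip_norm: float = 1.0
    patience: int = 20
    sgdr_t0: int = 10
    sgdr_t_mult: int = 2
    sgdr_min_lr: float = 1e-6
    weight_decay: float = 1e-4
    weighted_loss: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.base_lr, self.batch_size, self.max_epochs,
               self.clip_norm, self.patience) <= 0:
            raise ValueError("all training parameters must be positive")


@dataclass
class TrainHistory:
    """Per-epoch trace of the training run."""

    train_loss: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    lrs: list[dict] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def labels_to_index(labels: list[str]) -> np.ndarray:
    return np.array([CLASSES.index(l) for l in labels], dtype=int)


def make_class_weights(labels: list[str]) -> np.ndarray:
    """Inverse-frequency class weights: w_c = N_total / (n_classes * N_c).

    Balanced data gives all-ones; the weights always satisfy
    ``sum_c w_c * N_c = N_total``.
    """
    y = labels_to_index(labels)
    counts = np.bincount(y, minlength=len(CLASSES))
    if (counts == 0).any():
        missing = [CLASSES[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"empty class(es): {missing}")
    return len(y) / (len(CLASSES) * counts.astype(float))


def wce_loss(
    logits: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted cross-entropy, mean over the mini-batch.

    Per sample: ``-w[y] * log softmax(logits)[y]`` via a numerically stable
    log-softmax.  Returns ``(loss, d loss / d logits)``.
    """
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits")
    B = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    wy = w[y]
    loss = float(-(wy * logp[np.arange(B), y]).mean())
    p = np.exp(logp)
    grad = p * wy[:, None]
    grad[np.arange(B), y] -= wy
    return loss, grad / B


def make_sampler(labels: list[str]) -> np.ndarray:
    """Per-sample draw weights proportional to 1/N_class, normalized to sum
    to 1; the expected class composition of a batch is balanced."""
    y = labels_to_index(labels)
    counts = np.bincount(y, minlength=len(CLASSES))
    if (counts[np.unique(y)] == 0).any():
        raise ValueError("empty class")
    w = 1.0 / counts[y]
    return w / w.sum()


def layerwise_param_groups(
    model: RTAFNet, config: TrainConfig
) -> dict[str, dict]:
    """Partition parameters by role into lr-multiplier groups.

    The groups are pairwise disjoint and exhaustive; a parameter whose role
    has no configured multiplier raises (no silent default).
    """
    groups = {
        role: {"params": [], "lr_mult": mult}
        for role, mult in config.lr_multipliers.items()
    }
    for p in model.parameters():
        if p.role not in groups:
            raise ValueError(
                f"parameter {p.name} has untagged role {p.role!r}"
            )
        groups[p.role]["params"].append(p)
    return groups


def sgdr_lr(epoch: float, config: TrainConfig) -> float:
    """SGDR multiplicative factor for the given (0-based) epoch."""
    return sgdr_factor(
        epoch, config.sgdr_t0, config.sgdr_t_mult,
        config.sgdr_min_lr / config.base_lr,
    )


class early_stopper:
    """Stop after ``patience`` consecutive non-improving epochs.

    Equality counts as non-improvement; the best epoch is the earliest
    argmax of the monitored score.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = -1
        self.bad_epochs = 0

    def update(self, score: float, epoch: int) -> bool:
        """Record one epoch's score; returns True when training should stop."""
        if score > self.best:
            self.best = score
            self.best_epoch = epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def _stack(windows: list[Window]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([w.samples for w in windows])
    y = labels_to_index([w.label for w in windows])
    return X, y


def evaluate_f1(model: RTAFNet, windows: list[Window],
                batch_size: int = 256) -> tuple[float, float]:
    """Support-weighted F1 and accuracy of argmax predictions (eval mode)."""
    model.eval()
    X, y = _stack(windows)
    preds = []
    for i in range(0, len(X), batch_size):
        p = model.predict_proba(X[i : i + batch_size])
        preds.append(p.argmax(axis=1))
    yhat = np.concatenate(preds)
    labels = [CLASSES[i] for i in y]
    predictions = [CLASSES[i] for i in yhat]
    rep = metrics_from_confusion(confusion(labels, predictions))
    return rep.weighted["f1"] / 100.0, rep.accuracy / 100.0


def train(
    model: RTAFNet,
    train_windows: list[Window],
    val_windows: list[Window],
    config: TrainConfig = TrainConfig(),
    verbose: bool = False,
) -> TrainHistory:
    """Run the full training algorithm; the model is updated in place and
    left holding the best-validation-F1 checkpoint."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    model.set_rng(rng)

    X, y = _stack(train_windows)
    labels = [w.label for w in train_windows]
    if config.weighted_loss:
        class_w = make_class_weights(labels)
    else:
        class_w = np.ones(len(CLASSES))
    draw_w = make_sampler(labels)

    groups = layerwise_param_groups(model, config)
    opt = AdamW(groups, base_lr=config.base_lr,
                weight_decay=config.weight_decay)
    stopper = early_stopper(config.patience)
    history = TrainHistory()
    best_state = None

    n = len(X)
    steps_per_epoch = max(1, n // config.batch_size)
    for epoch in range(config.max_epochs):
        factor = sgdr_lr(epoch, config)
        model.train(True)
        losses = []
        for _ in range(steps_per_epoch):
            idx = rng.choice(n, size=config.batch_size, p=draw_w)
            logits = model.forward(X[idx])
            loss, g = wce_loss(logits, y[idx], class_w)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch}: {loss}"
                )
            model.zero_grad()
            model.backward(g)
            params = model.parameters()
            pre_norm = clip_gradients(params, config.clip_norm)
            opt.step(factor)
            losses.append(loss)
        val_f1, val_acc = evaluate_f1(model, val_windows)
        history.train_loss.append(float(np.mean(losses)))
        history.val_f1.append(val_f1)
        history.val_accuracy.append(val_acc)
        history.lrs.append(opt.group_lrs(factor))
        history.grad_norms.append(pre_norm)
        if verbose:
            print(
                f"epoch {epoch:3d} loss {history.train_loss[-1]:.4f} "
                f"val F1 {val_f1:.4f}"
            )
        if val_f1 > stopper.best:
            best_state = copy.deepcopy(model.state_dict())
        if stopper.update(val_f1, epoch):
            history.stopped_early = True
            break
    history.best_epoch = stopper.best_epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return history
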