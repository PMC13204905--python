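"""AdamW optimizer with parameter groups, cosine-annealing warm restarts
(SGDR) scheduling, and global-norm gradient clipping."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["AdamW", "sgdr_factor", "clip_gradients", "global_grad_norm"]


def global_grad_norm(params: list[Param]) -> float:
    sq = sum(float(np.sum(p.grad * p.grad)) for p in params)
    return float(np.sqrt(sq))


def clip_gradients(params: list[Param], max_norm: float) -> float:
    """Scale all gradients by max_norm/||g|| when the global L2 norm
    exceeds ``max_norm``; returns the pre-clip norm.  Direction-preserving
    (a single scalar rescale)."""
    if max_norm <= 0:
        raise ValueError("max_norm must be positive")
    norm = global_grad_norm(params)
    if norm > max_norm:
        scale = max_norm / norm
        for p in params:
            p.grad *= scale
    return norm


def sgdr_factor(epoch: float, t0: int = 10, t_mult: int = 2,
                min_factor: float = 0.0) -> float:
    """Multiplicative learning-rate factor of the SGDR schedule.

    Cosine annealing from 1 to ``min_factor`` over each cycle; cycle k has
    length ``t0 * t_mult**k`` and the factor resets to 1 at each restart.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    t, length = float(epoch), float(t0)
    while t >= length:
        t -= length
        length *= t_mult
    cos = 0.5 * (1.0 + np.cos(np.pi * t / length))
    return float(min_factor + (1.0 - min_factor) * cos)


class AdamW:
    """Decoupled-weight-decay Adam over role-tagged parameter groups.

    ``groups`` maps a role name to ``{"params": [...], "lr_mult": m}``; the
    effective step size of a group is ``base_lr * lr_mult * schedule_factor``.
    Weight decay is skipped for parameters flagged ``decay=False``
    (biases, normalization scales/offsets).
    """

    def __init__(self, groups: dict[str, dict], base_lr: float = 5e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.groups = groups
        self.base_lr = base_lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {}
        self._v = {}
        for g in groups.values():
            for p in g["params"]:
                self._m[id(p)] = np.zeros_like(p.data)
                self._v[id(p)] = np.zeros_like(p.data)

    def group_lrs(self, factor: float = 1.0) -> dict[str, float]:
        return {
            name: self.base_lr * g["lr_mult"] * factor
            for name, g in self.groups.items()
        }

    def step(self, factor: float = 1.0) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for g in self.groups.values():
            lr = self.base_lr * g["lr_mult"] * factor
            for p in g["params"]:
                m, v = self._m[id(p)], self._v[id(p)]
                m += (1 - self.b1) * (p.grad - m)
                v += (1 - self.b2) * (p.grad * p.grad - v)
                mhat = m / bc1
                vhat = v / bc2
                if self.weight_decay and p.decay:
                    p.data -= lr * self.weight_decay * p.data
                p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
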