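"""The hybrid residual-CNN/Transformer AF classifier.

Architecture: a strided 1-D convolutional stem, four stages of residual
blocks (conv-BN-GELU-conv-BN plus an identity or 1x1 projected shortcut,
GELU after the addition), lightweight self-attention blocks appended to
stages 2 and 3, a sinusoidal-positional-encoding + post-norm Transformer
encoder over the downsampled feature sequence, global max+average pooling
fusion, and a two-layer fully connected classifier with softmax output.

The reference configuration maps a 4000-sample (10 s at 400 Hz) window to a
250 x 512 feature sequence (total stride 16), fuses it into a 1024-vector,
and classifies through 1024 -> 256 -> 2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np

from .layers import (
    Module, Sequential, Conv1d, BatchNorm, Linear, LayerNorm, GELU, ReLU,
    Dropout, MultiHeadSelfAttention, PositionalEncoding, MaxAvgFuse, softmax,
)

__all__ = ["ModelConfig", "RTAFNet", "reference_config", "count_flops"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``stages`` entries are ``(num_blocks, out_channels, stride)``; the last
    stage's channel width must equal ``d_model``.  ``attention_stages`` are
    1-based stage indices that receive an in-backbone self-attention block.
    ``variant`` selects the ablation wiring: ``full``, ``resnet_only``
    (encoder bypassed), ``transformer_only`` (stem + encoder only) or
    ``no_fusion`` (average pooling only).
    """

    stem_kernel: int = 15
    stem_stride: int = 2
    stem_channels: int = 64
    stages: tuple[tuple[int, int, int], ...] = (
        (2, 64, 2), (2, 128, 2), (2, 256, 2), (2, 512, 1),
    )
    attention_stages: frozenset[int] = frozenset({2, 3})
    block_kernel: int = 7
    block_attention_heads: int = 4
    d_model: int = 512
    encoder_layers: int = 3
    num_heads: int = 8
    ffn_dim: int = 1474
    dropout: float = 0.3
    classifier_hidden: int = 256
    n_classes: int = 2
    input_length: int = 4000
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.d_model % self.num_heads:
            raise ValueError("d_model must be divisible by num_heads")
        if self.variant not in (
            "full", "resnet_only", "transformer_only", "no_fusion"
        ):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant != "transformer_only":
            if self.stages[-1][1] != self.d_model:
                raise ValueError("last stage width must equal d_model")
        if self.input_length % self.total_stride:
            raise ValueError("total stride must divide input_length")

    @property
    def total_stride(self) -> int:
        # the transformer_only variant keeps the same L': its stem performs
        # the whole downsampling in one strided convolution
        s = self.stem_stride
        for _, _, st in self.stages:
            s *= st
        return s

    @property
    def seq_len(self) -> int:
        """Feature-sequence length after backbone downsampling (L')."""
        return self.input_length // self.total_stride

    @property
    def d_k(self) -> int:
        return self.d_model // self.num_heads

    @property
    def fused_dim(self) -> int:
        return self.d_model if self.variant == "no_fusion" else 2 * self.d_model

    def to_dict(self) -> dict:
        d = asdict(self)
        d["attention_stages"] = sorted(self.attention_stages)
        d["stages"] = [list(s) for s in self.stages]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["attention_stages"] = frozenset(d["attention_stages"])
        d["stages"] = tuple(tuple(s) for s in d["stages"])
        return cls(**d)

    def for_variant(self, variant: str) -> "ModelConfig":
        return replace(self, variant=variant)


def reference_config() -> ModelConfig:
    """The frozen reference architecture: L'=250, D=512, classifier
    1024->256->2, attention blocks in stages 2-3, 17.02 M parameters."""
    return ModelConfig()


class ResidualBlock(Module):
    """conv-BN-GELU-conv-BN + shortcut; GELU applied after the addition.

    The shortcut is the identity when input and output shapes match and a
    strided 1x1 projection (conv + BN) otherwise.
    """

    def __init__(self, c_in, c_out, stride, kernel, rng, name, dtype=np.float64):
        super().__init__()
        self.conv1 = self.register(
            Conv1d(c_in, c_out, kernel, stride, rng, f"{name}.conv1", dtype=dtype)
        )
        self.bn1 = self.register(BatchNorm(c_out, name=f"{name}.bn1", dtype=dtype))
        self.act1 = self.register(GELU())
        self.conv2 = self.register(
            Conv1d(c_out, c_out, kernel, 1, rng, f"{name}.conv2", dtype=dtype)
        )
        self.bn2 = self.register(BatchNorm(c_out, name=f"{name}.bn2", dtype=dtype))
        self.proj = None
        self.proj_bn = None
        if stride != 1 or c_in != c_out:
            self.proj = self.register(
                Conv1d(c_in, c_out, 1, stride, rng, f"{name}.proj", dtype=dtype)
            )
            self.proj_bn = self.register(BatchNorm(c_out, name=f"{name}.projbn", dtype=dtype))
        self.act_out = self.register(GELU())

    def forward(self, x):
        y = self.bn2.forward(
            self.conv2.forward(
                self.act1.forward(self.bn1.forward(self.conv1.forward(x)))
            )
        )
        sc = x if self.proj is None else self.proj_bn.forward(self.proj.forward(x))
        return self.act_out.forward(y + sc)

    def backward(self, g):
        g = self.act_out.backward(g)
        g_main = self.conv1.backward(
            self.bn1.backward(
                self.act1.backward(
                    self.conv2.backward(self.bn2.backward(g))
                )
            )
        )
        if self.proj is None:
            return g_main + g
        return g_main + self.proj.backward(self.proj_bn.backward(g))


class AttentionBlock(Module):
    """Lightweight in-backbone self-attention: LN -> MHSA -> residual add."""

    def __init__(self, c, heads, rng, name, dtype=np.float64):
        super().__init__()
        self.ln = self.register(LayerNorm(c, name=f"{name}.ln", dtype=dtype))
        self.attn = self.register(
            MultiHeadSelfAttention(c, heads, rng, name=f"{name}.attn", dtype=dtype)
        )

    def forward(self, x):
        return x + self.attn.forward(self.ln.forward(x))

    def backward(self, g):
        return g + self.ln.backward(self.attn.backward(g))


class EncoderLayer(Module):
    """Post-norm Transformer encoder layer: MHSA and FFN sub-layers, each
    wrapped in residual connection + layer normalization."""

    def __init__(self, d, heads, ffn_dim, dropout, rng, name, dtype=np.float64):
        super().__init__()
        self.attn = self.register(
            MultiHeadSelfAttention(d, heads, rng, name=f"{name}.mhsa", dtype=dtype)
        )
        self.drop1 = self.register(Dropout(dropout))
        self.ln1 = self.register(LayerNorm(d, name=f"{name}.ln1", dtype=dtype))
        self.ff1 = self.register(
            Linear(d, ffn_dim, rng, f"{name}.ff1", role="attention", dtype=dtype)
        )
        self.ff_act = self.register(ReLU())
        self.ff2 = self.register(
            Linear(ffn_dim, d, rng, f"{name}.ff2", role="attention", dtype=dtype)
        )
        self.drop2 = self.register(Dropout(dropout))
        self.ln2 = self.register(LayerNorm(d, name=f"{name}.ln2", dtype=dtype))

    def forward(self, x):
        x = self.ln1.forward(x + self.drop1.forward(self.attn.forward(x)))
        y = self.ff2.forward(self.ff_act.forward(self.ff1.forward(x)))
        return self.ln2.forward(x + self.drop2.forward(y))

    def backward(self, g):
        g = self.ln2.backward(g)
        g_ff = self.ff1.backward(
            self.ff_act.backward(self.ff2.backward(self.drop2.backward(g)))
        )
        g = g + g_ff
        g = self.ln1.backward(g)
        g_attn = self.attn.backward(self.drop1.backward(g))
        return g + g_attn


class RTAFNet(Module):
    """The full classifier as a configurable forward/backward graph."""

    def __init__(self, config: ModelConfig, init_seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(init_seed)

        if config.variant == "transformer_only":
            # stem alone performs the whole downsampling and lifts the raw
            # signal to d_model channels; the residual stages are bypassed
            self.stem = self.register(Sequential(
                Conv1d(1, config.d_model, config.stem_kernel,
                       config.total_stride, rng, "stem.conv", dtype=dtype),
                BatchNorm(config.d_model, name="stem.bn", dtype=dtype),
                GELU(),
            ))
            self.stages: list[Sequential] = []
        else:
            self.stem = self.register(Sequential(
                Conv1d(1, config.stem_channels, config.stem_kernel,
                       config.stem_stride, rng, "stem.conv", dtype=dtype),
                BatchNorm(config.stem_channels, name="stem.bn", dtype=dtype),
                GELU(),
            ))
            self.stages = []
            c_in = config.stem_channels
            for si, (n_blocks, c_out, stride) in enumerate(config.stages, 1):
                layers: list[Module] = []
                for bi in range(n_blocks):
                    layers.append(ResidualBlock(
                        c_in, c_out, stride if bi == 0 else 1,
                        config.block_kernel, rng, f"stage{si}.block{bi}",
                        dtype=dtype,
                    ))
                    c_in = c_out
                if si in config.attention_stages:
                    layers.append(AttentionBlock(
                        c_out, config.block_attention_heads, rng,
                        f"stage{si}.attnblk", dtype=dtype,
                    ))
                self.stages.append(self.register(Sequential(*layers)))

        self.use_encoder = config.variant != "resnet_only"
        if self.use_encoder:
            self.posenc = self.register(
                PositionalEncoding(config.d_model, config.seq_len, dtype=dtype)
            )
            self.encoder = self.register(Sequential(*[
                EncoderLayer(config.d_model, config.num_heads, config.ffn_dim,
                             config.dropout, rng, f"enc{i}", dtype=dtype)
                for i in range(config.encoder_layers)
            ]))
        self.fuse = self.register(MaxAvgFuse(
            "avg" if config.variant == "no_fusion" else "maxavg"
        ))
        self.head = self.register(Sequential(
            Linear(config.fused_dim, config.classifier_hidden, rng, "head.fc1",
                   dtype=dtype),
            ReLU(),
            Dropout(config.dropout),
            Linear(config.classifier_hidden, config.n_classes, rng, "head.fc2",
                   dtype=dtype),
        ))

    # ------------------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim == 3 and x.shape[1] == 1:  # (B, 1, L) channel-first
            x = x[:, 0, :]
        if x.ndim != 2 or x.shape[1] != self.config.input_length:
            raise ValueError(
                f"expected input of length {self.config.input_length}, "
                f"got shape {x.shape}"
            )
        return x[:, :, None]  # (B, L, 1)

    def backbone(self, x: np.ndarray) -> np.ndarray:
        """Raw windows (B, L) -> feature sequence (B, L', D)."""
        h = self.stem.forward(self._check_input(x))
        for st in self.stages:
            h = st.forward(h)
        return h

    def features(self, x: np.ndarray) -> np.ndarray:
        """Fused feature vector (B, fused_dim) before the classifier head."""
        h = self.backbone(x)
        if self.use_encoder:
            h = self.encoder.forward(self.posenc.forward(h))
        return self.fuse.forward(h)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (B, n_classes)."""
        return self.head.forward(self.features(x))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x), axis=-1)

    def backward(self, g_logits: np.ndarray) -> np.ndarray:
        g = self.head.backward(g_logits)
        g = self.fuse.backward(g)
        if self.use_encoder:
            g = self.posenc.backward(self.encoder.backward(g))
        for st in reversed(self.stages):
            g = st.backward(g)
        g = self.stem.backward(g)
        return g[:, :, 0]

    def count_parameters(self) -> int:
        """Total number of trainable scalar parameters."""
        return self.n_parameters()


def count_flops(config: ModelConfig, n: int | None = None) -> dict[str, float]:
    """Closed-form per-module FLOP estimate for one input window.

    Convention: 1 multiply-accumulate = 2 FLOPs.  Convolution terms are
    linear in the input length ``n``; the attention terms scale with
    L'^2 * D where L' = n / total_stride; pooling and classifier terms are
    independent of ``n``.
    """
    n = n or config.input_length
    flops = {"backbone": 0.0, "attention": 0.0, "encoder": 0.0,
             "pooling": 0.0, "classifier": 0.0}

    def conv(c_in, c_out, k, L_out):
        return 2.0 * k * c_in * c_out * L_out

    def mhsa(L, d):
        # QKV + output projections and the two attention matmuls
        return 2.0 * (4 * d * d * L) + 2.0 * (2 * L * L * d)

    L = -(-n // config.stem_stride)
    if config.variant == "transformer_only":
        L = -(-n // config.total_stride)
        flops["backbone"] += conv(1, config.d_model, config.stem_kernel, L)
    else:
        flops["backbone"] += conv(1, config.stem_channels, config.stem_kernel, L)
        c_in = config.stem_channels
        for si, (n_blocks, c_out, stride) in enumerate(config.stages, 1):
            for bi in range(n_blocks):
                s = stride if bi == 0 else 1
                L_out = -(-L // s)
                flops["backbone"] += conv(c_in, c_out, config.block_kernel, L_out)
                flops["backbone"] += conv(c_out, c_out, config.block_kernel, L_out)
                if s != 1 or c_in != c_out:
                    flops["backbone"] += conv(c_in, c_out, 1, L_out)
                c_in, L = c_out, L_out
            if si in config.attention_stages:
                flops["attention"] += mhsa(L, c_out)
    if config.variant != "resnet_only":
        d, F = config.d_model, config.ffn_dim
        per_layer = mhsa(L, d) + 2.0 * (2 * d * F * L)
        flops["encoder"] = config.encoder_layers * per_layer
    flops["pooling"] = 2.0 * config.d_model * config.seq_len
    h = config.classifier_hidden
    flops["classifier"] = 2.0 * (config.fused_dim * h + h * config.n_classes)
    flops["total"] = sum(flops.values())
    return flops
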