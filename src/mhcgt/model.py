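"""The MHCgT network: a transformer encoder for spectral sequences.

A reflectance spectrum is treated as a univariate sequence of S=125 band
steps. The pipeline is: add a fixed sinusoidal positional encoding; pass
through ``num_blocks`` pre-norm encoder blocks (layer normalization →
multi-head self-attention → dropout → residual, then layer normalization →
width-1 convolution to ``ff_dim`` with ReLU → dropout → width-1 convolution
back → residual); global-average-pool over the feature axis to a length-S
vector; and classify with a two-layer MLP head under softmax.

With the default configuration (8 heads, per-head key dimension 256,
ff_dim 64, 4 blocks, mlp_units 125, 7 classes) the network has exactly
74,768 trainable parameters; ``closed_form_parameter_count`` states the
count symbolically and ``count_parameters`` counts the built tensors.

Univariate note: with M=1 variables per step, feature-axis layer
normalization maps every position to its bias exactly, so the attention and
feed-forward sub-layers contribute position-constant offsets. The encoder
therefore admits an exact algebraic fast path (compute each sub-layer's
constant once instead of at all B·S positions) which is used by default for
M=1; the general path is retained and the two are identical to floating-
point roundoff (see tests).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat, relu, softmax

__all__ = [
    "ModelConfig",
    "positional_encoding",
    "scaled_dot_product_attention",
    "MultiHeadSelfAttention",
    "multi_head_self_attention",
    "EncoderBlock",
    "MHCgT",
    "build_model",
    "count_parameters",
    "closed_form_parameter_count",
    "save_model",
    "load_model",
]

_LN_EPS = 1e-6


@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters; defaults define the 74,768-parameter
    network (8 heads of key dimension 256, ff width 64, 4 blocks, 125-unit
    MLP head, dropout 0.25 in the encoder and 0.4 in the head)."""

    num_heads: int = 8
    key_dim: int = 256
    ff_dim: int = 64
    num_blocks: int = 4
    mlp_units: int = 125
    mlp_dropout: float = 0.4
    dropout: float = 0.25
    num_classes: int = 7
    seq_len: int = 125
    num_vars: int = 1

    def __post_init__(self):
        for name in ("num_heads", "key_dim", "ff_dim", "mlp_units", "seq_len", "num_vars"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.num_blocks < 0:
            raise ValueError("num_blocks must be >= 0")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        for name in ("mlp_dropout", "dropout"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


def positional_encoding(S: int, M: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding of shape (S, M).

    PE(pos, 2i) = sin(pos / 10000^(2i/M)), PE(pos, 2i+1) = cos(...); for
    M=1 this reduces to sin(pos). Contains no trainable values; entries lie
    in [-1, 1].
    """
    if S < 1 or M < 1:
        raise ValueError(f"dimensions must be positive, got S={S}, M={M}")
    pos = np.arange(S, dtype=np.float64)[:, None]
    pe = np.empty((S, M))
    i = np.arange(0, M, 2, dtype=np.float64)
    angles = pos / np.power(10000.0, i / M)
    pe[:, 0::2] = np.sin(angles)
    if M > 1:
        pe[:, 1::2] = np.cos(angles[:, : M // 2])
    return pe


def scaled_dot_product_attention(Q, K, V):
    """softmax(Q Kᵀ / sqrt(D_k)) V.

    Q, K, V: (..., S, D_k) arrays or Tensors sharing row count and width.
    Returns (output, weights); every weight row is a probability vector.
    """
    Q, K, V = as_tensor(Q), as_tensor(K), as_tensor(V)
    for name, t in (("K", K), ("V", V)):
        if t.shape != Q.shape:
            raise ValueError(
                f"operand {name} has shape {t.shape}, expected {Q.shape} (same as Q)"
            )
    d_k = Q.shape[-1]
    scores = (Q @ K.swapaxes(-1, -2)) / np.sqrt(d_k)
    weights = softmax(scores, axis=-1)
    return weights @ V, weights


def _he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def _param(rng, fan_in, shape) -> Tensor:
    return Tensor(_he_uniform(rng, fan_in, shape), requires_grad=True)


def _zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class _Dropout:
    """Inverted dropout; identity when inactive or rate 0."""

    def __init__(self, rate: float):
        self.rate = rate

    def __call__(self, x: Tensor, shape, active: bool, rng) -> Tensor:
        if not active or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("dropout needs an rng when active")
        mask = (rng.random(shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class _LayerNorm:
    """Feature-axis layer normalization with gain/bias, epsilon 1e-6."""

    def __init__(self, width: int):
        self.gamma = Tensor(np.ones(width), requires_grad=True)
        self.beta = _zeros(width)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        d = x - mu
        var = (d * d).mean(axis=-1, keepdims=True)
        return d * (var + _LN_EPS) ** -0.5 * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class MultiHeadSelfAttention:
    """n parallel scaled-dot-product heads on learned Q/K/V projections,
    concatenated and mapped back to the input width by W° (all with bias)."""

    def __init__(self, num_heads: int, num_vars: int, key_dim: int, rng):
        self.num_heads, self.num_vars, self.key_dim = num_heads, num_vars, key_dim
        m, d = num_vars, key_dim
        self.w_q = [_param(rng, m, (m, d)) for _ in range(num_heads)]
        self.b_q = [_zeros(d) for _ in range(num_heads)]
        self.w_k = [_param(rng, m, (m, d)) for _ in range(num_heads)]
        self.b_k = [_zeros(d) for _ in range(num_heads)]
        self.w_v = [_param(rng, m, (m, d)) for _ in range(num_heads)]
        self.b_v = [_zeros(d) for _ in range(num_heads)]
        self.w_o = _param(rng, num_heads * d, (num_heads * d, m))
        self.b_o = _zeros(m)

    def __call__(self, x, return_weights: bool = False):
        """General path: x (..., S, M) → (..., S, M)."""
        x = as_tensor(x)
        if x.shape[-1] != self.num_vars:
            raise ValueError(
                f"input width {x.shape[-1]} does not match num_vars={self.num_vars}"
            )
        heads, weights = [], []
        for i in range(self.num_heads):
            q = x @ self.w_q[i] + self.b_q[i]
            k = x @ self.w_k[i] + self.b_k[i]
            v = x @ self.w_v[i] + self.b_v[i]
            out, w = scaled_dot_product_attention(q, k, v)
            heads.append(out)
            weights.append(w)
        out = concat(heads, axis=-1) @ self.w_o + self.b_o
        return (out, weights) if return_weights else out

    def constant_output(self, point: Tensor) -> Tensor:
        """Output row when every sequence position equals ``point`` (1, M).

        With identical rows, each head's attention weights are uniform and
        every output row equals the projected value vector, so the whole
        module reduces to a single-position evaluation.
        """
        heads = [point @ self.w_v[i] + self.b_v[i] for i in range(self.num_heads)]
        return concat(heads, axis=-1) @ self.w_o + self.b_o

    def parameters(self):
        out = []
        for i in range(self.num_heads):
            out += [self.w_q[i], self.b_q[i], self.w_k[i], self.b_k[i],
                    self.w_v[i], self.b_v[i]]
        out += [self.w_o, self.b_o]
        return out


def multi_head_self_attention(x, params: MultiHeadSelfAttention) -> Tensor:
    """Functional wrapper over :class:`MultiHeadSelfAttention` (general path)."""
    return params(x)


class EncoderBlock:
    """Pre-norm transformer encoder block with width-1 convolutional
    feed-forward (two pointwise convolutions with an inner ReLU)."""

    def __init__(self, cfg: ModelConfig, rng):
        m, ff = cfg.num_vars, cfg.ff_dim
        self.cfg = cfg
        self.ln1 = _LayerNorm(m)
        self.attn = MultiHeadSelfAttention(cfg.num_heads, m, cfg.key_dim, rng)
        self.ln2 = _LayerNorm(m)
        self.w_ff1 = _param(rng, m, (m, ff))
        self.b_ff1 = _zeros(ff)
        self.w_ff2 = _param(rng, ff, (ff, m))
        self.b_ff2 = _zeros(m)
        self.drop = _Dropout(cfg.dropout)

    def __call__(self, x, dropout_active: bool = False, rng=None,
                 fast: bool | None = None) -> Tensor:
        x = as_tensor(x)
        if not np.all(np.isfinite(x.data)):
            raise ValueError("encoder block received non-finite input")
        squeeze = x.ndim == 2
        if squeeze:
            x = x.reshape(1, *x.shape)
        if fast is None:
            fast = self.cfg.num_vars == 1
        b, s, m = x.shape

        if fast and m == 1:
            # Feature-axis LN with one feature returns its bias at every
            # position, so both sub-layers add position-constant offsets;
            # evaluate each constant once and broadcast.
            beta1 = self.ln1.beta.reshape(1, 1)
            attn_const = self.attn.constant_output(beta1).reshape(1, 1, m)
            x = x + self.drop(attn_const, (b, s, m), dropout_active, rng)
            beta2 = self.ln2.beta.reshape(1, 1)
            h = relu(beta2 @ self.w_ff1 + self.b_ff1).reshape(1, 1, self.cfg.ff_dim)
            h = self.drop(h, (b, s, self.cfg.ff_dim), dropout_active, rng)
            x = x + (h @ self.w_ff2 + self.b_ff2)
        else:
            a = self.attn(self.ln1(x))
            x = x + self.drop(a, (b, s, m), dropout_active, rng)
            h = relu(self.ln2(x) @ self.w_ff1 + self.b_ff1)
            h = self.drop(h, (b, s, self.cfg.ff_dim), dropout_active, rng)
            x = x + (h @ self.w_ff2 + self.b_ff2)
        return x.reshape(s, m) if squeeze else x

    def parameters(self):
        return (
            self.ln1.parameters() + self.attn.parameters() + self.ln2.parameters()
            + [self.w_ff1, self.b_ff1, self.w_ff2, self.b_ff2]
        )


class MHCgT:
    """The full classifier; build with :func:`build_model`."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.pe = positional_encoding(cfg.seq_len, cfg.num_vars)
        self.blocks = [EncoderBlock(cfg, rng) for _ in range(cfg.num_blocks)]
        self.w_mlp = _param(rng, cfg.seq_len, (cfg.seq_len, cfg.mlp_units))
        self.b_mlp = _zeros(cfg.mlp_units)
        self.w_out = _param(rng, cfg.mlp_units, (cfg.mlp_units, cfg.num_classes))
        self.b_out = _zeros(cfg.num_classes)
        self.head_drop = _Dropout(cfg.mlp_dropout)
        self.use_positional_encoding = True  # disable only for diagnostics

    def encode(self, x, training: bool = False, rng=None,
               add_positional: bool | None = None) -> Tensor:
        """Positional encoding + encoder stack; x (B, S, M) → (B, S, M)."""
        x = as_tensor(x)
        if x.shape[-2:] != (self.cfg.seq_len, self.cfg.num_vars):
            raise ValueError(
                f"input shape {x.shape} does not match (S, M)="
                f"({self.cfg.seq_len}, {self.cfg.num_vars})"
            )
        if add_positional is None:
            add_positional = self.use_positional_encoding
        if add_positional:
            x = x + Tensor(self.pe)
        for block in self.blocks:
            x = block(x, dropout_active=training, rng=rng)
        return x

    def forward(self, x, training: bool = False, rng=None) -> Tensor:
        """Logits (B, num_classes)."""
        x = as_tensor(x)
        single = x.ndim == 2
        if single:
            x = x.reshape(1, *x.shape)
        h = self.encode(x, training=training, rng=rng)
        pooled = h.mean(axis=-1)  # GAP over the feature axis → (B, S)
        z = relu(pooled @ self.w_mlp + self.b_mlp)
        z = self.head_drop(z, z.shape, training, rng)
        logits = z @ self.w_out + self.b_out
        return logits.reshape(self.cfg.num_classes) if single else logits

    def predict_proba(self, x) -> np.ndarray:
        """Class probabilities under softmax (rows sum to 1)."""
        logits = self.forward(x, training=False)
        return softmax(logits, axis=-1).numpy()

    def predict(self, x) -> np.ndarray:
        """Predicted species labels (1-based)."""
        p = self.predict_proba(np.asarray(x))
        return np.argmax(np.atleast_2d(p), axis=-1) + 1

    def parameters(self):
        out = []
        for block in self.blocks:
            out += block.parameters()
        out += [self.w_mlp, self.b_mlp, self.w_out, self.b_out]
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter p{i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.astype(np.float64).copy()


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> MHCgT:
    """Construct the network with seeded He-uniform initialization."""
    return MHCgT(cfg or ModelConfig(), seed=seed)


def count_parameters(model: MHCgT) -> int:
    """Number of trainable scalar parameters in the built model."""
    return int(sum(p.size for p in model.parameters()))


def closed_form_parameter_count(cfg: ModelConfig) -> int:
    """Symbolic parameter count of the architecture.

    Per block: n heads × 3 projections of (M·D_k weights + D_k biases), the
    output map (n·D_k·M + M), two layer norms (2M each), and the two
    pointwise convolutions (M·ff + ff) + (ff·M + M). Head: (S·mlp + mlp) +
    (mlp·C + C); the positional encoding is fixed and contributes nothing.
    """
    n, d, m = cfg.num_heads, cfg.key_dim, cfg.num_vars
    ff, s, c, u = cfg.ff_dim, cfg.seq_len, cfg.num_classes, cfg.mlp_units
    per_block = (
        n * 3 * (m * d + d)
        + (n * d * m + m)
        + 2 * (2 * m)
        + (m * ff + ff)
        + (ff * m + m)
    )
    head = s * u + u + u * c + c
    return cfg.num_blocks * per_block + head


def save_model(model: MHCgT, directory: str) -> None:
    """Checkpoint: parameter arrays (.npz) + JSON sidecar with config/seed."""
    os.makedirs(directory, exist_ok=True)
    np.savez(os.path.join(directory, "weights.npz"), **model.state_dict())
    with open(os.path.join(directory, "model.json"), "w") as f:
        json.dump({"config": asdict(model.cfg), "seed": model.seed}, f, indent=2)


def load_model(directory: str) -> MHCgT:
    with open(os.path.join(directory, "model.json")) as f:
        meta = json.load(f)
    model = MHCgT(ModelConfig(**meta["config"]), seed=meta["seed"])
    with np.load(os.path.join(directory, "weights.npz")) as state:
        model.load_state_dict({k: state[k] for k in state.files})
    return model
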