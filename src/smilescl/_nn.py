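"""Transformer building blocks and the AdamW optimizer, on the autodiff core.

Conventions: pre-norm residual blocks, GELU (tanh approximation) feed-forward
of width 4*d_model, fixed sinusoidal positional encodings, and key-side
attention masking so padded positions are never attended to.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, softmax, take_rows

NEG_INF = -1e9


class Module:
    """Base class: tracks named parameters of nested sub-modules."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, d_in ** -0.5, size=(d_in, d_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class EmbeddingTable(Module):
    def __init__(self, n_tokens: int, d_model: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, d_model ** -0.5,
                                        size=(n_tokens, d_model)),
                             requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return take_rows(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layernorm(self.eps) * self.gamma + self.beta


def gelu(x: Tensor) -> Tensor:
    # tanh approximation, fused forward/backward
    return x.gelu()


def sinusoidal_positions(max_len: int, d_model: int) -> np.ndarray:
    """Fixed sinusoidal positional-encoding matrix of shape (max_len, d_model)."""
    pos = np.arange(max_len)[:, None].astype(np.float64)
    i = np.arange(d_model // 2)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.zeros((max_len, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def dropout(x: Tensor, p: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    if not training or p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(keep)


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, key_bias: np.ndarray) -> Tensor:
        """x: (B, L, d). key_bias: (B, 1, 1, L) additive mask, 0 or NEG_INF."""
        B, L, d = x.shape
        h, dh = self.n_heads, self.d_head

        def heads(t: Tensor) -> Tensor:  # (B, L, d) -> (B, h, L, dh)
            return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

        q, k, v = heads(self.wq(x)), heads(self.wk(x)), heads(self.wv(x))
        scores = q @ k.transpose(0, 1, 3, 2) * (dh ** -0.5)  # (B, h, L, L)
        attn = softmax(scores + Tensor(key_bias), axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.wo(ctx)


class EncoderBlock(Module):
    """Pre-norm transformer block: LN->MHA->residual, LN->FF->residual."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 p_drop: float = 0.1):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, 4 * d_model, rng)
        self.ff2 = Linear(4 * d_model, d_model, rng)
        self.p_drop = p_drop

    def __call__(self, x: Tensor, key_bias: np.ndarray,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        a = self.attn(self.ln1(x), key_bias)
        x = x + dropout(a, self.p_drop, rng, training)
        f = self.ff2(gelu(self.ff1(self.ln2(x))))
        return x + dropout(f, self.p_drop, rng, training)


class AdamW:
    """Decoupled weight-decay Adam (Loshchilov & Hutter defaults)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                         + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
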