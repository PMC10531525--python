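"""Neural-network building blocks: modules, layers, initializers, Adam.

Everything here is batched numpy running on the :mod:`dtifusion.autodiff`
tape. Attention masks are plain ``{0,1}`` float arrays; masked positions
receive a large negative additive bias before softmax so their weights
are numerically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat

NEG_INF = 1.0e9


@dataclass
class TrainContext:
    """Per-forward state: RNG for dropout masks and the train/eval switch."""

    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))
    training: bool = False

    @staticmethod
    def eval() -> "TrainContext":
        return TrainContext(training=False)


def xavier_uniform(shape: tuple[int, ...], rng: np.random.Generator, dtype=np.float64) -> np.ndarray:
    """Glorot/Xavier uniform initialization for a 2-D weight."""
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Module:
    """Container base class; collects parameters recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            params.extend(_collect(value, seen))
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def post_step(self) -> None:
        """Hook run after each optimizer step (e.g. re-zero pad rows)."""
        for value in self.__dict__.values():
            for mod in _collect_modules(value):
                mod.post_step()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _collect(value, seen: set[int]) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        if id(value) in seen:
            return []
        seen.add(id(value))
        return [value]
    if isinstance(value, Module):
        out = []
        for v in value.__dict__.values():
            out.extend(_collect(v, seen))
        return out
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v, seen))
        return out
    return []


def _collect_modules(value) -> list["Module"]:
    if isinstance(value, Module):
        return [value]
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect_modules(v))
        return out
    return []


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float64):
        self.weight = Tensor(xavier_uniform((d_in, d_out), rng, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Embedding(Module):
    """Token embedding with a zero, update-frozen padding row (id 0)."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator,
                 dtype=np.float64, init: np.ndarray | None = None):
        if init is not None:
            w = np.array(init, dtype=dtype, copy=True)
            if w.shape != (n_tokens, dim):
                raise ValueError(f"init shape {w.shape} != ({n_tokens}, {dim})")
        else:
            w = (rng.standard_normal((n_tokens, dim)) * 0.1).astype(dtype)
        w[0] = 0.0
        self.weight = Tensor(w, requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        from .autodiff import embedding_lookup

        return embedding_lookup(self.weight, indices)

    def post_step(self) -> None:
        self.weight.data[0] = 0.0


class LayerNorm(Module):
    """Post-activation layer normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-6, dtype=np.float64):
        self.gain = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.offset = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.gain + self.offset

    def normalized(self, x: Tensor) -> Tensor:
        """Pre-gain/offset normalization (exposed for invariant checks)."""
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5


class Dropout(Module):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, ctx: TrainContext) -> Tensor:
        if not ctx.training or self.p == 0.0:
            return x
        keep = (ctx.rng.random(x.shape) >= self.p).astype(x.data.dtype)
        return x * (keep / (1.0 - self.p))


def masked_softmax(scores: Tensor, key_mask: np.ndarray | None, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` with masked keys forced to zero weight.

    ``key_mask`` broadcasts against ``scores`` (1 = real, 0 = padding).
    """
    if key_mask is None:
        return scores.softmax(axis=axis)
    bias = (np.asarray(key_mask, dtype=scores.data.dtype) - 1.0) * NEG_INF
    return scores.softmax(axis=axis, additive_bias=bias)


def masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over axis 1 counting only positions with mask 1.

    x: (B, L, D), mask: (B, L) -> (B, D).
    """
    m = np.asarray(mask, dtype=x.data.dtype)
    denom = m.sum(axis=1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("masked_mean: some rows have no unmasked position")
    weighted = x * m[:, :, None]
    return weighted.sum(axis=1) * (1.0 / denom)


class MultiHeadAttention(Module):
    """Scaled dot-product attention, self- or cross-, with key masking.

    Queries, keys and values are linear projections split into
    ``n_heads`` subspaces of size d_model / n_heads; head outputs are
    concatenated and mapped by an output projection.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, dtype=np.float64):
        if d_model % n_heads != 0:
            raise ValueError(f"n_heads={n_heads} must divide d_model={d_model}")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.w_q = Linear(d_model, d_model, rng, bias=False, dtype=dtype)
        self.w_k = Linear(d_model, d_model, rng, bias=False, dtype=dtype)
        self.w_v = Linear(d_model, d_model, rng, bias=False, dtype=dtype)
        self.w_o = Linear(d_model, d_model, rng, bias=False, dtype=dtype)

    def _split(self, x: Tensor, batch: int, length: int) -> Tensor:
        # (B, L, D) -> (B, H, L, d_head)
        return x.reshape(batch, length, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def attention_weights(self, q_x: Tensor, kv_x: Tensor,
                          key_mask: np.ndarray | None) -> Tensor:
        b, lq = q_x.shape[0], q_x.shape[1]
        lk = kv_x.shape[1]
        # fold the 1/sqrt(d) scale into q (small) rather than scores (large)
        q = self._split(self.w_q(q_x), b, lq) * (1.0 / np.sqrt(self.d_head))
        k = self._split(self.w_k(kv_x), b, lk)
        scores = q @ k.transpose(0, 1, 3, 2)
        mask = None if key_mask is None else np.asarray(key_mask)[:, None, None, :]
        return masked_softmax(scores, mask, axis=-1)

    def __call__(self, q_x: Tensor, kv_x: Tensor, key_mask: np.ndarray | None) -> Tensor:
        b, lq = q_x.shape[0], q_x.shape[1]
        lk = kv_x.shape[1]
        attn = self.attention_weights(q_x, kv_x, key_mask)  # (B, H, Lq, Lk)
        v = self._split(self.w_v(kv_x), b, lk)
        ctx_heads = attn @ v  # (B, H, Lq, d_head)
        merged = ctx_heads.transpose(0, 2, 1, 3).reshape(b, lq, self.d_model)
        return self.w_o(merged)


class FeedForward(Module):
    """Position-wise two-layer MLP: W2 relu(W1 x + b1) + b2."""

    def __init__(self, d_model: int, d_hid: int, rng: np.random.Generator, dtype=np.float64):
        self.lin1 = Linear(d_model, d_hid, rng, bias=True, dtype=dtype)
        self.lin2 = Linear(d_hid, d_model, rng, bias=True, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class TransformerEncoderLayer(Module):
    """Post-norm transformer block: x = LN(x + MHA(x)); x = LN(x + FFN(x))."""

    def __init__(self, d_model: int, n_heads: int, d_hid: int, dropout: float,
                 rng: np.random.Generator, dtype=np.float64):
        self.attn = MultiHeadAttention(d_model, n_heads, rng, dtype)
        self.ffn = FeedForward(d_model, d_hid, rng, dtype)
        self.norm1 = LayerNorm(d_model, dtype=dtype)
        self.norm2 = LayerNorm(d_model, dtype=dtype)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, mask: np.ndarray | None, ctx: TrainContext) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x, x, mask), ctx))
        x = self.norm2(x + self.drop(self.ffn(x), ctx))
        return x


class CrossAttentionLayer(Module):
    """Post-norm cross-attention block: queries from one stream, keys and
    values from the other, with residual connections around both the
    attention and feed-forward sublayers."""

    def __init__(self, d_model: int, n_heads: int, d_hid: int, dropout: float,
                 rng: np.random.Generator, dtype=np.float64):
        self.attn = MultiHeadAttention(d_model, n_heads, rng, dtype)
        self.ffn = FeedForward(d_model, d_hid, rng, dtype)
        self.norm1 = LayerNorm(d_model, dtype=dtype)
        self.norm2 = LayerNorm(d_model, dtype=dtype)
        self.drop = Dropout(dropout)

    def __call__(self, q_x: Tensor, kv_x: Tensor, kv_mask: np.ndarray | None,
                 ctx: TrainContext) -> Tensor:
        q_x = self.norm1(q_x + self.drop(self.attn(q_x, kv_x, kv_mask), ctx))
        q_x = self.norm2(q_x + self.drop(self.ffn(q_x), ctx))
        return q_x


class Adam:
    """Adam with decoupled-from-nothing classic L2 regularization
    (weight decay added to the raw gradient)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
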