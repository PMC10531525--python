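"""Multi-head graph attention encoder for molecular graphs.

Each layer lifts node features per head (h -> W h), scores every edge
(i, j) of the adjacency (self-loops included) with
LeakyReLU(a^T [W h_i || W h_j]), normalizes scores over each node's
neighborhood with softmax, aggregates neighbor features with the
resulting attention weights, applies ReLU, concatenates the heads, and
projects back to the model width so layers stack at constant dimension.
Non-neighbors receive a large negative additive bias before the softmax,
giving them exactly zero weight.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import Embedding, Linear, Module, TrainContext, masked_softmax, xavier_uniform


class GATLayer(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 leaky_slope: float = 0.2, dtype=np.float64):
        if d_model % n_heads != 0:
            raise ValueError(f"n_heads={n_heads} must divide d_model={d_model}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.d_model = d_model
        self.leaky_slope = leaky_slope
        # per-head lift matrices packed as one (d_model, n_heads*d_head) weight
        self.w = Tensor(xavier_uniform((d_model, d_model), rng, dtype), requires_grad=True)
        # scoring vector a (2*d_head per head) split into source/destination halves
        self.a_src = Tensor(xavier_uniform((n_heads, self.d_head), rng, dtype),
                            requires_grad=True)
        self.a_dst = Tensor(xavier_uniform((n_heads, self.d_head), rng, dtype),
                            requires_grad=True)
        self.proj = Linear(d_model, d_model, rng, bias=False, dtype=dtype)

    def _lift(self, h: Tensor) -> Tensor:
        b, n = h.shape[0], h.shape[1]
        return (h @ self.w).reshape(b, n, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def attention(self, h: Tensor, adjacency: np.ndarray) -> Tensor:
        """Attention coefficients a_ij, shape (B, H, N, N); rows are
        probability vectors supported exactly on each node's neighborhood."""
        wh = self._lift(h)  # (B, H, N, d_head)
        src = (wh * self.a_src.reshape(1, self.n_heads, 1, self.d_head)).sum(
            axis=-1, keepdims=True)                      # (B, H, N, 1) score of query i
        dst = (wh * self.a_dst.reshape(1, self.n_heads, 1, self.d_head)).sum(
            axis=-1, keepdims=True).transpose(0, 1, 3, 2)  # (B, H, 1, N) score of key j
        e = (src + dst).leaky_relu(self.leaky_slope)
        adj = np.asarray(adjacency)
        if adj.ndim == 2:
            adj = adj[None]
        return masked_softmax(e, adj[:, None, :, :], axis=-1)

    def __call__(self, h: Tensor, adjacency: np.ndarray, ctx: TrainContext) -> Tensor:
        if not np.all(np.isfinite(h.data)):
            raise ValueError("non-finite node features")
        wh = self._lift(h)
        attn = self.attention(h, adjacency)       # (B, H, N, N)
        agg = (attn @ wh).relu()                  # (B, H, N, d_head)
        b, n = h.shape[0], h.shape[1]
        merged = agg.transpose(0, 2, 1, 3).reshape(b, n, self.d_model)
        return self.proj(merged)


class DrugEncoder(Module):
    """Atom-environment embedding followed by stacked GAT layers."""

    def __init__(self, n_tokens: int, d_model: int, n_layers: int, n_heads: int,
                 rng: np.random.Generator, leaky_slope: float = 0.2, dtype=np.float64):
        self.embedding = Embedding(n_tokens, d_model, rng, dtype=dtype)
        self.layers = [
            GATLayer(d_model, n_heads, rng, leaky_slope, dtype) for _ in range(n_layers)
        ]

    def __call__(self, atom_ids: np.ndarray, adjacency: np.ndarray,
                 ctx: TrainContext) -> Tensor:
        """atom_ids (B, A), adjacency (B, A, A) -> features (B, A, d_model).

        Padded atoms must carry a self-loop in the (padded) adjacency so
        their softmax neighborhoods are non-empty; their outputs are
        ignored downstream via the atom mask.
        """
        if adjacency.ndim == 3 and np.any(adjacency.sum(axis=-1) == 0):
            raise ValueError("empty neighborhood: adjacency needs self-loops")
        x = self.embedding(atom_ids)
        for layer in self.layers:
            x = layer(x, adjacency, ctx)
        return x
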