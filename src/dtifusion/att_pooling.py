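"""Attention pooling: node-level features -> one graph-level vector.

Pipeline: ReLU-activated input embedding, two masked multi-head
self-attention layers (with residual + layer norm for stability), masked
average pooling over real positions, hyperbolic tangent, and a learned
down-projection to the graph-vector dimension. The tanh bounds every
pre-projection entry inside (-1, 1), which also controls the magnitude
of the vectors entering the bilinear tensor module downstream.

The whole map is invariant to permuting node order and to appending
padded positions.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import (Dropout, LayerNorm, Linear, Module, MultiHeadAttention,
                 TrainContext, masked_mean)


class AttentionPooler(Module):
    def __init__(self, d_model: int, d_graph: int, n_heads: int, n_layers: int,
                 dropout: float, rng: np.random.Generator, dtype=np.float64):
        self.embed = Linear(d_model, d_model, rng, bias=True, dtype=dtype)
        self.attn_layers = [MultiHeadAttention(d_model, n_heads, rng, dtype)
                            for _ in range(n_layers)]
        self.norms = [LayerNorm(d_model, dtype=dtype) for _ in range(n_layers)]
        self.drop = Dropout(dropout)
        self.proj = Linear(d_model, d_graph, rng, bias=True, dtype=dtype)

    def pooled_pre_projection(self, x: Tensor, mask: np.ndarray,
                              ctx: TrainContext) -> Tensor:
        """tanh-bounded pooled vector before the final down-projection."""
        if mask.sum() == 0:
            raise ValueError("all positions masked: nothing to pool")
        h = self.embed(x).relu()
        for attn, norm in zip(self.attn_layers, self.norms):
            h = norm(h + self.drop(attn(h, h, mask), ctx))
        return masked_mean(h, mask).tanh()

    def __call__(self, x: Tensor, mask: np.ndarray, ctx: TrainContext) -> Tensor:
        """x (B, L, d_model), mask (B, L) -> graph vectors (B, d_graph)."""
        return self.proj(self.pooled_pre_projection(x, mask, ctx))


class MeanPooler(Module):
    """Plain masked global average pooling (the no-attention ablation)."""

    def __init__(self, d_model: int, d_graph: int):
        if d_model != d_graph:
            raise ValueError("mean pooling keeps the model width")

    def __call__(self, x: Tensor, mask: np.ndarray, ctx: TrainContext) -> Tensor:
        if mask.sum() == 0:
            raise ValueError("all positions masked: nothing to pool")
        return masked_mean(x, mask)
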