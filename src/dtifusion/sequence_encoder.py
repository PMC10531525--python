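"""Transformer encoder for protein n-gram sequences.

Token embeddings plus sinusoidal positional encodings feed a stack of
post-norm self-attention blocks (multi-head attention, position-wise
feed-forward, residual connections, layer normalization). Padding
positions are excluded from attention by the key mask.

The sinusoidal encoding uses angle k / n^(2i/d) (scale constant
n = 10000): entry (k, 2i) = sin, entry (k, 2i+1) = cos. This is the form
for which the relative-position property holds — the row at position
k + m is an i-wise planar rotation of the row at position k, so dot
products between rows depend only on the offset m.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import Dropout, Embedding, Module, TrainContext, TransformerEncoderLayer


def positional_encoding(length: int, d: int, n: float = 10000.0) -> np.ndarray:
    """Sinusoidal positional-encoding matrix of shape (length, d).

    d must be even: columns come in (sin, cos) pairs sharing one angular
    frequency 1 / n^(2i/d).
    """
    if d % 2 != 0:
        raise ValueError(f"positional encoding dimension must be even, got {d}")
    if length < 1:
        raise ValueError("length must be >= 1")
    k = np.arange(length)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = k / n ** (2 * i / d)
    pe = np.empty((length, d))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


class ProteinEncoder(Module):
    """Embedding + positional encoding + N post-norm transformer layers."""

    def __init__(self, n_tokens: int, d_model: int, n_layers: int, n_heads: int,
                 d_hid: int, dropout: float, rng: np.random.Generator,
                 dtype=np.float64, init_table: np.ndarray | None = None):
        self.embedding = Embedding(n_tokens, d_model, rng, dtype=dtype, init=init_table)
        self.layers = [
            TransformerEncoderLayer(d_model, n_heads, d_hid, dropout, rng, dtype)
            for _ in range(n_layers)
        ]
        self.drop = Dropout(dropout)
        self.d_model = d_model
        self.dtype = dtype
        self._pe_cache: dict[int, np.ndarray] = {}

    def __call__(self, token_ids: np.ndarray, mask: np.ndarray,
                 ctx: TrainContext) -> Tensor:
        """token_ids, mask: (B, L) -> features (B, L, d_model)."""
        if mask.sum() == 0:
            raise ValueError("all positions masked: no valid input")
        # scale token embeddings by sqrt(d) so they are not swamped by the
        # unit-amplitude positional encodings (standard transformer practice)
        x = self.embedding(token_ids) * float(np.sqrt(self.d_model))
        length = token_ids.shape[1]
        pe = self._pe_cache.get(length)
        if pe is None:
            pe = positional_encoding(length, self.d_model).astype(self.dtype)
            self._pe_cache[length] = pe
        x = x + pe[None, :, :] * mask[:, :, None].astype(self.dtype)
        x = self.drop(x, ctx)
        for layer in self.layers:
            x = layer(x, mask, ctx)
        return x
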