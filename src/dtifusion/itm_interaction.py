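"""Interaction transformer: bidirectional cross-attention features.

Two parallel cross-attention encoders with independent parameters. In
one, the drug atom features are the queries and the protein n-gram
features supply keys and values (how each atom reads the protein); in
the other, the roles are reversed. Each encoder is a stack of post-norm
blocks — multi-head scaled dot-product attention, residual + layer norm,
position-wise feed-forward, residual + layer norm — repeated N times.
Each stream's per-position outputs are reduced by a masked mean over its
query positions, giving one fixed-size interaction vector per direction.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import CrossAttentionLayer, Module, TrainContext, masked_mean


class CrossAttentionEncoder(Module):
    def __init__(self, d_model: int, n_heads: int, d_hid: int, n_layers: int,
                 dropout: float, rng: np.random.Generator, dtype=np.float64):
        self.layers = [
            CrossAttentionLayer(d_model, n_heads, d_hid, dropout, rng, dtype)
            for _ in range(n_layers)
        ]

    def __call__(self, query: Tensor, context: Tensor, context_mask: np.ndarray,
                 ctx: TrainContext) -> Tensor:
        if context_mask.sum() == 0:
            raise ValueError("context fully masked: cross-attention undefined")
        x = query
        for layer in self.layers:
            x = layer(x, context, context_mask, ctx)
        return x


class InteractionTransformer(Module):
    """The two parallel cross-attention streams and their pooled outputs."""

    def __init__(self, d_model: int, n_heads: int, d_hid: int, n_layers: int,
                 dropout: float, rng: np.random.Generator, dtype=np.float64):
        self.drug_reads_protein = CrossAttentionEncoder(
            d_model, n_heads, d_hid, n_layers, dropout, rng, dtype)
        self.protein_reads_drug = CrossAttentionEncoder(
            d_model, n_heads, d_hid, n_layers, dropout, rng, dtype)

    def __call__(self, drug_nodes: Tensor, drug_mask: np.ndarray,
                 protein_nodes: Tensor, protein_mask: np.ndarray,
                 ctx: TrainContext) -> tuple[Tensor, Tensor]:
        """Returns (v_com_p, v_pro_c): drug-attending-protein and
        protein-attending-drug interaction vectors, each (B, d_model)."""
        dp = self.drug_reads_protein(drug_nodes, protein_nodes, protein_mask, ctx)
        pd = self.protein_reads_drug(protein_nodes, drug_nodes, drug_mask, ctx)
        v_com_p = masked_mean(dp, drug_mask)
        v_pro_c = masked_mean(pd, protein_mask)
        return v_com_p, v_pro_c
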