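"""Neural tensor network relating the two graph-level vectors.

For drug vector h_d and protein vector h_p (both dimension d), slice k
of the output is

    g_k = ReLU( h_d^T W_k h_p  +  V_k . [h_d || h_p]  +  b_k )

with K learnable d x d bilinear slices W, a K x 2d linear map V and a
bias b. The K-dimensional output is the graph-level interaction feature;
its entries are non-negative by construction. Slices are stored as one
(K, d, d) parameter; the contraction is evaluated as two matrix products
(O(K d^2) per pair).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .nn import Module, xavier_uniform


class NeuralTensorNetwork(Module):
    def __init__(self, d: int, k_dim: int, rng: np.random.Generator, dtype=np.float64):
        self.d = d
        self.k_dim = k_dim
        w = np.stack([xavier_uniform((d, d), rng, dtype) for _ in range(k_dim)])
        self.w_slices = Tensor(w, requires_grad=True)               # (K, d, d)
        self.v_lin = Tensor(xavier_uniform((2 * d, k_dim), rng, dtype),
                            requires_grad=True)                     # maps [h_d || h_p]
        self.bias = Tensor(np.zeros(k_dim, dtype=dtype), requires_grad=True)

    def pre_activation(self, h_drug: Tensor, h_pro: Tensor) -> Tensor:
        if h_drug.shape[-1] != self.d or h_pro.shape[-1] != self.d:
            raise ValueError(
                f"expected dimension {self.d}, got {h_drug.shape[-1]} / {h_pro.shape[-1]}"
            )
        # bilinear term: h_d @ W -> (B, K*d) via (d, K*d) view, then dot with h_p
        w_flat = self.w_slices.transpose(1, 0, 2).reshape(self.d, self.k_dim * self.d)
        mixed = (h_drug @ w_flat).reshape(h_drug.shape[0], self.k_dim, self.d)
        bilinear = (mixed * h_pro.reshape(h_pro.shape[0], 1, self.d)).sum(axis=-1)
        linear = concat([h_drug, h_pro], axis=-1) @ self.v_lin
        return bilinear + linear + self.bias

    def __call__(self, h_drug: Tensor, h_pro: Tensor) -> Tensor:
        """(B, d) x (B, d) -> non-negative interaction scores (B, K)."""
        return self.pre_activation(h_drug, h_pro).relu()
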