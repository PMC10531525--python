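"""Independent nested-loop reference implementations used as test oracles.

Each function recomputes one model operation directly from its defining
formula with explicit Python loops, sharing no code with the package's
vectorized implementations.
"""

import numpy as np


def gat_attention_loops(h, adjacency, w, a_src, a_dst, slope=0.2):
    """Per-head GAT attention coefficients via explicit neighborhood loops.

    h: (N, d); w: (d, H*dh); a_src/a_dst: (H, dh). Returns (H, N, N).
    """
    n, d = h.shape
    n_heads, dh = a_src.shape
    out = np.zeros((n_heads, n, n))
    for head in range(n_heads):
        w_h = w[:, head * dh:(head + 1) * dh]
        wh = np.array([w_h.T @ h[i] for i in range(n)])
        for i in range(n):
            neigh = [j for j in range(n) if adjacency[i, j] == 1]
            e = {}
            for j in neigh:
                score = a_src[head] @ wh[i] + a_dst[head] @ wh[j]
                e[j] = score if score > 0 else slope * score
            mx = max(e.values())
            z = sum(np.exp(e[j] - mx) for j in neigh)
            for j in neigh:
                out[head, i, j] = np.exp(e[j] - mx) / z
    return out


def scaled_dot_attention_loops(q, k, v):
    """softmax(Q K^T / sqrt(d)) V, one query row at a time."""
    d = q.shape[1]
    out = np.zeros((q.shape[0], v.shape[1]))
    for i in range(q.shape[0]):
        scores = np.array([q[i] @ k[j] / np.sqrt(d) for j in range(k.shape[0])])
        scores = scores - scores.max()
        weights = np.exp(scores) / np.exp(scores).sum()
        out[i] = sum(weights[j] * v[j] for j in range(v.shape[0]))
    return out


def ntn_loops(h_drug, h_pro, w_slices, v_lin, bias):
    """Slice-by-slice bilinear + linear + bias, then ReLU.

    w_slices: (K, d, d); v_lin: (2d, K); bias: (K,).
    """
    k_dim, d, _ = w_slices.shape
    out = np.zeros(k_dim)
    for k in range(k_dim):
        bilinear = 0.0
        for a in range(d):
            for b in range(d):
                bilinear += h_drug[a] * w_slices[k, a, b] * h_pro[b]
        linear = 0.0
        for a in range(d):
            linear += v_lin[a, k] * h_drug[a]
            linear += v_lin[d + a, k] * h_pro[a]
        pre = bilinear + linear + bias[k]
        out[k] = pre if pre > 0 else 0.0
    return out


def mlp_head_loops(features, w1, w2):
    """sigmoid(W2 relu(W1 f)) with explicit loops (bias-free head)."""
    hidden = np.zeros(w1.shape[1])
    for j in range(w1.shape[1]):
        s = sum(features[i] * w1[i, j] for i in range(w1.shape[0]))
        hidden[j] = s if s > 0 else 0.0
    logit = sum(hidden[j] * w2[j, 0] for j in range(w2.shape[0]))
    return 1.0 / (1.0 + np.exp(-logit))


def auc_pairwise(scores, labels):
    """(concordant + 0.5 * tied) / (n_pos * n_neg) over all pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def masked_mean_loops(x, mask):
    """Arithmetic mean over real positions only; x (B, L, D), mask (B, L)."""
    b, l, d = x.shape
    out = np.zeros((b, d))
    for i in range(b):
        rows = [x[i, j] for j in range(l) if mask[i, j] == 1]
        out[i] = np.mean(rows, axis=0)
    return out


def finite_difference_grads(f, params, step=1e-5):
    """Central-difference gradients of scalar f() w.r.t. Tensor params."""
    grads = []
    for p in params:
        g = np.zeros_like(p.data)
        flat = p.data.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + step
            hi = f()
            flat[i] = orig - step
            lo = f()
            flat[i] = orig
            gflat[i] = (hi - lo) / (2 * step)
        grads.append(g)
    return grads
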