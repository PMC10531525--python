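"""Skip-gram with negative sampling (SGNS), vectorized in numpy.

Trains input/output vector tables over integer token "sentences". The
update is the classic SGNS gradient, applied in shuffled minibatches of
(center, context) pairs with ``negatives`` noise samples per pair drawn
from the unigram^0.75 distribution. Single-threaded and fully seeded, so
two runs with the same seed produce identical tables.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def skipgram_pairs(sentences: list[np.ndarray], window: int) -> np.ndarray:
    """All (center, context) pairs within a symmetric fixed window."""
    pairs = []
    for sent in sentences:
        n = len(sent)
        for i in range(n):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((sent[i], sent[j]))
    if not pairs:
        raise ValueError("corpus yields no skip-gram pairs")
    return np.asarray(pairs, dtype=np.int64)


def train_skipgram(sentences: list[np.ndarray], n_ids: int, dim: int,
                   window: int = 5, epochs: int = 5, negatives: int = 5,
                   lr: float = 0.025, seed: int = 0,
                   batch_size: int = 1024) -> np.ndarray:
    """Return the input-vector table of shape (n_ids, dim).

    ``n_ids`` is the full id space (padding and unknown rows included;
    they simply never occur in the corpus and stay at initialization).
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_ids)
    for sent in sentences:
        np.add.at(counts, np.asarray(sent, dtype=np.int64), 1)
    noise = counts ** 0.75
    total = noise.sum()
    if total == 0:
        raise ValueError("empty corpus")
    noise /= total

    w_in = ((rng.random((n_ids, dim)) - 0.5) / dim)
    w_out = np.zeros((n_ids, dim))

    pairs = skipgram_pairs([np.asarray(s, dtype=np.int64) for s in sentences], window)
    n_pairs = len(pairs)
    total_batches = epochs * int(np.ceil(n_pairs / batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            batch = pairs[order[start:start + batch_size]]
            cur_lr = lr * max(1e-4, 1.0 - step / total_batches)
            step += 1
            centers, contexts = batch[:, 0], batch[:, 1]
            b = len(batch)
            negs = rng.choice(n_ids, size=(b, negatives), p=noise)
            # a drawn negative that collides with the true context is skipped
            neg_valid = (negs != contexts[:, None]).astype(float)

            v_c = w_in[centers]                      # (b, d)
            u_pos = w_out[contexts]                  # (b, d)
            u_neg = w_out[negs]                      # (b, k, d)

            pos_score = _sigmoid(np.einsum("bd,bd->b", v_c, u_pos))
            neg_score = _sigmoid(np.einsum("bd,bkd->bk", v_c, u_neg)) * neg_valid

            g_pos = (pos_score - 1.0)[:, None]       # d/du_pos coefficient
            g_neg = neg_score[:, :, None]

            grad_vc = g_pos * u_pos + np.einsum("bk,bkd->bd", neg_score, u_neg)
            grad_upos = g_pos * v_c
            grad_uneg = g_neg * v_c[:, None, :]

            # normalize by per-id multiplicity within the batch so heavily
            # repeated tokens see an averaged, not summed, update (keeps the
            # effective per-token step bounded on small vocabularies)
            c_mult = np.bincount(centers, minlength=n_ids)[centers, None]
            out_idx = np.concatenate([contexts, negs.reshape(-1)])
            out_counts = np.bincount(out_idx, minlength=n_ids)
            np.add.at(w_in, centers, -cur_lr * grad_vc / c_mult)
            np.add.at(w_out, contexts,
                      -cur_lr * grad_upos / out_counts[contexts, None])
            np.add.at(w_out, negs.reshape(-1),
                      -cur_lr * grad_uneg.reshape(-1, dim)
                      / out_counts[negs.reshape(-1), None])
    return w_in
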