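"""Model assembly, fusion head, training protocol and evaluation.

The full model fuses three interaction views before classification:

* ``v_scores`` — K-dimensional neural-tensor interaction of the two
  graph-level vectors,
* ``v_com_p`` / ``v_pro_c`` — the two pooled cross-attention streams
  (drug reading protein, protein reading drug).

The concatenated feature vector enters a two-layer bias-free MLP with a
ReLU between the layers and a sigmoid output; training minimizes binary
cross-entropy with Adam (L2 regularization via weight decay), Xavier
initialization, dropout active only during training, and a fixed epoch
budget. Ablation variants drop individual views:

* ``wo_ntn_itm`` — no interaction modules; the two graph vectors are
  concatenated directly,
* ``wo_itm`` — graph-level (tensor) interaction only,
* ``wo_ntn`` — node-level (cross-attention) interaction only,
* ``wo_att`` — attention pooling replaced by masked global averaging.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, fields
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .att_pooling import AttentionPooler, MeanPooler
from .autodiff import Tensor, concat
from .featurize import (MolecularGraph, ProteinTokens, protein_to_ngrams,
                        smiles_to_graph, train_ngram_embeddings)
from .gat_encoder import DrugEncoder
from .io_datasets import InteractionRecord, Vocabulary, stratified_kfold
from .itm_interaction import InteractionTransformer
from .nn import Adam, Dropout, Linear, Module, TrainContext
from .ntn_interaction import NeuralTensorNetwork
from .sequence_encoder import ProteinEncoder

logger = logging.getLogger(__name__)

VARIANTS = ("full", "wo_ntn_itm", "wo_itm", "wo_ntn", "wo_att")


@dataclass
class ModelConfig:
    """Hyperparameters; the first ten fields are the canonical defaults."""

    epochs: int = 40
    dropout: float = 0.1
    lr: float = 1e-3
    weight_decay: float = 1e-4
    radius: int = 2
    ngram: int = 3
    ntn_k: int = 16
    d_model: int = 64
    n_gat_layers: int = 3
    n_heads: int = 8

    # architecture details beyond the headline table
    n_bert_layers: int = 3
    d_hid: int | None = None          # feed-forward width; default 4 * d_model
    d_graph: int | None = None        # graph-vector width; default d_model
    att_pool_layers: int = 2
    att_pool_heads: int | None = None
    itm_layers: int = 1
    itm_heads: int | None = None
    mlp_hidden: int = 256
    token_dropout: float = 0.0        # whole-token dropout on both embedding streams
    leaky_slope: float = 0.2
    max_atoms: int = 150
    max_tokens: int = 1000

    # training protocol
    batch_size: int = 32
    seed: int = 0
    variant: str = "full"
    use_word2vec: bool = True         # skip-gram pre-training of n-gram embeddings
    freeze_protein_embeddings: bool = False   # keep pre-trained vectors static
    w2v_window: int = 5
    w2v_epochs: int = 5
    dtype: str = "float32"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.d_hid is None:
            self.d_hid = 4 * self.d_model
        if self.d_graph is None:
            self.d_graph = self.d_model
        if self.att_pool_heads is None:
            self.att_pool_heads = self.n_heads
        if self.itm_heads is None:
            self.itm_heads = self.n_heads

    def table_defaults(self) -> dict:
        """The ten canonical hyperparameters, in reporting units."""
        return {
            "epochs": self.epochs,
            "dropout": self.dropout,
            "learning_rate": self.lr,
            "regularization_coefficient": self.weight_decay,
            "radius": self.radius,
            "ngram": self.ngram,
            "n_major_associations_K": self.ntn_k,
            "hidden_dim": self.d_model,
            "n_gat_layers": self.n_gat_layers,
            "n_attention_heads": self.n_heads,
        }

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @property
    def np_dtype(self):
        return np.float64 if self.dtype == "float64" else np.float32


def scaled_config(seed: int = 42, variant: str = "full", epochs: int = 10) -> ModelConfig:
    """Desk-scale configuration for CPU experiments: half-width model
    (d_model 32, 4 heads of the same per-head size as the default),
    two-layer protein and graph encoders, one cross-attention layer,
    token-level dropout for regularization at small sample sizes, a
    tight skip-gram window (desk-scale corpora are short, so local
    co-occurrence carries most of the signal), short epoch budget."""
    return ModelConfig(d_model=32, n_heads=4, epochs=epochs, batch_size=32,
                       itm_layers=1, n_bert_layers=2, n_gat_layers=2,
                       token_dropout=0.1, w2v_window=3,
                       seed=seed, variant=variant)


# ---------------------------------------------------------------------------
# metrics and loss
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    auc: float
    precision: float
    recall: float
    threshold: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return asdict(self)


def ce_loss(y: int, y_hat: float, eps: float = 1e-7) -> float:
    """Binary cross-entropy -[y log p + (1-y) log(1-p)], p clamped to
    [eps, 1-eps]."""
    if not 0.0 <= y_hat <= 1.0:
        raise ValueError(f"predicted probability {y_hat} outside [0, 1]")
    p = min(max(y_hat, eps), 1.0 - eps)
    return -(y * math.log(p) + (1 - y) * math.log(1.0 - p))


def compute_metrics(scores: Sequence[float], labels: Sequence[int],
                    threshold: float = 0.5) -> MetricsReport:
    """AUC (threshold-free) plus precision/recall at ``threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return MetricsReport(auc, precision, recall, threshold, n_pos, n_neg)


# ---------------------------------------------------------------------------
# featurization pipeline (vocabularies fitted on training data only)
# ---------------------------------------------------------------------------

@dataclass
class FeaturizedPair:
    graph: MolecularGraph
    protein: ProteinTokens
    label: int


class FeaturePipeline:
    """Fit vocabularies on the training split; transform any split.

    Raw token strings are cached per unique SMILES/sequence so repeated
    folds re-tokenize cheaply. Atom lists and n-gram sequences are
    truncated at ``max_atoms`` / ``max_tokens``.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.drug_vocab = Vocabulary()
        self.protein_vocab = Vocabulary()
        self.w2v_table: np.ndarray | None = None
        self._fitted = False

    def fit(self, records: Sequence[InteractionRecord],
            seed: int | None = None) -> "FeaturePipeline":
        cfg = self.config
        self.drug_vocab = Vocabulary()
        self.protein_vocab = Vocabulary()
        corpus = []
        for rec in records:
            smiles_to_graph(rec.smiles, cfg.radius, self.drug_vocab, update_vocab=True)
            corpus.append(protein_to_ngrams(rec.sequence, cfg.ngram,
                                            self.protein_vocab, update_vocab=True))
        if cfg.use_word2vec:
            table = train_ngram_embeddings(
                corpus, self.protein_vocab, dim=cfg.d_model,
                window=cfg.w2v_window, epochs=cfg.w2v_epochs,
                seed=cfg.seed if seed is None else seed,
            )
            self.w2v_table = table.vectors.astype(cfg.np_dtype)
        self._fitted = True
        return self

    def transform(self, records: Sequence[InteractionRecord]) -> list[FeaturizedPair]:
        if not self._fitted:
            raise RuntimeError("pipeline not fitted")
        cfg = self.config
        graph_cache: dict[str, MolecularGraph] = {}
        token_cache: dict[str, ProteinTokens] = {}
        out = []
        for rec in records:
            g = graph_cache.get(rec.smiles)
            if g is None:
                g = smiles_to_graph(rec.smiles, cfg.radius, self.drug_vocab)
                if g.n_atom > cfg.max_atoms:
                    g = MolecularGraph(g.atom_ids[:cfg.max_atoms],
                                       g.adjacency[:cfg.max_atoms, :cfg.max_atoms],
                                       cfg.max_atoms)
                graph_cache[rec.smiles] = g
            p = token_cache.get(rec.sequence)
            if p is None:
                p = protein_to_ngrams(rec.sequence, cfg.ngram, self.protein_vocab)
                if p.length > cfg.max_tokens:
                    p = ProteinTokens(p.token_ids[:cfg.max_tokens], cfg.max_tokens)
                token_cache[rec.sequence] = p
            out.append(FeaturizedPair(g, p, rec.label))
        return out


def collate(pairs: Sequence[FeaturizedPair], dtype=np.float32) -> dict:
    """Pad a minibatch to rectangular arrays with masks.

    Padded atoms receive a self-loop in the adjacency so their attention
    neighborhoods are non-empty; their outputs are masked everywhere
    downstream.
    """
    b = len(pairs)
    a_max = max(p.graph.n_atom for p in pairs)
    l_max = max(p.protein.length for p in pairs)
    atom_ids = np.zeros((b, a_max), dtype=np.int64)
    adj = np.zeros((b, a_max, a_max), dtype=dtype)
    atom_mask = np.zeros((b, a_max), dtype=dtype)
    prot_ids = np.zeros((b, l_max), dtype=np.int64)
    prot_mask = np.zeros((b, l_max), dtype=dtype)
    labels = np.zeros(b, dtype=dtype)
    for i, p in enumerate(pairs):
        n, l = p.graph.n_atom, p.protein.length
        atom_ids[i, :n] = p.graph.atom_ids
        adj[i, :n, :n] = p.graph.adjacency
        adj[i, range(a_max), range(a_max)] = 1.0  # pad self-loops
        atom_mask[i, :n] = 1.0
        prot_ids[i, :l] = p.protein.token_ids
        prot_mask[i, :l] = 1.0
        labels[i] = p.label
    return {"atom_ids": atom_ids, "adjacency": adj, "atom_mask": atom_mask,
            "prot_ids": prot_ids, "prot_mask": prot_mask, "labels": labels}


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class DTIModel(Module):
    """End-to-end drug–target interaction classifier."""

    def __init__(self, config: ModelConfig, n_drug_tokens: int, n_prot_tokens: int,
                 rng: np.random.Generator, prot_init: np.ndarray | None = None):
        cfg = config
        dtype = cfg.np_dtype
        self.config = cfg
        self.drug_encoder = DrugEncoder(
            n_drug_tokens, cfg.d_model, cfg.n_gat_layers, cfg.n_heads, rng,
            cfg.leaky_slope, dtype)
        self.protein_encoder = ProteinEncoder(
            n_prot_tokens, cfg.d_model, cfg.n_bert_layers, cfg.n_heads,
            cfg.d_hid, cfg.dropout, rng, dtype, init_table=prot_init)
        if cfg.freeze_protein_embeddings:
            self.protein_encoder.embedding.weight.requires_grad = False
        if cfg.variant == "wo_att":
            self.drug_pool = MeanPooler(cfg.d_model, cfg.d_graph)
            self.protein_pool = MeanPooler(cfg.d_model, cfg.d_graph)
        else:
            self.drug_pool = AttentionPooler(
                cfg.d_model, cfg.d_graph, cfg.att_pool_heads, cfg.att_pool_layers,
                cfg.dropout, rng, dtype)
            self.protein_pool = AttentionPooler(
                cfg.d_model, cfg.d_graph, cfg.att_pool_heads, cfg.att_pool_layers,
                cfg.dropout, rng, dtype)
        self.use_itm = cfg.variant in ("full", "wo_ntn", "wo_att")
        self.use_ntn = cfg.variant in ("full", "wo_itm", "wo_att")
        if self.use_itm:
            self.itm = InteractionTransformer(
                cfg.d_model, cfg.itm_heads, cfg.d_hid, cfg.itm_layers,
                cfg.dropout, rng, dtype)
        if self.use_ntn:
            self.ntn = NeuralTensorNetwork(cfg.d_graph, cfg.ntn_k, rng, dtype)
        self.head_in = self._head_width()
        self.head1 = Linear(self.head_in, cfg.mlp_hidden, rng, bias=False, dtype=dtype)
        self.head2 = Linear(cfg.mlp_hidden, 1, rng, bias=False, dtype=dtype)
        self.head_drop = Dropout(cfg.dropout)

    def _head_width(self) -> int:
        cfg = self.config
        if cfg.variant == "wo_ntn_itm":
            return 2 * cfg.d_graph
        width = 0
        if self.use_ntn:
            width += cfg.ntn_k
        if self.use_itm:
            width += 2 * cfg.d_model
        return width

    def _token_drop(self, ids: np.ndarray, ctx: TrainContext) -> np.ndarray:
        """Whole-token dropout: replace ids with padding during training so
        the model cannot rely on any single token's identity."""
        p = self.config.token_dropout
        if not ctx.training or p <= 0.0:
            return ids
        keep = ctx.rng.random(ids.shape) >= p
        return np.where(keep, ids, 0)

    def interaction_features(self, batch: dict, ctx: TrainContext) -> Tensor:
        """The fused feature vector entering the classifier, (B, head_in)."""
        drug_nodes = self.drug_encoder(self._token_drop(batch["atom_ids"], ctx),
                                       batch["adjacency"], ctx)
        prot_nodes = self.protein_encoder(self._token_drop(batch["prot_ids"], ctx),
                                          batch["prot_mask"], ctx)
        h_drug = self.drug_pool(drug_nodes, batch["atom_mask"], ctx)
        h_pro = self.protein_pool(prot_nodes, batch["prot_mask"], ctx)
        parts: list[Tensor] = []
        if self.config.variant == "wo_ntn_itm":
            return concat([h_drug, h_pro], axis=-1)
        if self.use_ntn:
            parts.append(self.ntn(h_drug, h_pro))
        if self.use_itm:
            v_com_p, v_pro_c = self.itm(
                drug_nodes, batch["atom_mask"], prot_nodes, batch["prot_mask"], ctx)
            parts.extend([v_com_p, v_pro_c])
        return concat(parts, axis=-1)

    def forward(self, batch: dict, ctx: TrainContext) -> Tensor:
        """Interaction probabilities, shape (B,)."""
        feats = self.interaction_features(batch, ctx)
        if not np.all(np.isfinite(feats.data)):
            raise FloatingPointError("non-finite interaction features")
        hidden = self.head_drop(self.head1(feats).relu(), ctx)
        logits = self.head2(hidden)
        return logits.sigmoid().reshape(logits.shape[0])

    __call__ = forward


def build_variant(config: ModelConfig, drug_vocab: Vocabulary,
                  protein_vocab: Vocabulary, rng: np.random.Generator,
                  prot_init: np.ndarray | None = None) -> DTIModel:
    """Construct the model variant named by ``config.variant``."""
    return DTIModel(config, drug_vocab.n_rows, protein_vocab.n_rows, rng, prot_init)


def batched_ce(probs: Tensor, labels: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy; probabilities clamped differentiably."""
    p = probs * (1.0 - 2.0 * eps) + eps
    y = np.asarray(labels, dtype=probs.data.dtype)
    loss = -(y * p.log() + (1.0 - y) * (1.0 - p).log())
    return loss.mean()


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: DTIModel
    pipeline: FeaturePipeline
    config: ModelConfig
    history: list[float] = field(default_factory=list)   # mean loss per epoch


def train(records: Sequence[InteractionRecord], config: ModelConfig,
          pipeline: FeaturePipeline | None = None,
          log_every: int | None = None) -> TrainResult:
    """Train on ``records`` with the configured protocol.

    One master seed fans out to initialization, shuffling and dropout.
    Raises on divergence (non-finite loss).
    """
    master = np.random.default_rng(config.seed)
    init_seed, shuffle_seed, drop_seed, w2v_seed = master.integers(0, 2**31 - 1, size=4)
    if pipeline is None:
        pipeline = FeaturePipeline(config).fit(records, seed=int(w2v_seed))
    pairs = pipeline.transform(records)
    model = build_variant(config, pipeline.drug_vocab, pipeline.protein_vocab,
                          np.random.default_rng(int(init_seed)),
                          prot_init=pipeline.w2v_table)
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    shuffle_rng = np.random.default_rng(int(shuffle_seed))
    ctx = TrainContext(rng=np.random.default_rng(int(drop_seed)), training=True)
    history: list[float] = []
    n = len(pairs)
    lengths = np.array([p.protein.length for p in pairs])
    for epoch in range(config.epochs):
        # jittered length-sorted batches: near-uniform padding within a
        # batch (cheap), random batch order and composition across epochs
        keys = lengths + shuffle_rng.uniform(0, 24, size=n)
        order = np.argsort(keys, kind="stable")
        batch_starts = list(range(0, n, config.batch_size))
        shuffle_rng.shuffle(batch_starts)
        losses = []
        for start in batch_starts:
            idx = order[start:start + config.batch_size]
            batch = collate([pairs[i] for i in idx], dtype=config.np_dtype)
            probs = model(batch, ctx)
            loss = batched_ce(probs, batch["labels"])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged: loss={loss.data} at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.post_step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if log_every and (epoch + 1) % log_every == 0:
            logger.info("epoch %d/%d mean loss %.4f", epoch + 1, config.epochs,
                        history[-1])
    return TrainResult(model, pipeline, config, history)


def predict_scores(result: TrainResult, records: Sequence[InteractionRecord],
                   batch_size: int | None = None) -> np.ndarray:
    """Interaction probabilities for ``records`` in evaluation mode."""
    pairs = result.pipeline.transform(records)
    bs = batch_size or result.config.batch_size
    ctx = TrainContext.eval()
    scores = []
    for start in range(0, len(pairs), bs):
        batch = collate(pairs[start:start + bs], dtype=result.config.np_dtype)
        scores.append(result.model(batch, ctx).data)
    return np.concatenate(scores)


def evaluate(result: TrainResult, records: Sequence[InteractionRecord],
             threshold: float = 0.5) -> MetricsReport:
    scores = predict_scores(result, records)
    labels = [r.label for r in records]
    return compute_metrics(scores, labels, threshold)


@dataclass
class CVResult:
    fold_metrics: list[MetricsReport]
    mean: MetricsReport

    def to_dict(self) -> dict:
        return {"folds": [m.to_dict() for m in self.fold_metrics],
                "mean": self.mean.to_dict()}


def run_cv(records: Sequence[InteractionRecord], config: ModelConfig,
           k: int = 5) -> CVResult:
    """Stratified k-fold cross-validation, training from scratch per fold.

    Vocabularies (and optional skip-gram embeddings) are rebuilt from each
    fold's training split only; the mean report averages the per-fold
    AUC/precision/recall.
    """
    labels = [r.label for r in records]
    folds = stratified_kfold(labels, k=k, seed=config.seed)
    reports = []
    for fold in folds:
        train_recs = [records[i] for i in fold.train_indices]
        test_recs = [records[i] for i in fold.test_indices]
        result = train(train_recs, config)
        reports.append(evaluate(result, test_recs))
        logger.info("fold %d: AUC %.4f", fold.fold_index, reports[-1].auc)
    mean = MetricsReport(
        auc=float(np.mean([r.auc for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        threshold=reports[0].threshold,
        n_pos=sum(r.n_pos for r in reports),
        n_neg=sum(r.n_neg for r in reports),
    )
    return CVResult(reports, mean)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(result: TrainResult, path) -> None:
    """Serialize parameters, vocabularies and config into one .npz file."""
    params = result.model.parameters()
    arrays = {f"param_{i}": p.data for i, p in enumerate(params)}
    arrays["drug_tokens"] = np.array(list(result.pipeline.drug_vocab.token_to_id),
                                     dtype=object)
    arrays["protein_tokens"] = np.array(list(result.pipeline.protein_vocab.token_to_id),
                                        dtype=object)
    arrays["config_json"] = np.array([json.dumps(result.config.to_dict())])
    arrays["history"] = np.array(result.history)
    np.savez(path, **arrays)


def load_checkpoint(path) -> TrainResult:
    with np.load(path, allow_pickle=True) as data:
        config = ModelConfig.from_dict(json.loads(str(data["config_json"][0])))
        pipeline = FeaturePipeline(config)
        for t in data["drug_tokens"]:
            pipeline.drug_vocab.add(str(t))
        for t in data["protein_tokens"]:
            pipeline.protein_vocab.add(str(t))
        pipeline._fitted = True
        model = build_variant(config, pipeline.drug_vocab, pipeline.protein_vocab,
                              np.random.default_rng(0))
        params = model.parameters()
        for i, p in enumerate(params):
            p.data = data[f"param_{i}"].astype(config.np_dtype)
        history = [float(x) for x in data["history"]]
    return TrainResult(model, pipeline, config, history)
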