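"""Molecular and protein featurization.

Drugs: a SMILES string becomes a heavy-atom molecular graph. Each atom is
labelled by a radius-r *atom-environment token*: a Weisfeiler–Lehman-style
relabeling that starts from (element, aromaticity) and iteratively folds
in the bond-annotated labels of the neighborhood, out to ``radius`` bonds.
Tokens are graph-intrinsic, so any SMILES spelling of the same molecule
yields the same multiset of tokens. The adjacency matrix covers covalent
bonds between heavy atoms, with self-loops added so every atom attends to
itself in the graph attention layers.

Proteins: an amino-acid sequence becomes the sequence of its overlapping
n-grams (stride 1), each n-gram a vocabulary token. Token embeddings can
be pre-trained with skip-gram negative sampling over the training corpus
(:func:`train_ngram_embeddings`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .io_datasets import Vocabulary
from .word2vec import train_skipgram

RDLogger.DisableLog("rdApp.*")  # rdkit parse warnings handled as exceptions here

logger = logging.getLogger(__name__)


class FeaturizationError(ValueError):
    """Raised when a SMILES string or sequence cannot be featurized."""


@dataclass
class MolecularGraph:
    """Atom-environment token ids plus {0,1} adjacency with self-loops."""

    atom_ids: np.ndarray          # (n_atom,) int, >= 1 after vocabulary lookup
    adjacency: np.ndarray         # (n_atom, n_atom) float {0,1}, symmetric, diag 1
    n_atom: int


@dataclass
class ProteinTokens:
    """Overlapping n-gram token ids; length = L - n + 1 for sequence length L."""

    token_ids: np.ndarray         # (length,) int
    length: int


@dataclass
class EmbeddingTable:
    """(vocab size + 2) x dim matrix: row 0 = padding (zero), last row = unknown."""

    vectors: np.ndarray
    dim: int


def atom_environment_tokens(mol: Chem.Mol, radius: int) -> list[str]:
    """Radius-r environment token per heavy atom.

    Iterative relabeling: label_0 = (element, aromatic); label_{r} folds in
    the sorted multiset of (bond type, neighbor label_{r-1}). String tokens
    are stable across processes (no hash randomization involved).
    """
    labels = [f"{a.GetSymbol()}|{int(a.GetIsAromatic())}" for a in mol.GetAtoms()]
    for _ in range(radius):
        new_labels = []
        for atom in mol.GetAtoms():
            i = atom.GetIdx()
            neigh = []
            for bond in atom.GetBonds():
                j = bond.GetOtherAtomIdx(i)
                neigh.append(f"{bond.GetSmarts(allBondsExplicit=True) or '-'}{labels[j]}")
            neigh.sort()
            new_labels.append(labels[i] + "(" + ",".join(neigh) + ")")
        labels = new_labels
    return labels


def smiles_to_graph(smiles: str, radius: int, vocab: Vocabulary,
                    update_vocab: bool = False) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    With ``update_vocab`` (training time) unseen environment tokens are
    added to the vocabulary; otherwise they map to the unknown id.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None or mol.GetNumAtoms() == 0:
        raise FeaturizationError(f"unparsable or empty SMILES: {smiles!r}")
    tokens = atom_environment_tokens(mol, radius)
    if update_vocab:
        ids = np.array([vocab.add(t) for t in tokens], dtype=np.int64)
    else:
        ids = np.array([vocab.lookup(t) for t in tokens], dtype=np.int64)
    n = mol.GetNumAtoms()
    adj = np.eye(n)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
    return MolecularGraph(atom_ids=ids, adjacency=adj, n_atom=n)


def sequence_ngrams(sequence: str, n: int) -> list[str]:
    """All stride-1 windows of length ``n``."""
    if len(sequence) < n:
        raise FeaturizationError(
            f"sequence of length {len(sequence)} shorter than n-gram size {n}"
        )
    return [sequence[k:k + n] for k in range(len(sequence) - n + 1)]


def protein_to_ngrams(sequence: str, n: int, vocab: Vocabulary,
                      update_vocab: bool = False) -> ProteinTokens:
    """Tokenize a protein into overlapping n-gram ids (length = L - n + 1)."""
    grams = sequence_ngrams(sequence, n)
    if update_vocab:
        ids = np.array([vocab.add(g) for g in grams], dtype=np.int64)
    else:
        ids = np.array([vocab.lookup(g) for g in grams], dtype=np.int64)
    return ProteinTokens(token_ids=ids, length=len(grams))


def train_ngram_embeddings(corpus: list[ProteinTokens], vocab: Vocabulary,
                           dim: int = 64, window: int = 5, epochs: int = 5,
                           seed: int = 0, negatives: int = 5,
                           lr: float = 0.025) -> EmbeddingTable:
    """Skip-gram-with-negative-sampling embeddings for protein n-grams.

    Each protein's n-gram token sequence is one training sentence.
    Deterministic given ``seed``. Row 0 of the returned table is the
    zero padding vector; the final row (unknown token) is the mean of
    all trained vectors, a neutral stand-in for unseen n-grams.
    """
    if not corpus:
        raise ValueError("empty corpus")
    sentences = [p.token_ids for p in corpus]
    vecs = train_skipgram(
        sentences, n_ids=vocab.n_rows, dim=dim, window=window,
        epochs=epochs, negatives=negatives, lr=lr, seed=seed,
    )
    vecs[0] = 0.0
    used = sorted({int(t) for s in sentences for t in s})
    vecs[vocab.unk_id] = vecs[used].mean(axis=0)
    return EmbeddingTable(vectors=vecs, dim=dim)


def save_embeddings(table: EmbeddingTable, vocab: Vocabulary, path) -> None:
    """Serialize an embedding table plus its vocabulary to one .npz checkpoint."""
    tokens = list(vocab.token_to_id.keys())
    np.savez(
        path,
        format_version=np.array([1]),
        vectors=table.vectors,
        tokens=np.array(tokens, dtype=object),
    )


def load_embeddings(path) -> tuple[EmbeddingTable, Vocabulary]:
    with np.load(path, allow_pickle=True) as data:
        vectors = data["vectors"]
        tokens = list(data["tokens"])
    vocab = Vocabulary()
    for t in tokens:
        vocab.add(str(t))
    return EmbeddingTable(vectors=vectors, dim=vectors.shape[1]), vocab
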