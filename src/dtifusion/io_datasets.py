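"""Interaction-dataset I/O, token vocabularies and cross-validation splits.

The on-disk format is a headerless UTF-8 table with three columns —
SMILES, amino-acid sequence, binary label — separated by tabs (single
spaces are auto-detected for compatibility with published CPI benchmark
dumps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

MIN_SEQ_LEN = 3  # shortest sequence that still yields one 3-gram token


class DatasetFormatError(ValueError):
    """Raised for malformed dataset files (carries the offending line number)."""


@dataclass(frozen=True)
class InteractionRecord:
    """One (drug SMILES, protein sequence, binary interaction label) example."""

    smiles: str
    sequence: str
    label: int

    def __post_init__(self):
        if not self.smiles:
            raise ValueError("empty SMILES")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class Vocabulary:
    """Token -> id map with reserved ids: 0 = padding, size+1 = unknown.

    Real tokens receive contiguous ids 1..size in first-occurrence order,
    so a vocabulary built from the same token stream is identical across
    runs.
    """

    token_to_id: dict = field(default_factory=dict)
    pad_id: int = 0

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    @property
    def unk_id(self) -> int:
        return self.size + 1

    @property
    def n_rows(self) -> int:
        """Rows an embedding table needs: pad + tokens + unk."""
        return self.size + 2

    def add(self, token) -> int:
        tid = self.token_to_id.get(token)
        if tid is None:
            tid = len(self.token_to_id) + 1
            self.token_to_id[token] = tid
        return tid

    def lookup(self, token) -> int:
        """Id of ``token``; unseen tokens map to the reserved unknown id."""
        return self.token_to_id.get(token, self.unk_id)


def build_vocab(tokens: Iterable) -> Vocabulary:
    """Build a vocabulary in first-occurrence order (training split only)."""
    vocab = Vocabulary()
    for tok in tokens:
        vocab.add(tok)
    if vocab.size == 0:
        logger.warning("build_vocab: empty token stream -> size-0 vocabulary")
    return vocab


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]


def _split_line(line: str, lineno: int) -> tuple[str, str, str]:
    if "\t" in line:
        parts = line.split("\t")
    else:
        parts = line.split(" ")
    parts = [p for p in parts if p != ""]
    if len(parts) != 3:
        raise DatasetFormatError(
            f"line {lineno}: expected 3 fields (smiles, sequence, label), got {len(parts)}"
        )
    return parts[0], parts[1], parts[2]


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read interaction records from a 3-column TSV (or space-separated) file.

    Records whose sequence is shorter than the 3-gram window are rejected
    with a warning; an invalid label is fatal and names the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[InteractionRecord] = []
    n_rejected = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            smiles, sequence, label_s = _split_line(line, lineno)
            if label_s not in ("0", "1"):
                raise DatasetFormatError(
                    f"line {lineno}: label must be 0 or 1, got {label_s!r}"
                )
            if len(sequence) < MIN_SEQ_LEN:
                logger.warning(
                    "line %d: sequence shorter than %d residues, record rejected",
                    lineno, MIN_SEQ_LEN,
                )
                n_rejected += 1
                continue
            records.append(InteractionRecord(smiles, sequence, int(label_s)))
    if n_rejected:
        logger.warning("read_interactions: rejected %d short-sequence records", n_rejected)
    if not records:
        logger.warning("read_interactions: %s produced no records", path)
    return records


def write_interactions(records: Sequence[InteractionRecord], path: str | Path) -> None:
    """Write records as tab-separated smiles/sequence/label lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.sequence}\t{rec.label}\n")


def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Deterministic stratified k-fold split of ``range(len(labels))``.

    Each test fold's class ratio is within one example of the global
    ratio; every index appears in exactly one test fold.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls in (0, 1):
        n_cls = int((labels == cls).sum())
        if n_cls < k:
            raise ValueError(f"class {cls} has {n_cls} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_index, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds.append(FoldSplit(fold_index, tuple(int(i) for i in train_idx),
                               tuple(int(i) for i in test_idx)))
    return folds


def dataset_summary(records: Sequence[InteractionRecord]) -> dict:
    """Counts and length statistics mirroring benchmark-table summaries."""
    n = len(records)
    n_pos = sum(r.label for r in records)
    smiles_lens = [len(r.smiles) for r in records]
    seq_lens = [len(r.sequence) for r in records]
    return {
        "n_records": n,
        "n_positive": n_pos,
        "n_negative": n - n_pos,
        "n_drugs": len({r.smiles for r in records}),
        "n_proteins": len({r.sequence for r in records}),
        "smiles_len_mean": float(np.mean(smiles_lens)) if n else 0.0,
        "smiles_len_max": int(max(smiles_lens)) if n else 0,
        "sequence_len_mean": float(np.mean(seq_lens)) if n else 0.0,
        "sequence_len_max": int(max(seq_lens)) if n else 0,
    }
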