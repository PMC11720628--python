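"""Latent-semantic-analysis embeddings for categorical values, plus the one-hot baseline.

The categorical part of a claims table is summarized by a binary co-occurrence
matrix X (c categories × p actions): X[i, j] = 1 iff category i appears in
action j, with a single vocabulary pooled over *all* categorical columns
(tokens namespaced by column). A rank-k truncated SVD X ≈ C S Pᵀ yields a
k-dimensional vector per category — the rows of CS = XP — which are then
l2-normalized, so cosine similarity between categories is a plain dot product.

Cardinalities in claims data reach the hundreds of thousands, so the one-hot
(dummy) representation of Eq-style indicator vectors explodes the feature
space; the k-dimensional LSA vectors (k = 3 by default) replace it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .schema import ClaimsTable


def one_hot_encode(value: str, column_vocab: Sequence[str]) -> np.ndarray:
    """Indicator vector over an ordered vocabulary; all-zero for unseen values."""
    if len(column_vocab) == 0:
        raise ValueError("vocabulary must be nonempty")
    x = np.zeros(len(column_vocab))
    for i, c in enumerate(column_vocab):
        if value == c:
            x[i] = 1.0
            break
    return x


@dataclass(frozen=True)
class CategoryVocabulary:
    """Pooled, ordered vocabulary of (column, token) pairs across all categorical columns."""

    entries: tuple[tuple[str, str], ...]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        idx = {e: i for i, e in enumerate(self.entries)}
        if len(idx) != len(self.entries):
            raise ValueError("vocabulary entries must be unique")
        object.__setattr__(self, "_index", idx)

    def __len__(self) -> int:
        return len(self.entries)

    def index(self, column: str, token: str) -> int:
        return self._index[(column, token)]

    def __contains__(self, key) -> bool:
        return key in self._index


@dataclass
class CooccurrenceMatrix:
    """Binary category × action matrix (sparse CSR) with its vocabulary."""

    X: sp.csr_matrix
    vocabulary: CategoryVocabulary

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def build_cooccurrence(table: ClaimsTable) -> CooccurrenceMatrix:
    """Construct the binary co-occurrence matrix from a claims table.

    Rows follow schema column order, tokens sorted lexicographically within a
    column, so the vocabulary (and hence the embedding) is invariant to
    action-row order. Column j corresponds to the j-th action row; each
    action contributes exactly one 1 per categorical schema column.
    """
    schema = table.schema
    if len(table) == 0 or not schema.categorical_columns:
        raise ValueError("need a nonempty table with at least one categorical column")
    p = len(table)
    entries: list[tuple[str, str]] = []
    rows_parts, cols_parts = [], []
    offset = 0
    for col in schema.categorical_columns:
        tokens = sorted(table.data[col].unique())
        lookup = {t: offset + i for i, t in enumerate(tokens)}
        entries.extend((col, t) for t in tokens)
        rows_parts.append(table.data[col].map(lookup).to_numpy(dtype=np.int64))
        cols_parts.append(np.arange(p, dtype=np.int64))
        offset += len(tokens)
    rows = np.concatenate(rows_parts)
    cols = np.concatenate(cols_parts)
    X = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(offset, p), dtype=np.float64
    )
    return CooccurrenceMatrix(X, CategoryVocabulary(tuple(entries)))


def _fix_signs(U: np.ndarray, s: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve SVD sign indeterminacy: make the largest-|·| entry of each P
    column (row of Vt) positive, ties broken by lowest index."""
    for r in range(Vt.shape[0]):
        row = Vt[r]
        j = int(np.argmax(np.abs(row)))  # argmax returns the lowest index on ties
        if row[j] < 0:
            Vt[r] = -row
            U[:, r] = -U[:, r]
    return U, Vt


@dataclass
class EmbeddingTable:
    """Fitted LSA embedding: (column, token) → unit k-vector.

    ``matrix`` holds the normalized embeddings row-aligned with the
    vocabulary; ``embed`` returns a zero vector for unseen tokens so they
    contribute neutrally to downstream mean aggregation.
    """

    k: int
    vocabulary: CategoryVocabulary
    matrix: np.ndarray  # (c, k), rows l2-normalized (or zero)
    singular_values: np.ndarray  # (k,), nonincreasing
    columns: tuple[str, ...]

    def embed(self, column: str, value: str) -> np.ndarray:
        if column not in self.columns:
            raise KeyError(f"unknown categorical column {column!r}")
        key = (column, value)
        if key in self.vocabulary:
            return self.matrix[self.vocabulary.index(column, value)].copy()
        return np.zeros(self.k)

    def column_matrix(self, column: str) -> tuple[list[str], np.ndarray]:
        """Tokens of one column and their embedding rows, vocabulary order."""
        idx = [i for i, (c, _) in enumerate(self.vocabulary.entries) if c == column]
        tokens = [self.vocabulary.entries[i][1] for i in idx]
        return tokens, self.matrix[idx]

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "claimscope-embedding-v1",
            "k": self.k,
            "sign_convention": "largest-abs-P-entry-positive",
            "columns": list(self.columns),
            "singular_values": self.singular_values.tolist(),
            "entries": [[c, t] for c, t in self.vocabulary.entries],
            "vectors": self.matrix.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"],
            vocabulary=CategoryVocabulary(tuple((c, t) for c, t in d["entries"])),
            matrix=np.asarray(d["vectors"]),
            singular_values=np.asarray(d["singular_values"]),
            columns=tuple(d["columns"]),
        )


def fit_lsa(cooc: CooccurrenceMatrix, k: int = 3,
            columns: Optional[tuple[str, ...]] = None) -> EmbeddingTable:
    """Rank-k truncated SVD of the co-occurrence matrix; rows of CS = XP,
    l2-normalized, with a deterministic sign convention.

    Requests beyond the matrix rank are clamped with a warning. Small
    matrices use a dense SVD; large ones an iterative sparse solver.
    """
    X = cooc.X
    c, p = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    k_max = min(c, p)
    if k > k_max:
        warnings.warn(f"k={k} exceeds min(c, p)={k_max}; clamping")
        k = k_max
    if min(c, p) <= 200 or k >= min(c, p) - 1:
        U, s, Vt = np.linalg.svd(X.toarray(), full_matrices=False)
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
    else:
        U, s, Vt = svds(X, k=k, random_state=0)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    U, Vt = _fix_signs(U, s, Vt)
    raw = U * s  # rows of CS = XP
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    normalized = np.divide(raw, norms, out=np.zeros_like(raw), where=norms > 0)
    cols = columns if columns is not None else tuple(
        dict.fromkeys(c_ for c_, _ in cooc.vocabulary.entries)
    )
    return EmbeddingTable(k=k, vocabulary=cooc.vocabulary, matrix=normalized,
                          singular_values=s, columns=cols)


def fit_embeddings(table: ClaimsTable, k: int = 3) -> EmbeddingTable:
    """Convenience: build the co-occurrence matrix and fit rank-k embeddings."""
    cooc = build_cooccurrence(table)
    return fit_lsa(cooc, k=k, columns=table.schema.categorical_columns)


class OneHotEncoder:
    """Per-column one-hot (dummy) encoding baseline, vocabulary sorted."""

    def __init__(self, table: ClaimsTable):
        self.vocab: dict[str, list[str]] = {
            col: sorted(table.data[col].unique())
            for col in table.schema.categorical_columns
        }

    def encode(self, column: str, value: str) -> np.ndarray:
        return one_hot_encode(value, self.vocab[column])

    def cardinality(self, column: str) -> int:
        return len(self.vocab[column])
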