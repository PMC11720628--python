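"""Per-practitioner profile aggregation and standardization.

Each entity's variable-length action history collapses into one fixed-length
vector: every numerical column contributes six summary statistics (sum, mean,
median, standard deviation, minimum, maximum) and every categorical column
contributes the mean of its k-dimensional embeddings. Profile dimensionality
is therefore d = 6·m + k·q for m numerical and q categorical columns.

A :class:`FeatureGroupMap` records which expanded columns came from which
original feature; Shapley attributions over expanded columns are summed per
group to recover per-feature importances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sparse

from .embedding import EmbeddingTable, OneHotEncoder
from .schema import ClaimsTable

NUM_STATS = ("sum", "mean", "median", "std", "min", "max")


class AggregationError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureGroupMap:
    """Ordered partition of expanded profile columns into original features."""

    groups: tuple[tuple[str, tuple[int, ...]], ...]  # (feature, expanded indices)
    expanded_names: tuple[str, ...]

    def __post_init__(self):
        seen: set[int] = set()
        for _, idx in self.groups:
            if seen & set(idx):
                raise ValueError("expanded columns must belong to exactly one group")
            seen |= set(idx)
        if seen != set(range(len(self.expanded_names))):
            raise ValueError("groups must partition the expanded column range")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.groups)

    def indices(self, feature: str) -> tuple[int, ...]:
        for name, idx in self.groups:
            if name == feature:
                return idx
        raise KeyError(feature)

    def __len__(self) -> int:
        return len(self.groups)


@dataclass
class ProfileMatrix:
    """One feature row per practitioner.

    ``standardization`` is None for raw profiles; after :func:`standardize`
    it holds per-column (mean, scale) so held-out entities can be projected
    onto the same scale.
    """

    entity_ids: list[str]
    values: np.ndarray  # (n_entities, d)
    group_map: FeatureGroupMap
    standardization: Optional[tuple[np.ndarray, np.ndarray]] = None

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.entity_ids.index(entity_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.group_map.expanded_names))
        df.insert(0, "entity_id", self.entity_ids)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def aggregate_numerical(values: Sequence[float]) -> np.ndarray:
    """Six summary statistics (sum, mean, median, std, min, max) of the
    non-missing values; population (ddof=0) standard deviation."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise AggregationError("all values missing")
    return np.array([v.sum(), v.mean(), np.median(v), v.std(ddof=0), v.min(), v.max()])


def aggregate_embedded(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Componentwise mean of an entity's embedded categorical values."""
    arr = np.asarray(list(vectors), dtype=float)
    if arr.size == 0:
        raise AggregationError("no vectors to aggregate")
    return arr.mean(axis=0)


def _numerical_block(table: ClaimsTable) -> tuple[np.ndarray, list[str], list[str]]:
    schema = table.schema
    eid_col = schema.entity_id_column
    entity_ids = table.entities()
    grouped = table.data.groupby(eid_col, sort=False)
    blocks, names = [], []
    for col in schema.numerical_columns:
        agg = grouped[col].agg(
            ["sum", "mean", "median", lambda s: s.std(ddof=0), "min", "max"]
        )
        all_missing = grouped[col].count() == 0
        if all_missing.any():
            bad = all_missing[all_missing].index[0]
            raise AggregationError(
                f"entity {bad!r} has no non-missing values for feature {col!r}"
            )
        block = agg.to_numpy(dtype=float)
        block[:, 3] = np.nan_to_num(block[:, 3])  # singleton std -> 0
        blocks.append(block)
        names.extend(f"{col}__{s}" for s in NUM_STATS)
    values = np.hstack(blocks) if blocks else np.empty((len(entity_ids), 0))
    return values, names, entity_ids


def build_profiles(table: ClaimsTable, emb: EmbeddingTable) -> ProfileMatrix:
    """Unstandardized profile matrix: numerical blocks (schema order, 6 stats
    each) then categorical embedding blocks (schema order, k dims each)."""
    schema = table.schema
    num_values, names, entity_ids = _numerical_block(table)

    cat_blocks = []
    for col in schema.categorical_columns:
        tokens, vecs = emb.column_matrix(col)
        lookup = {t: i for i, t in enumerate(tokens)}
        codes = table.data[col].map(lookup)
        # unseen tokens -> zero vector (neutral under the mean)
        vec_rows = np.zeros((len(table.data), emb.k))
        known = codes.notna().to_numpy()
        vec_rows[known] = vecs[codes[known].to_numpy(dtype=int)]
        per_action = pd.DataFrame(vec_rows, index=table.data.index)
        means = per_action.groupby(table.entity_ids, sort=False).mean()
        cat_blocks.append(means.loc[entity_ids].to_numpy())
        names.extend(f"{col}__emb{j}" for j in range(emb.k))

    parts = ([num_values] if num_values.shape[1] else []) + cat_blocks
    values = np.hstack(parts)
    group_map = _make_group_map(schema.numerical_columns, 6,
                                schema.categorical_columns, emb.k, names)
    return ProfileMatrix(entity_ids, values, group_map)


def build_onehot_profiles(table: ClaimsTable, encoder: Optional[OneHotEncoder] = None
                          ) -> ProfileMatrix:
    """One-hot baseline: categorical blocks are within-entity relative
    frequencies over each column's full vocabulary (mean of indicator vectors)."""
    schema = table.schema
    if encoder is None:
        encoder = OneHotEncoder(table)
    num_values, names, entity_ids = _numerical_block(table)
    ent_lookup = {e: i for i, e in enumerate(entity_ids)}
    ent_idx = table.entity_ids.map(ent_lookup).to_numpy(dtype=np.int64)
    ent_counts = np.bincount(ent_idx, minlength=len(entity_ids)).astype(float)
    cat_blocks, widths = [], []
    for col in schema.categorical_columns:
        vocab = encoder.vocab[col]
        tok_lookup = {t: j for j, t in enumerate(vocab)}
        tok_idx = table.data[col].map(tok_lookup).to_numpy(dtype=np.int64)
        # sparse count accumulation keeps high-cardinality columns tractable
        counts = sparse.csr_matrix(
            (np.ones(len(tok_idx)), (ent_idx, tok_idx)),
            shape=(len(entity_ids), len(vocab)),
        )
        cat_blocks.append(counts.toarray() / ent_counts[:, None])
        names.extend(f"{col}__is_{t}" for t in vocab)
        widths.append(len(vocab))
    parts = ([num_values] if num_values.shape[1] else []) + cat_blocks
    values = np.hstack(parts)
    group_map = _make_group_map(schema.numerical_columns, 6,
                                schema.categorical_columns, widths, names)
    return ProfileMatrix(entity_ids, values, group_map)


def _make_group_map(num_cols, num_width, cat_cols, cat_width, names) -> FeatureGroupMap:
    groups = []
    pos = 0
    for col in num_cols:
        groups.append((col, tuple(range(pos, pos + num_width))))
        pos += num_width
    widths = cat_width if isinstance(cat_width, list) else [cat_width] * len(cat_cols)
    for col, w in zip(cat_cols, widths):
        groups.append((col, tuple(range(pos, pos + w))))
        pos += w
    return FeatureGroupMap(tuple(groups), tuple(names))


def standardize(profiles: ProfileMatrix) -> ProfileMatrix:
    """Column-wise z-scoring: subtract the mean, divide by the population
    standard deviation; constant columns get scale 1 (become all-zero)."""
    if len(profiles.entity_ids) < 2:
        raise ValueError("standardization needs at least 2 entities")
    mean = profiles.values.mean(axis=0)
    scale = profiles.values.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return ProfileMatrix(
        entity_ids=list(profiles.entity_ids),
        values=(profiles.values - mean) / scale,
        group_map=profiles.group_map,
        standardization=(mean, scale),
    )


def apply_standardization(profiles: ProfileMatrix, mean: np.ndarray, scale: np.ndarray
                          ) -> ProfileMatrix:
    """Project (held-out) profiles onto a previously fitted scale."""
    return ProfileMatrix(
        entity_ids=list(profiles.entity_ids),
        values=(profiles.values - mean) / scale,
        group_map=profiles.group_map,
        standardization=(mean, scale),
    )
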