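"""Claims data model: schema definition, long-format table container, I/O and activity filter.

A claims table is *long-format*: one row per medical act, keyed by a pseudonymous
practitioner (entity) identifier, with categorical columns (discipline, location,
billing / nomenclature code, ...) and numerical columns (billed amount, ...).
Entity identifiers are opaque tokens; nothing in this package attempts
re-identification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

#: reserved token for missing categorical cells; participates in embedding
#: like any other category so row dimensionality stays fixed.
MISSING_TOKEN = "__missing__"


class SchemaError(ValueError):
    """Input does not conform to the declared feature schema."""


class RowParseError(ValueError):
    """A data cell could not be parsed; carries the offending line number."""


@dataclass(frozen=True)
class FeatureSchema:
    """Declares which columns of a claims file play which role.

    Column order is significant: it fixes the order of expanded feature
    blocks in downstream profile matrices, and hence the layout of every
    attribution vector.

    Parameters
    ----------
    entity_id_column : str
        Column holding the pseudonymous practitioner identifier.
    categorical_columns : sequence of str
        Opaque-token columns (no ordinal meaning).
    numerical_columns : sequence of str
        Real-valued columns; missing cells are recorded as missing, never 0.
    period_column : str, optional
        Column holding the period (e.g. year) of the act, used by the
        per-period activity filter.
    """

    entity_id_column: str
    categorical_columns: tuple[str, ...] = ()
    numerical_columns: tuple[str, ...] = ()
    period_column: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "categorical_columns", tuple(self.categorical_columns))
        object.__setattr__(self, "numerical_columns", tuple(self.numerical_columns))
        cat, num = set(self.categorical_columns), set(self.numerical_columns)
        if len(cat) != len(self.categorical_columns) or len(num) != len(self.numerical_columns):
            raise SchemaError("duplicate column names within a role")
        special = {self.entity_id_column} | ({self.period_column} if self.period_column else set())
        if cat & num or cat & special or num & special:
            raise SchemaError("schema column roles must be disjoint")
        if not cat and not num:
            raise SchemaError("schema needs at least one categorical or numerical column")

    @property
    def feature_columns(self) -> tuple[str, ...]:
        return self.numerical_columns + self.categorical_columns

    @property
    def all_columns(self) -> tuple[str, ...]:
        cols = (self.entity_id_column,) + self.feature_columns
        if self.period_column:
            cols += (self.period_column,)
        return cols

    def to_dict(self) -> dict:
        return {
            "entity_id_column": self.entity_id_column,
            "categorical_columns": list(self.categorical_columns),
            "numerical_columns": list(self.numerical_columns),
            "period_column": self.period_column,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            entity_id_column=d["entity_id_column"],
            categorical_columns=tuple(d.get("categorical_columns", ())),
            numerical_columns=tuple(d.get("numerical_columns", ())),
            period_column=d.get("period_column"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ClaimsTable:
    """Validated long-format claims table: one row per medical act.

    ``data`` is a pandas DataFrame whose columns cover the schema.
    Categorical cells are strings (missing → :data:`MISSING_TOKEN`),
    numerical cells are float64 with NaN marking *missing* (never zero).
    """

    data: pd.DataFrame
    schema: FeatureSchema

    def __post_init__(self):
        missing = [c for c in self.schema.all_columns if c not in self.data.columns]
        if missing:
            raise SchemaError(f"table is missing schema columns: {missing}")
        df = self.data
        eid = df[self.schema.entity_id_column]
        if eid.isna().any() or (eid.astype(str).str.len() == 0).any():
            raise SchemaError("every row must carry a non-empty entity ID")
        df[self.schema.entity_id_column] = eid.astype(str)
        for c in self.schema.categorical_columns:
            col = df[c].astype(object)
            col = col.where(~pd.isna(col), MISSING_TOKEN).astype(str)
            df[c] = col.replace("", MISSING_TOKEN)
        for c in self.schema.numerical_columns:
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
            if np.isinf(df[c].to_numpy()).any():
                raise SchemaError(f"non-finite value in numerical column {c!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def entity_ids(self) -> pd.Series:
        return self.data[self.schema.entity_id_column]

    def entities(self) -> list[str]:
        """Distinct entity IDs in order of first appearance."""
        return list(dict.fromkeys(self.entity_ids))

    def subset(self, entity_id: str) -> pd.DataFrame:
        return self.data[self.entity_ids == entity_id]

    def write_csv(self, path: str | Path, delimiter: str = ",") -> None:
        self.data.to_csv(path, sep=delimiter, index=False)


def read_claims(
    path: str | Path,
    schema: FeatureSchema,
    delimiter: str = ",",
    decimal: str = ".",
    quotechar: str = '"',
) -> ClaimsTable:
    """Read and validate a delimited claims file.

    Missing numerical cells stay missing (NaN); an unparseable numeric cell
    raises :class:`RowParseError` naming the 1-based file line. Row order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep=delimiter, quotechar=quotechar, dtype=str,
        keep_default_na=False, na_values=[""],
    )
    missing = [c for c in schema.all_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"file {path.name} lacks required column(s): {missing}")
    for c in schema.numerical_columns:
        raw = df[c]
        cleaned = raw.str.replace(decimal, ".", regex=False) if decimal != "." else raw
        values = pd.to_numeric(cleaned, errors="coerce")
        bad = values.isna() & raw.notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise RowParseError(
                f"unparseable numeric value {raw.iloc[i]!r} in column {c!r} "
                f"at line {i + 2} of {path.name}"
            )
        df[c] = values
    return ClaimsTable(df, schema)


def filter_min_actions(
    table: ClaimsTable, min_actions: int = 50, per_period: bool = False
) -> ClaimsTable:
    """Keep entities with *strictly more than* ``min_actions`` recorded acts.

    With ``per_period=True`` (requires a period column) an entity is retained
    only if every period it is active in exceeds the threshold. Idempotent.
    """
    if min_actions < 0:
        raise ValueError("min_actions must be >= 0")
    schema = table.schema
    if per_period:
        if schema.period_column is None:
            raise SchemaError("per_period filtering requires a period column in the schema")
        counts = table.data.groupby(
            [schema.entity_id_column, schema.period_column], sort=False
        ).size()
        ok_per_entity = counts.gt(min_actions).groupby(level=0).all()
        keep = set(ok_per_entity[ok_per_entity].index)
    else:
        counts = table.entity_ids.value_counts()
        keep = set(counts[counts > min_actions].index)
    mask = table.entity_ids.isin(keep)
    return ClaimsTable(table.data[mask].reset_index(drop=True), schema)
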