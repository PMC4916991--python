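"""Flat-table I/O for bioactivity measurement and publication data.

All pipeline stages exchange plain UTF-8 CSV/TSV tables with a header row.
Each table kind has a declared :class:`TableSchema` (column order, semantic
types, sort key); writers emit full-precision ``repr``-style floats so that a
write/read round trip reproduces every value exactly, and readers never
filter — a file with *n* data rows yields *n* rows or an error.

The measurement table carries one row per potency determination: compound,
assay, target (with organism and type), ChEMBL-style assay confidence score
and relationship type, the activity type (Ki, IC50, ...), the relation
qualifier ("=", ">", "<", "~", ">=", "<="), the numeric potency value with
its unit, and the source document. Approximate relations are *kept* at read
time; excluding them is the curation stage's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "SchemaError",
    "IntegrityError",
    "TableSchema",
    "MEASUREMENT_SCHEMA",
    "PUBLICATION_SCHEMA",
    "RECORD_SCHEMA",
    "PUBLICATION_PROFILE_SCHEMA",
    "COMPOUND_PROFILE_SCHEMA",
    "read_measurements",
    "read_publications",
    "read_table",
    "write_table",
]

#: Unit strings the pipeline can convert to nM.
CONVERTIBLE_UNITS = ("nM", "uM", "M")

#: Relation qualifiers treated as approximate ("e.g." in the source
#: vocabulary is open-ended, so >= and <= are included).
APPROXIMATE_RELATIONS = (">", "<", "~", ">=", "<=")


class SchemaError(ValueError):
    """A table does not match its declared schema (missing column, bad type)."""


class IntegrityError(ValueError):
    """A referential or uniqueness constraint is violated."""


@dataclass(frozen=True)
class TableSchema:
    """Declared column order, per-column semantic types and sort key.

    ``dtypes`` maps column name to one of ``"str"``, ``"int"``, ``"float"``.
    ``key`` is the column tuple used to sort rows deterministically on write;
    an empty key preserves the caller's row order (used for matrix-style
    tables whose row order is a declared bin order, not a sort order).
    """

    name: str
    columns: tuple[str, ...]
    dtypes: Mapping[str, str] = field(default_factory=dict)
    key: tuple[str, ...] = ()

    def dtype_of(self, column: str) -> str:
        return self.dtypes.get(column, "str")


MEASUREMENT_SCHEMA = TableSchema(
    name="measurements",
    columns=(
        "compound_id",
        "assay_id",
        "target_id",
        "target_organism",
        "target_type",
        "confidence_score",
        "relationship_type",
        "activity_type",
        "relation",
        "value",
        "units",
        "doc_id",
    ),
    dtypes={"confidence_score": "int", "value": "float"},
    key=(
        "doc_id",
        "assay_id",
        "compound_id",
        "target_id",
        "activity_type",
        "relation",
        "value",
        "units",
    ),
)

PUBLICATION_SCHEMA = TableSchema(
    name="publications",
    columns=("doc_id", "journal", "year", "doc_type"),
    dtypes={"year": "int"},
    key=("doc_id",),
)

RECORD_SCHEMA = TableSchema(
    name="records",
    columns=(
        "compound_id",
        "target_id",
        "n_publications",
        "n_measurements",
        "n_distinct_values",
        "record_class",
        "log_range",
        "doc_ids",
        "values_nM",
    ),
    dtypes={
        "n_publications": "int",
        "n_measurements": "int",
        "n_distinct_values": "int",
        "log_range": "float",
    },
    key=("compound_id", "target_id"),
)

PUBLICATION_PROFILE_SCHEMA = TableSchema(
    name="publication_profiles",
    columns=(
        "doc_id",
        "journal",
        "year",
        "n_assays",
        "n_targets",
        "n_compounds",
        "category",
    ),
    dtypes={
        "year": "int",
        "n_assays": "int",
        "n_targets": "int",
        "n_compounds": "int",
    },
    key=("doc_id",),
)

COMPOUND_PROFILE_SCHEMA = TableSchema(
    name="compound_profiles",
    columns=("compound_id", "degree", "n_publications", "subset"),
    dtypes={"degree": "int", "n_publications": "int"},
    key=("compound_id",),
)


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() == ".tsv" else ","


def _coerce(frame: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    """Validate column presence and convert typed columns, failing fast.

    Unparsable numeric cells are reported with their file line number
    (header is line 1, first data row line 2).
    """
    missing = [c for c in schema.columns if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{schema.name} table is missing mandatory column(s): "
            + ", ".join(missing)
        )
    frame = frame.loc[:, list(schema.columns)].copy()
    for col in schema.columns:
        kind = schema.dtype_of(col)
        if kind == "str":
            frame[col] = frame[col].fillna("").astype(str)
            continue
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        bad |= frame[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{schema.name} table: unparsable {kind} value "
                f"{frame[col].iloc[bad.idxmax()]!r} in column {col!r} "
                f"(file line {line})"
            )
        frame[col] = numeric.astype(int if kind == "int" else float)
    return frame


def read_table(
    path: str | Path, schema: TableSchema, *, sep: str | None = None
) -> pd.DataFrame:
    """Read any declared table kind; header required, order-insensitive."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    return _coerce(frame, schema)


def read_measurements(
    path: str | Path,
    schema: TableSchema = MEASUREMENT_SCHEMA,
    *,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a measurement table; one row per potency determination.

    The relation column is normalized only by trimming whitespace, with empty
    cells defaulting to "="; approximate relations survive reading untouched.
    Raises :class:`SchemaError` for missing columns or unparsable numerics.
    """
    frame = read_table(path, schema, sep=sep)
    relation = frame["relation"].str.strip()
    frame["relation"] = relation.where(relation != "", "=")
    nonpos = frame["value"] <= 0
    if nonpos.any():
        line = int(nonpos.idxmax()) + 2
        raise SchemaError(
            f"measurements table: non-positive potency value "
            f"{frame['value'].iloc[nonpos.idxmax()]} (file line {line})"
        )
    return frame.reset_index(drop=True)


def read_publications(
    path: str | Path, *, sep: str | None = None
) -> pd.DataFrame:
    """Read the publication table; ``doc_id`` must be unique."""
    frame = read_table(path, PUBLICATION_SCHEMA, sep=sep)
    dupes = frame.loc[frame["doc_id"].duplicated(), "doc_id"].unique()
    if len(dupes):
        raise IntegrityError(
            "duplicate doc_id(s) in publication table: " + ", ".join(sorted(dupes))
        )
    return frame.reset_index(drop=True)


def write_table(
    rows: pd.DataFrame,
    path: str | Path,
    schema: TableSchema | None = None,
    *,
    sep: str | None = None,
) -> int:
    """Write a result table as UTF-8 CSV/TSV and return the row count.

    Columns follow the schema's declared order and rows are sorted by its
    key, so identical content always yields identical bytes. Floats are
    written at full ``repr`` precision, making round trips exact.
    """
    path = Path(path)
    frame = rows
    if schema is not None:
        missing = [c for c in schema.columns if c not in frame.columns]
        if missing:
            raise SchemaError(
                f"{schema.name} table to write is missing column(s): "
                + ", ".join(missing)
            )
        frame = frame.loc[:, list(schema.columns)]
        if schema.key:
            frame = frame.sort_values(list(schema.key), kind="mergesort")
    frame.to_csv(path, sep=_sep_for(path, sep), index=False, encoding="utf-8")
    return len(frame)
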