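"""Compound-target activity records: aggregation, classification, ranges.

An *activity record* is a unique compound-target combination together with
every publication and potency value reporting it. A compound may be tested
against the same target in several assays, within one paper or across many;
all those measurements pool into a single record. Records are then placed
in a four-way decision tree:

* one publication, one potency value (the dominant case in the literature),
* one publication, replicate potency values,
* multiple publications with varying values (independent re-measurement),
* multiple publications all reporting one identical value — the signature
  of a potency *referenced* from an earlier paper rather than re-measured.

Potencies are normalized to nM before pooling. Two normalized values count
as "the same" iff they agree after rounding to three significant figures,
absorbing the trivial formatting differences a cited value accumulates. The
logarithmic potency range of a record, log10(max) - log10(min) over those
rounded values, measures the spread of experimental assessments in orders
of magnitude; it is zero exactly when the record has one distinct value.
"""

from __future__ import annotations

import warnings
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "RecordClass",
    "UNIT_TO_NM",
    "RANGE_BINS",
    "normalize_to_nM",
    "round_sig",
    "classify_record",
    "log_range",
    "build_records",
    "range_histogram",
]

UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "M": 1e9}

#: Log-range display bins, in orders of magnitude.
RANGE_BINS = ("<=1", "(1,2]", "(2,3]", ">3")


class RecordClass(str, Enum):
    SINGLE_PUB_SINGLE_VALUE = "SINGLE_PUB_SINGLE_VALUE"
    SINGLE_PUB_MULTI_VALUE = "SINGLE_PUB_MULTI_VALUE"
    MULTI_PUB_VARYING_VALUES = "MULTI_PUB_VARYING_VALUES"
    MULTI_PUB_SAME_VALUE = "MULTI_PUB_SAME_VALUE"


def normalize_to_nM(value: float, units: str) -> float:
    """Convert a potency to nM; curation guarantees a convertible unit."""
    try:
        factor = UNIT_TO_NM[units]
    except KeyError:
        raise ValueError(f"cannot convert unit {units!r} to nM") from None
    if value <= 0:
        raise ValueError(f"potency must be positive, got {value}")
    return value * factor


def round_sig(value: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (value-identity rule)."""
    return float(f"{value:.{digits}g}")


def classify_record(
    n_publications: int, n_measurements: int, n_distinct_values: int
) -> RecordClass:
    """Place a record in the four-way decision tree.

    The single-publication branch splits on the number of *reported* values
    (replicates included); the multi-publication branch splits on whether
    any two of them actually differ.
    """
    if n_publications == 1:
        if n_measurements == 1:
            return RecordClass.SINGLE_PUB_SINGLE_VALUE
        return RecordClass.SINGLE_PUB_MULTI_VALUE
    if n_distinct_values == 1:
        return RecordClass.MULTI_PUB_SAME_VALUE
    return RecordClass.MULTI_PUB_VARYING_VALUES


def log_range(values_nM) -> float:
    """log10(max) - log10(min) over a record's potencies; 0 for one value."""
    values = np.asarray(list(values_nM), dtype=float)
    if values.size == 0:
        raise ValueError("log_range of an empty value set is undefined")
    if np.any(values <= 0):
        raise ValueError("potency values must be positive")
    return float(np.log10(values.max()) - np.log10(values.min()))


def build_records(kept: pd.DataFrame) -> pd.DataFrame:
    """Aggregate curated measurements into one row per compound-target pair.

    Returns the record table (see ``io_tables.RECORD_SCHEMA``): publication
    ids and normalized nM values are pooled over all assays and documents,
    semicolon-joined in sorted order for deterministic output. The number
    of records equals the number of distinct (compound_id, target_id) pairs
    and the record measurements sum to the input row count.
    """
    if kept.empty:
        return pd.DataFrame(
            columns=[
                "compound_id",
                "target_id",
                "n_publications",
                "n_measurements",
                "n_distinct_values",
                "record_class",
                "log_range",
                "doc_ids",
                "values_nM",
            ]
        )
    work = kept[["compound_id", "target_id", "doc_id"]].copy()
    factors = kept["units"].map(UNIT_TO_NM)
    if factors.isna().any():
        bad = kept.loc[factors.isna(), "units"].unique()
        raise ValueError(f"unconvertible unit(s) reached aggregation: {bad}")
    work["value_nM"] = kept["value"].to_numpy() * factors.to_numpy()

    rows = []
    for (compound, target), group in work.groupby(
        ["compound_id", "target_id"], sort=True
    ):
        values = sorted(group["value_nM"].tolist())
        rounded = [round_sig(v) for v in values]
        docs = sorted(set(group["doc_id"]))
        n_meas = len(values)
        n_pubs = len(docs)
        n_distinct = len(set(rounded))
        cls = classify_record(n_pubs, n_meas, n_distinct)
        rows.append(
            {
                "compound_id": compound,
                "target_id": target,
                "n_publications": n_pubs,
                "n_measurements": n_meas,
                "n_distinct_values": n_distinct,
                "record_class": cls.value,
                "log_range": log_range(rounded),
                "doc_ids": ";".join(docs),
                "values_nM": ";".join(repr(v) for v in values),
            }
        )
    return pd.DataFrame(rows)


def _range_bin(span: float) -> str:
    if span <= 1:
        return "<=1"
    if span <= 2:
        return "(1,2]"
    if span <= 3:
        return "(2,3]"
    return ">3"


def range_histogram(
    records: pd.DataFrame, min_publications: int = 10
) -> pd.DataFrame:
    """Percentage of records per log-range bin, for well-replicated records.

    Only records with more than ``min_publications`` source publications are
    binned (the regime where large potency spreads become visible). Returns
    a table with columns bin/count/percentage; empty selection returns an
    empty table with a warning rather than an error.
    """
    selected = records.loc[records["n_publications"] > min_publications]
    if selected.empty:
        warnings.warn(
            f"no records with more than {min_publications} publications",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["bin", "count", "percentage"])
    bins = selected["log_range"].map(_range_bin)
    counts = bins.value_counts().reindex(RANGE_BINS, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "bin": RANGE_BINS,
            "count": counts.to_numpy(),
            "percentage": 100.0 * counts.to_numpy() / total,
        }
    )
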