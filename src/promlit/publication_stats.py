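"""Per-publication profiling of curated bioactivity data.

Each source document is profiled by the number of distinct assays, targets
and active compounds it contributes after curation, and placed in one of
three categories: a single assay (hence a single target), multiple assays
on one target, or multiple assays spanning several targets. Summary
distributions (histograms over 1..5 and ">5", with mean and median), a
journal ranking and a publication-year histogram round out the module.

An assay is assumed document-exclusive — it is reported in exactly one
publication and probes exactly one target. The profiler asserts the
one-target property (it makes n_targets <= n_assays a theorem, not an
assumption) and warns when foreign data violates document exclusivity.
"""

from __future__ import annotations

import warnings
from enum import Enum

import pandas as pd

from .io_tables import IntegrityError

__all__ = [
    "PublicationCategory",
    "COUNT_BINS",
    "profile_publications",
    "classify_publication",
    "distribution_summary",
    "journal_ranking",
    "year_histogram",
]

#: Display bins for per-publication counts.
COUNT_BINS = ("1", "2", "3", "4", "5", ">5")


class PublicationCategory(str, Enum):
    SINGLE_ASSAY = "SINGLE_ASSAY"
    MULTI_ASSAY_SINGLE_TARGET = "MULTI_ASSAY_SINGLE_TARGET"
    MULTI_ASSAY_MULTI_TARGET = "MULTI_ASSAY_MULTI_TARGET"


def classify_publication(n_assays: int, n_targets: int) -> PublicationCategory:
    """Three-way category from distinct assay and target counts."""
    if n_targets > n_assays:
        raise ValueError(
            f"n_targets ({n_targets}) cannot exceed n_assays ({n_assays}) "
            "when each assay probes one target"
        )
    if n_assays == 1:
        return PublicationCategory.SINGLE_ASSAY
    if n_targets == 1:
        return PublicationCategory.MULTI_ASSAY_SINGLE_TARGET
    return PublicationCategory.MULTI_ASSAY_MULTI_TARGET


def profile_publications(
    kept: pd.DataFrame, publications: pd.DataFrame
) -> pd.DataFrame:
    """One profile row per document with curated rows.

    Counts are *distinct* assays, targets and compounds among the document's
    kept measurements. Documents contributing no kept row are absent from
    the profile table. Raises :class:`IntegrityError` for an unresolvable
    doc_id; warns if an assay spans documents (foreign-data anomaly).
    """
    if kept.empty:
        return pd.DataFrame(
            columns=[
                "doc_id",
                "journal",
                "year",
                "n_assays",
                "n_targets",
                "n_compounds",
                "category",
            ]
        )
    unknown = sorted(set(kept["doc_id"]) - set(publications["doc_id"]))
    if unknown:
        raise IntegrityError(
            "doc_id(s) not in publication table: " + ", ".join(unknown[:10])
        )
    assay_targets = kept.groupby("assay_id")["target_id"].nunique()
    multi = assay_targets[assay_targets > 1]
    if not multi.empty:
        raise IntegrityError(
            "assay(s) mapped to multiple targets: "
            + ", ".join(multi.index[:10])
        )
    assay_docs = kept.groupby("assay_id")["doc_id"].nunique()
    if (assay_docs > 1).any():
        warnings.warn(
            "assay id(s) appear in multiple documents; per-publication assay "
            "counts may double-count shared assays",
            stacklevel=2,
        )
    grouped = kept.groupby("doc_id").agg(
        n_assays=("assay_id", "nunique"),
        n_targets=("target_id", "nunique"),
        n_compounds=("compound_id", "nunique"),
    )
    grouped["category"] = [
        classify_publication(a, t).value
        for a, t in zip(grouped["n_assays"], grouped["n_targets"])
    ]
    profiles = grouped.reset_index().merge(
        publications[["doc_id", "journal", "year"]], on="doc_id", how="left"
    )
    cols = [
        "doc_id",
        "journal",
        "year",
        "n_assays",
        "n_targets",
        "n_compounds",
        "category",
    ]
    return profiles[cols].sort_values("doc_id", kind="mergesort").reset_index(
        drop=True
    )


def _count_bin(value: int) -> str:
    return str(value) if value <= 5 else ">5"


def distribution_summary(profiles: pd.DataFrame, field: str) -> dict:
    """Histogram over {1..5, >5} plus mean (1 decimal) and median.

    ``field`` is one of n_assays / n_targets / n_compounds. The mean is
    reported to one decimal place (full precision under ``mean_exact``);
    the median is the standard middle-order statistic.
    """
    if field not in ("n_assays", "n_targets", "n_compounds"):
        raise ValueError(f"unknown profile field {field!r}")
    if profiles.empty:
        raise ValueError("distribution_summary of an empty profile table")
    values = profiles[field]
    counts = (
        values.map(_count_bin).value_counts().reindex(COUNT_BINS, fill_value=0)
    )
    total = int(counts.sum())
    histogram = pd.DataFrame(
        {
            "bin": COUNT_BINS,
            "count": counts.to_numpy(),
            "percentage": 100.0 * counts.to_numpy() / total,
        }
    )
    mean_exact = float(values.mean())
    return {
        "field": field,
        "histogram": histogram,
        "mean": round(mean_exact, 1),
        "mean_exact": mean_exact,
        "median": float(values.median()),
    }


def journal_ranking(
    profiles: pd.DataFrame, threshold: int = 100
) -> pd.DataFrame:
    """Journals by descending qualifying-publication count.

    Keeps journals with more than ``threshold`` publications (the classic
    cut keeps those above 100); ties break alphabetically.
    """
    counts = profiles.groupby("journal").size().rename("n_publications")
    table = counts.reset_index().sort_values(
        ["n_publications", "journal"],
        ascending=[False, True],
        kind="mergesort",
    )
    table = table.loc[table["n_publications"] > threshold]
    return table.reset_index(drop=True)


def year_histogram(profiles: pd.DataFrame) -> pd.DataFrame:
    """Qualifying publications per calendar year, ascending."""
    counts = profiles.groupby("year").size().rename("n_publications")
    return counts.reset_index().sort_values("year").reset_index(drop=True)
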