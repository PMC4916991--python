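"""Promiscuity degrees cross-tabulated against publication frequency.

The *promiscuity degree* of a compound is the number of distinct protein
targets it is reported active against — its count of activity records. Its
*publication frequency* is the number of distinct documents contributing
any qualifying measurement for it (the union over its records). Both are
summarized over the bins {1, 2, 3, 4, 5, 6-10, 11-20, >20} and jointly as
a degree x publication matrix whose marginals reproduce the two binned
distributions exactly.

Four named compound subsets capture the corners of that matrix, with
"more than five" meaning >= 6 throughout:

* A: one target, one publication (the dominant literature pattern),
* B: one target, more than five publications,
* C: more than five targets, a single publication,
* D: more than five targets, more than five publications.

All other compounds fall in NONE; the five labels partition the compounds.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "PROMISCUITY_BINS",
    "compound_profiles",
    "assign_subset",
    "degree_distribution",
    "publication_frequency_distribution",
    "degree_publication_matrix",
    "mean_median_degree",
    "format_percentage",
]

#: Shared bin labels for degrees and publication counts.
PROMISCUITY_BINS = ("1", "2", "3", "4", "5", "6-10", "11-20", ">20")


def promiscuity_bin(value: int) -> str:
    if value <= 5:
        return str(value)
    if value <= 10:
        return "6-10"
    if value <= 20:
        return "11-20"
    return ">20"


def format_percentage(count: int, total: int) -> str:
    """Percentage string: one decimal, two decimals below 0.1%."""
    pct = 100.0 * count / total
    return f"{pct:.2f}" if pct < 0.1 else f"{pct:.1f}"


def assign_subset(degree: int, n_publications: int) -> str:
    """Subset label A/B/C/D/NONE from (degree, publication count)."""
    if degree < 1 or n_publications < 1:
        raise ValueError("degree and n_publications must be >= 1")
    many_targets = degree >= 6
    many_pubs = n_publications >= 6
    if degree == 1 and n_publications == 1:
        return "A"
    if degree == 1 and many_pubs:
        return "B"
    if many_targets and n_publications == 1:
        return "C"
    if many_targets and many_pubs:
        return "D"
    return "NONE"


def compound_profiles(records: pd.DataFrame) -> pd.DataFrame:
    """One profile per compound from the activity-record table.

    degree = number of records (distinct targets); n_publications = size of
    the union of the records' document sets. The degrees over all profiles
    sum to the record count — each record contributes its compound exactly
    one target.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["compound_id", "degree", "n_publications", "subset"]
        )
    doc_sets = records["doc_ids"].str.split(";")
    work = pd.DataFrame(
        {"compound_id": records["compound_id"], "docs": doc_sets}
    )
    rows = []
    for compound, group in work.groupby("compound_id", sort=True):
        pubs = set()
        for docs in group["docs"]:
            pubs.update(docs)
        degree = len(group)
        rows.append(
            {
                "compound_id": compound,
                "degree": degree,
                "n_publications": len(pubs),
                "subset": assign_subset(degree, len(pubs)),
            }
        )
    return pd.DataFrame(rows)


def _binned_distribution(values: pd.Series, total: int) -> pd.DataFrame:
    counts = (
        values.map(promiscuity_bin)
        .value_counts()
        .reindex(PROMISCUITY_BINS, fill_value=0)
    )
    return pd.DataFrame(
        {
            "bin": PROMISCUITY_BINS,
            "count": counts.to_numpy(),
            "percentage": 100.0 * counts.to_numpy() / total,
            "percentage_printed": [
                format_percentage(int(c), total) for c in counts.to_numpy()
            ],
        }
    )


def degree_distribution(profiles: pd.DataFrame) -> pd.DataFrame:
    """Binned compound counts and percentages over promiscuity degree."""
    if profiles.empty:
        raise ValueError("degree_distribution of an empty profile table")
    return _binned_distribution(profiles["degree"], len(profiles))


def publication_frequency_distribution(profiles: pd.DataFrame) -> pd.DataFrame:
    """Binned compound counts and percentages over publication frequency."""
    if profiles.empty:
        raise ValueError(
            "publication_frequency_distribution of an empty profile table"
        )
    return _binned_distribution(profiles["n_publications"], len(profiles))


def degree_publication_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Compound counts by degree bin (rows) x publication bin (columns).

    Row sums equal the degree distribution and column sums the publication
    frequency distribution, cell-exactly; the cells sum to the number of
    compounds.
    """
    if profiles.empty:
        raise ValueError("degree_publication_matrix of an empty profile table")
    table = pd.crosstab(
        profiles["degree"].map(promiscuity_bin),
        profiles["n_publications"].map(promiscuity_bin),
    )
    table = table.reindex(
        index=PROMISCUITY_BINS, columns=PROMISCUITY_BINS, fill_value=0
    )
    matrix = table.reset_index(drop=True)
    matrix.insert(0, "degree_bin", PROMISCUITY_BINS)
    matrix.columns = ["degree_bin", *PROMISCUITY_BINS]
    return matrix


def mean_median_degree(profiles: pd.DataFrame) -> tuple[float, float]:
    """(mean degree to one decimal, median degree)."""
    if profiles.empty:
        raise ValueError("mean_median_degree of an empty profile table")
    return (
        round(float(profiles["degree"].mean()), 1),
        float(profiles["degree"].median()),
    )
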