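"""Selection of high-confidence bioactivity measurements.

Two shipped policies mirror the two standard confidence tiers used when
mining medicinal-chemistry potency data:

* ``set1`` (high confidence): direct target interactions (assay relationship
  type "D") with single human protein targets at the top assay confidence
  score (9), Ki or IC50 values only.
* ``set2`` (relaxed): defined potency values for single human protein
  targets, with no relationship-type or confidence requirement.

Both exclude approximate measurements (relations ">", "<", "~", ">=", "<=")
and both admit only rows from original publications. Because every set-1
predicate implies the corresponding set-2 predicate, set-1 output is always
a subset of set-2 output for the same input.

Rules are applied in a declared order and each rejected row is attributed to
the *first* rule it fails, so the audit counts plus the kept count always
equal the input count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .io_tables import APPROXIMATE_RELATIONS, CONVERTIBLE_UNITS, IntegrityError

__all__ = [
    "CurationPolicy",
    "SET1_POLICY",
    "SET2_POLICY",
    "RULE_ORDER",
    "curate",
    "assert_subset",
    "load_policy",
]

#: Rule application order; affects only audit attribution, never membership.
RULE_ORDER = (
    "doc_type",
    "target_organism",
    "target_type",
    "exclude_approximate",
    "activity_type",
    "relationship_type",
    "confidence_score",
    "unconvertible_units",
)


@dataclass(frozen=True)
class CurationPolicy:
    """Predicate bundle applied row-wise by :func:`curate`.

    ``None`` for the optional fields means the corresponding rule accepts
    every row (the set-2 relaxation). ``exclude_approximate`` is always true
    for the shipped policies: an approximate potency cannot enter any
    downstream value comparison or log-range computation.
    """

    name: str = "custom"
    require_relationship_type: str | None = None
    require_confidence_score: int | None = None
    allowed_activity_types: frozenset[str] | None = frozenset({"Ki", "IC50"})
    require_target_organism: str = "Homo sapiens"
    require_target_type: str = "SINGLE PROTEIN"
    exclude_approximate: bool = True
    require_doc_type: str = "PUBLICATION"
    allowed_units: frozenset[str] = frozenset(CONVERTIBLE_UNITS)


SET1_POLICY = CurationPolicy(
    name="set1",
    require_relationship_type="D",
    require_confidence_score=9,
)

SET2_POLICY = CurationPolicy(name="set2")


def _predicates(
    frame: pd.DataFrame, policy: CurationPolicy
) -> dict[str, pd.Series]:
    true = pd.Series(True, index=frame.index)
    preds = {
        "doc_type": frame["doc_type"] == policy.require_doc_type,
        "target_organism": frame["target_organism"]
        == policy.require_target_organism,
        "target_type": frame["target_type"] == policy.require_target_type,
        "exclude_approximate": (
            ~frame["relation"].isin(APPROXIMATE_RELATIONS)
            & (frame["relation"] == "=")
            if policy.exclude_approximate
            else true
        ),
        "activity_type": (
            frame["activity_type"].isin(policy.allowed_activity_types)
            if policy.allowed_activity_types is not None
            else true
        ),
        "relationship_type": (
            frame["relationship_type"] == policy.require_relationship_type
            if policy.require_relationship_type is not None
            else true
        ),
        "confidence_score": (
            frame["confidence_score"] == policy.require_confidence_score
            if policy.require_confidence_score is not None
            else true
        ),
        "unconvertible_units": frame["units"].isin(policy.allowed_units),
    }
    return preds


def curate(
    measurements: pd.DataFrame,
    publications: pd.DataFrame,
    policy: CurationPolicy,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply a policy, returning kept rows and per-rule rejection counts.

    Every measurement ``doc_id`` must resolve in the publication table
    (raises :class:`IntegrityError` otherwise). The audit dict maps each
    rule name, in application order, to the number of rows that rule was
    the first to reject; ``len(kept) + sum(audit.values()) == len(input)``.
    """
    known = set(publications["doc_id"])
    orphans = sorted(set(measurements["doc_id"]) - known)
    if orphans:
        raise IntegrityError(
            "measurement doc_id(s) absent from publication table: "
            + ", ".join(orphans[:10])
        )
    merged = measurements.merge(
        publications[["doc_id", "doc_type"]], on="doc_id", how="left"
    )
    merged.index = measurements.index
    preds = _predicates(merged, policy)
    audit: dict[str, int] = {}
    remaining = pd.Series(True, index=merged.index)
    for rule in RULE_ORDER:
        rejected = remaining & ~preds[rule]
        audit[rule] = int(rejected.sum())
        remaining &= preds[rule]
    kept = measurements.loc[remaining].copy()
    return kept, audit


def assert_subset(set1_kept: pd.DataFrame, set2_kept: pd.DataFrame) -> bool:
    """True iff every set-1 row occurs in set-2 output (with multiplicity).

    With the shipped policies and a shared raw input this always holds: the
    high-confidence predicates strictly imply the relaxed ones.
    """
    cols = list(set1_kept.columns)
    if set1_kept.empty:
        return True
    from collections import Counter

    c1 = Counter(map(tuple, set1_kept[cols].itertuples(index=False)))
    c2 = Counter(map(tuple, set2_kept[cols].itertuples(index=False)))
    return all(c2[row] >= n for row, n in c1.items())


def load_policy(source: str | Path) -> CurationPolicy:
    """Resolve a policy by shipped name ("set1"/"set2") or YAML/JSON file.

    A policy file holds :class:`CurationPolicy` field names; set-valued
    fields may be given as lists. Unknown keys raise ``ValueError``.
    """
    if str(source) == "set1":
        return SET1_POLICY
    if str(source) == "set2":
        return SET2_POLICY
    data = yaml.safe_load(Path(source).read_text(encoding="utf-8")) or {}
    valid = {f.name for f in fields(CurationPolicy)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown policy field(s): {', '.join(sorted(unknown))}")
    for key in ("allowed_activity_types", "allowed_units"):
        if key in data and data[key] is not None:
            data[key] = frozenset(data[key])
    return CurationPolicy(**data)
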