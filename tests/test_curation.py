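"""Curation policies: membership, audit conservation, set nesting."""

import pandas as pd
import pytest

import promlit as pl
from promlit.curation import RULE_ORDER
from promlit.io_tables import IntegrityError, MEASUREMENT_SCHEMA


def _measurement(**overrides):
    base = {
        "compound_id": "C1",
        "assay_id": "A1",
        "target_id": "T1",
        "target_organism": "Homo sapiens",
        "target_type": "SINGLE PROTEIN",
        "confidence_score": 9,
        "relationship_type": "D",
        "activity_type": "Ki",
        "relation": "=",
        "value": 10.0,
        "units": "nM",
        "doc_id": "D1",
    }
    base.update(overrides)
    return base


def _frame(rows):
    return pd.DataFrame(rows, columns=list(MEASUREMENT_SCHEMA.columns))


PUBS = pd.DataFrame(
    {
        "doc_id": ["D1", "D2"],
        "journal": ["J. Med. Chem.", "Bioorg. Med. Chem. Lett."],
        "year": [2010, 2011],
        "doc_type": ["PUBLICATION", "PUBLICATION"],
    }
)


class TestPolicyPredicates:
    def test_approximate_measurement_rejected_despite_high_confidence(self):
        """A '>' potency fails set 1 even when every other criterion holds."""
        frame = _frame([_measurement(relation=">")])
        kept, audit = pl.curate(frame, PUBS, pl.SET1_POLICY)
        assert len(kept) == 0
        assert audit["exclude_approximate"] == 1

    @pytest.mark.parametrize("relation", [">", "<", "~", ">=", "<="])
    def test_every_approximate_relation_fails_both_policies(self, relation):
        frame = _frame([_measurement(relation=relation)])
        for policy in (pl.SET1_POLICY, pl.SET2_POLICY):
            kept, audit = pl.curate(frame, PUBS, policy)
            assert len(kept) == 0
            assert audit["exclude_approximate"] == 1

    def test_sub_maximal_confidence_splits_the_policies(self):
        """Confidence 8 fails the high-confidence set but passes the relaxed one."""
        frame = _frame([_measurement(confidence_score=8, activity_type="IC50")])
        kept1, audit1 = pl.curate(frame, PUBS, pl.SET1_POLICY)
        kept2, _ = pl.curate(frame, PUBS, pl.SET2_POLICY)
        assert len(kept1) == 0 and audit1["confidence_score"] == 1
        assert len(kept2) == 1

    def test_empty_input_gives_empty_kept_and_zero_audit(self):
        kept, audit = pl.curate(_frame([]), PUBS, pl.SET1_POLICY)
        assert len(kept) == 0
        assert set(audit) == set(RULE_ORDER)
        assert all(v == 0 for v in audit.values())

    def test_unknown_doc_id_raises_integrity_error(self):
        frame = _frame([_measurement(doc_id="D404")])
        with pytest.raises(IntegrityError, match="D404"):
            pl.curate(frame, PUBS, pl.SET1_POLICY)


class TestAuditAgainstIndependentPredicates:
    """Audit counts must match row-by-row first-failing-rule evaluation."""

    def _independent_first_rejection(self, row, doc_types, policy):
        # Oracle: evaluate each rule independently, in declared order.
        checks = {
            "doc_type": doc_types[row["doc_id"]] == policy.require_doc_type,
            "target_organism": row["target_organism"]
            == policy.require_target_organism,
            "target_type": row["target_type"] == policy.require_target_type,
            "exclude_approximate": row["relation"] == "=",
            "activity_type": policy.allowed_activity_types is None
            or row["activity_type"] in policy.allowed_activity_types,
            "relationship_type": policy.require_relationship_type is None
            or row["relationship_type"] == policy.require_relationship_type,
            "confidence_score": policy.require_confidence_score is None
            or row["confidence_score"] == policy.require_confidence_score,
            "unconvertible_units": row["units"] in policy.allowed_units,
        }
        for rule in RULE_ORDER:
            if not checks[rule]:
                return rule
        return None

    def _violation_fixture(self):
        rows = [
            _measurement(compound_id=f"C{i}", assay_id=f"A{i}") for i in range(6)
        ]
        rows += [
            _measurement(assay_id="A10", relation="~"),
            _measurement(assay_id="A11", relation="<"),
            _measurement(assay_id="A12", confidence_score=3),
            _measurement(assay_id="A13", relationship_type="H"),
            _measurement(assay_id="A14", target_organism="Rattus norvegicus"),
            _measurement(assay_id="A15", target_type="PROTEIN COMPLEX"),
            _measurement(assay_id="A16", activity_type="EC50"),
            _measurement(assay_id="A17", units="ug/mL"),
            _measurement(assay_id="A18", doc_id="D2"),
            # multi-violation rows: first failing rule must get the credit
            _measurement(
                assay_id="A19", relation=">", confidence_score=2, units="%"
            ),
            _measurement(
                assay_id="A20",
                target_organism="Mus musculus",
                relationship_type="U",
            ),
        ]
        pubs = PUBS.copy()
        pubs.loc[pubs["doc_id"] == "D2", "doc_type"] = "DATASET"
        return _frame(rows), pubs

    @pytest.mark.parametrize("policy_name", ["set1", "set2"])
    def test_kept_and_audit_match_oracle(self, policy_name):
        frame, pubs = self._violation_fixture()
        policy = pl.load_policy(policy_name)
        doc_types = dict(zip(pubs["doc_id"], pubs["doc_type"]))
        expected_audit = {rule: 0 for rule in RULE_ORDER}
        expected_kept = 0
        for _, row in frame.iterrows():
            rule = self._independent_first_rejection(row, doc_types, policy)
            if rule is None:
                expected_kept += 1
            else:
                expected_audit[rule] += 1
        kept, audit = pl.curate(frame, pubs, policy)
        assert audit == expected_audit
        assert len(kept) == expected_kept

    @pytest.mark.parametrize("policy_name", ["set1", "set2"])
    def test_conservation(self, policy_name):
        frame, pubs = self._violation_fixture()
        kept, audit = pl.curate(frame, pubs, pl.load_policy(policy_name))
        assert len(kept) + sum(audit.values()) == len(frame)

    def test_idempotence(self):
        frame, pubs = self._violation_fixture()
        kept, _ = pl.curate(frame, pubs, pl.SET1_POLICY)
        kept2, audit2 = pl.curate(kept, pubs, pl.SET1_POLICY)
        pd.testing.assert_frame_equal(
            kept.reset_index(drop=True), kept2.reset_index(drop=True)
        )
        assert sum(audit2.values()) == 0


class TestSetNesting:
    def test_set1_is_subset_of_set2_on_mixed_input(self):
        frame = TestAuditAgainstIndependentPredicates()._violation_fixture()[0]
        pubs = TestAuditAgainstIndependentPredicates()._violation_fixture()[1]
        kept1, _ = pl.curate(frame, pubs, pl.SET1_POLICY)
        kept2, _ = pl.curate(frame, pubs, pl.SET2_POLICY)
        assert pl.assert_subset(kept1, kept2)

    def test_subset_on_synthetic_corpus(self, synthetic_corpus):
        (measurements, publications, _), _ = synthetic_corpus
        kept1, _ = pl.curate(measurements, publications, pl.SET1_POLICY)
        kept2, _ = pl.curate(measurements, publications, pl.SET2_POLICY)
        assert pl.assert_subset(kept1, kept2)
        assert len(kept2) >= len(kept1)

    def test_disjoint_frames_are_not_nested(self):
        a = _frame([_measurement(compound_id="CX")])
        b = _frame([_measurement(compound_id="CY")])
        assert not pl.assert_subset(a, b)


class TestPolicyLoading:
    def test_shipped_names_resolve(self):
        assert pl.load_policy("set1") is pl.SET1_POLICY
        assert pl.load_policy("set2") is pl.SET2_POLICY

    def test_yaml_policy_round_trip(self, tmp_path):
        path = tmp_path / "policy.yaml"
        path.write_text(
            "name: custom\nrequire_confidence_score: 7\n"
            "allowed_activity_types: [Ki, IC50, EC50]\n"
        )
        policy = pl.load_policy(path)
        assert policy.require_confidence_score == 7
        assert "EC50" in policy.allowed_activity_types

    def test_unknown_field_rejected(self, tmp_path):
        path = tmp_path / "policy.yaml"
        path.write_text("not_a_field: 1\n")
        with pytest.raises(ValueError, match="not_a_field"):
            pl.load_policy(path)
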