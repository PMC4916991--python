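"""Synthetic ChEMBL-shaped bioactivity corpora with a ground-truth manifest.

The generator emits a measurement table and a publication table whose
statistical shape follows what large-scale mining of the medicinal
chemistry literature actually shows: a heavily right-skewed publications-
per-compound distribution (~94% of compounds appear in a single paper), a
promiscuity-degree distribution dominated by single-target compounds
(~70% degree 1), a few assays per publication on average, replicated
potency values per compound-target pair with log-scale scatter, exact
value duplication across papers when a potency is cited rather than
re-measured, and contaminating rows that high-confidence curation must
remove (approximate relations, sub-maximal confidence scores, non-direct
relationship types, non-human or non-protein targets, non-publication
documents).

Every run also returns a :class:`dict` manifest recording, per compound,
the true promiscuity degree, publication count and subset label; per
record, the true class and logarithmic potency range; and the expected
row counts after high-confidence curation. The pipeline is deterministic
given the tables, so recomputing these quantities from the emitted tables
must reproduce the manifest exactly — that is the generator's contract
and the backbone of the test suite.

Output is fully determined by the config (including the seed): the same
config twice yields byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .activity_records import UNIT_TO_NM, classify_record, log_range, round_sig
from .io_tables import MEASUREMENT_SCHEMA, PUBLICATION_SCHEMA
from .promiscuity import PROMISCUITY_BINS, assign_subset

__all__ = [
    "GeneratorConfig",
    "DEGREE_BIN_WEIGHTS",
    "PUBLICATION_BIN_WEIGHTS",
    "BIN_RANGES",
    "generate",
    "fixture_small",
]

#: Default degree-bin weights: observed compound counts per promiscuity
#: degree in the high-confidence literature set this generator emulates.
DEGREE_BIN_WEIGHTS: dict[str, int] = {
    "1": 117_253,
    "2": 30_457,
    "3": 12_092,
    "4": 5_214,
    "5": 1_514,
    "6-10": 1_368,
    "11-20": 280,
    ">20": 30,
}

#: Default publication-count weights: observed compounds per number of
#: source publications in the same set (~94.5% singletons).
PUBLICATION_BIN_WEIGHTS: dict[str, int] = {
    "1": 158_995,
    "2": 7_054,
    "3": 991,
    "4": 398,
    "5": 200,
    "6-10": 327,
    "11-20": 146,
    ">20": 97,
}

#: Integer band sampled uniformly for each bin label. The open-ended top
#: bin is capped at 80 targets/publications, comfortably above the most
#: promiscuous compounds on record (tens of targets).
BIN_RANGES: dict[str, tuple[int, int]] = {
    "1": (1, 1),
    "2": (2, 2),
    "3": (3, 3),
    "4": (4, 4),
    "5": (5, 5),
    "6-10": (6, 10),
    "11-20": (11, 20),
    ">20": (21, 80),
}

#: Journal weights: the eight journals that dominate qualifying medicinal
#: chemistry publications, plus a residual bucket.
JOURNAL_WEIGHTS: dict[str, int] = {
    "Bioorg. Med. Chem. Lett.": 4456,
    "J. Med. Chem.": 3417,
    "Bioorg. Med. Chem.": 1424,
    "Eur. J. Med. Chem.": 689,
    "ACS Med. Chem. Lett.": 419,
    "J. Nat. Prod.": 200,
    "MedChemComm": 186,
    "Med. Chem. Res.": 111,
    "Other": 311,
}

CONTAMINATION_RULES = (
    "approximate_relation",
    "low_confidence",
    "non_d_relationship",
    "non_human_target",
    "non_protein_target",
    "non_publication_doc",
)

#: Audit rule (see curation.RULE_ORDER) each contamination kind trips.
CONTAMINATION_TO_AUDIT_RULE = {
    "approximate_relation": "exclude_approximate",
    "low_confidence": "confidence_score",
    "non_d_relationship": "relationship_type",
    "non_human_target": "target_organism",
    "non_protein_target": "target_type",
    "non_publication_doc": "doc_type",
}


def _normalize(weights: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(weights.values()))
    return {k: v / total for k, v in weights.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the corpus generator; the seed fully determines output.

    Defaults reproduce the observed literature structure: degree and
    publication-count distributions from the weight tables above (sampled
    independently per compound — degree and publication frequency show no
    detectable correlation in the real data), ~2.8 assays per publication,
    a log-normal potency model centred at 100 nM with within-record
    scatter of 0.5 log units, and small contamination fractions for each
    rule that high-confidence curation enforces.
    """

    seed: int = 0
    n_compounds: int = 1000
    degree_distribution: Mapping[str, float] = field(
        default_factory=lambda: _normalize(DEGREE_BIN_WEIGHTS)
    )
    publication_count_distribution: Mapping[str, float] = field(
        default_factory=lambda: _normalize(PUBLICATION_BIN_WEIGHTS)
    )
    assays_per_publication_mean: float = 2.8
    log10_potency_mean: float = 2.0
    log10_potency_sd_between: float = 1.2
    log10_potency_sd_within_record: float = 0.5
    #: P(a single-publication record reports replicate values).
    multi_value_probability: float = 0.107
    #: P(a multi-publication record repeats one identical cited value).
    referenced_value_probability: float = 0.39
    contamination: Mapping[str, float] = field(
        default_factory=lambda: {
            "approximate_relation": 0.06,
            "low_confidence": 0.04,
            "non_d_relationship": 0.03,
            "non_human_target": 0.05,
            "non_protein_target": 0.04,
            "non_publication_doc": 0.02,
        }
    )
    n_targets: int = 1566

    def validate(self) -> None:
        for name, dist in (
            ("degree_distribution", self.degree_distribution),
            ("publication_count_distribution", self.publication_count_distribution),
        ):
            if set(dist) != set(PROMISCUITY_BINS):
                raise ValueError(f"{name} must cover bins {PROMISCUITY_BINS}")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative probability")
        unknown = set(self.contamination) - set(CONTAMINATION_RULES)
        if unknown:
            raise ValueError(
                f"unknown contamination rule(s): {', '.join(sorted(unknown))}"
            )
        if any(not 0 <= f <= 1 for f in self.contamination.values()):
            raise ValueError("contamination fractions must lie in [0, 1]")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        max_degree = max(
            BIN_RANGES[b][1]
            for b, p in self.degree_distribution.items()
            if p > 0
        )
        if max_degree > self.n_targets:
            raise ValueError(
                f"infeasible config: degree up to {max_degree} possible but "
                f"only {self.n_targets} targets available"
            )
        for prob in (self.multi_value_probability, self.referenced_value_probability):
            if not 0 <= prob <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def _sample_bin_values(
    rng: np.random.Generator, dist: Mapping[str, float], n: int
) -> np.ndarray:
    """Sample a bin per draw, then an integer uniformly within the band."""
    labels = list(PROMISCUITY_BINS)
    probs = np.array([dist[b] for b in labels], dtype=float)
    probs = probs / probs.sum()
    bin_idx = rng.choice(len(labels), size=n, p=probs)
    lows = np.array([BIN_RANGES[b][0] for b in labels])
    highs = np.array([BIN_RANGES[b][1] for b in labels])
    return rng.integers(lows[bin_idx], highs[bin_idx] + 1)


def _round_robin_docs(doc_list: list[str], degree: int) -> list[list[str]]:
    """Assign a compound's documents to its records.

    Every record receives at least one document and every document is used,
    so the per-compound publication count is exactly ``len(doc_list)``.
    """
    p = len(doc_list)
    if p <= degree:
        return [[doc_list[j % p]] for j in range(degree)]
    return [doc_list[j::degree] for j in range(degree)]


def _draw_measurement_values(
    rng: np.random.Generator, mu: float, sd: float, k: int
) -> tuple[list[float], list[str], list[float]]:
    """Draw k potencies around a record's true log-potency.

    Returns (emitted values, emitted units, nM values as the pipeline will
    reconstruct them, i.e. emitted * unit factor).
    """
    units = [str(u) for u in rng.choice(
        ["nM", "uM", "M"], size=k, p=[0.70, 0.25, 0.05]
    )]
    nm = 10.0 ** (mu + rng.normal(0.0, sd, size=k))
    emitted = [float(v) / UNIT_TO_NM[u] for v, u in zip(nm, units)]
    recon = [e * UNIT_TO_NM[u] for e, u in zip(emitted, units)]
    return emitted, units, recon


def generate(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (measurements, publications, manifest) for a config.

    Clean rows pass high-confidence (set-1) curation by construction; each
    contaminated row violates exactly its flagged rule. Each compound's
    clean rows realize its sampled degree and publication count exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds

    degrees = _sample_bin_values(rng, config.degree_distribution, n)
    pub_counts = _sample_bin_values(
        rng, config.publication_count_distribution, n
    )

    # Size the shared document pool so the expected number of distinct
    # assays per document matches the configured mean. Each (record, doc)
    # incidence contributes one assay; replicate values add extras.
    incidences = int(np.maximum(degrees, pub_counts).sum())
    extra = config.multi_value_probability * 2.0 * int(
        (degrees >= pub_counts).sum()
    )
    n_docs = max(
        int(math.ceil((incidences + extra) / config.assays_per_publication_mean)),
        int(pub_counts.max()),
        1,
    )

    journals = list(JOURNAL_WEIGHTS)
    jprobs = np.array(list(JOURNAL_WEIGHTS.values()), dtype=float)
    jprobs /= jprobs.sum()
    doc_ids = [f"D{i:06d}" for i in range(n_docs)]
    pub_rows = {
        "doc_id": doc_ids,
        "journal": [journals[i] for i in rng.choice(len(journals), n_docs, p=jprobs)],
        "year": rng.integers(2006, 2015, size=n_docs).tolist(),
        "doc_type": ["PUBLICATION"] * n_docs,
    }

    target_ids = [f"T{i:05d}" for i in range(config.n_targets)]
    compound_ids = [f"C{i:06d}" for i in range(n)]

    rows: list[dict] = []
    manifest_compounds: dict[str, dict] = {}
    manifest_records: dict[str, dict] = {}
    assay_counter = 0

    def next_assay() -> str:
        nonlocal assay_counter
        assay_counter += 1
        return f"A{assay_counter:07d}"

    for ci in range(n):
        cid = compound_ids[ci]
        d = int(degrees[ci])
        p = int(pub_counts[ci])
        targets = [target_ids[t] for t in rng.choice(config.n_targets, d, replace=False)]
        docs = [doc_ids[j] for j in rng.choice(n_docs, p, replace=False)]
        record_docs = _round_robin_docs(docs, d)
        manifest_compounds[cid] = {
            "degree": d,
            "n_publications": p,
            "subset": assign_subset(d, p),
        }
        for tid, rdocs in zip(targets, record_docs):
            mu = rng.normal(
                config.log10_potency_mean, config.log10_potency_sd_between
            )
            m = len(rdocs)
            if m == 1:
                k = (
                    int(2 + rng.integers(0, 3))
                    if rng.random() < config.multi_value_probability
                    else 1
                )
                emitted, units, recon = _draw_measurement_values(
                    rng, mu, config.log10_potency_sd_within_record, k
                )
                meas_docs = rdocs * k
            elif rng.random() < config.referenced_value_probability:
                # A cited potency: every paper repeats one identical value.
                emitted, units, recon = _draw_measurement_values(rng, mu, 0.0, 1)
                emitted, units, recon = emitted * m, units * m, recon * m
                meas_docs = rdocs
            else:
                for _ in range(100):
                    emitted, units, recon = _draw_measurement_values(
                        rng, mu, config.log10_potency_sd_within_record, m
                    )
                    if len({round_sig(v) for v in recon}) >= 2:
                        break
                meas_docs = rdocs
            for value, unit, doc in zip(emitted, units, meas_docs):
                rows.append(
                    {
                        "compound_id": cid,
                        "assay_id": next_assay(),
                        "target_id": tid,
                        "target_organism": "Homo sapiens",
                        "target_type": "SINGLE PROTEIN",
                        "confidence_score": 9,
                        "relationship_type": "D",
                        "activity_type": ["Ki", "IC50"][int(rng.integers(0, 2))],
                        "relation": "=",
                        "value": value,
                        "units": unit,
                        "doc_id": doc,
                    }
                )
            rounded = [round_sig(v) for v in recon]
            n_distinct = len(set(rounded))
            cls = classify_record(m, len(recon), n_distinct)
            manifest_records[f"{cid}|{tid}"] = {
                "n_publications": m,
                "n_measurements": len(recon),
                "n_distinct_values": n_distinct,
                "record_class": cls.value,
                "log_range": log_range(rounded),
            }

    n_clean = len(rows)

    # Contamination: clone a clean row, give it a fresh assay, and break
    # exactly one high-confidence rule.
    contamination_counts: dict[str, int] = {}
    dataset_docs: list[str] = []
    n_nonpub = int(round(config.contamination.get("non_publication_doc", 0.0) * n_clean))
    if n_nonpub:
        dataset_docs = [f"X{i:04d}" for i in range(max(1, n_nonpub // 50))]
        for xid in dataset_docs:
            pub_rows["doc_id"].append(xid)
            pub_rows["journal"].append("Deposited data set")
            pub_rows["year"].append(int(rng.integers(2006, 2015)))
            pub_rows["doc_type"].append("DATASET")

    for rule in CONTAMINATION_RULES:
        frac = config.contamination.get(rule, 0.0)
        count = int(round(frac * n_clean))
        contamination_counts[rule] = count
        for _ in range(count):
            clone = dict(rows[int(rng.integers(0, n_clean))])
            clone["assay_id"] = next_assay()
            if rule == "approximate_relation":
                clone["relation"] = str(rng.choice([">", "<", "~"]))
            elif rule == "low_confidence":
                clone["confidence_score"] = int(rng.integers(0, 9))
            elif rule == "non_d_relationship":
                clone["relationship_type"] = str(rng.choice(["H", "U", "N"]))
            elif rule == "non_human_target":
                clone["target_organism"] = str(
                    rng.choice(["Rattus norvegicus", "Mus musculus"])
                )
            elif rule == "non_protein_target":
                clone["target_type"] = str(
                    rng.choice(["PROTEIN COMPLEX", "CELL-LINE", "ORGANISM"])
                )
            elif rule == "non_publication_doc":
                clone["doc_id"] = dataset_docs[int(rng.integers(0, len(dataset_docs)))]
            rows.append(clone)

    measurements = pd.DataFrame(rows, columns=list(MEASUREMENT_SCHEMA.columns))
    measurements = measurements.sort_values(
        list(MEASUREMENT_SCHEMA.key) + ["compound_id"], kind="mergesort"
    ).reset_index(drop=True)
    publications = pd.DataFrame(pub_rows, columns=list(PUBLICATION_SCHEMA.columns))
    publications = publications.sort_values("doc_id", kind="mergesort").reset_index(
        drop=True
    )

    manifest = {
        "config": {
            **asdict(config),
            "degree_distribution": dict(config.degree_distribution),
            "publication_count_distribution": dict(
                config.publication_count_distribution
            ),
            "contamination": dict(config.contamination),
        },
        "compounds": manifest_compounds,
        "records": manifest_records,
        "n_clean_rows": n_clean,
        "n_contaminated_rows": int(sum(contamination_counts.values())),
        "contamination_counts": contamination_counts,
        "expected_audit": {
            CONTAMINATION_TO_AUDIT_RULE[rule]: count
            for rule, count in contamination_counts.items()
        },
        "expected_set1_rows": n_clean,
    }
    return measurements, publications, manifest


def fixture_small() -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Hand-written ~20-row corpus exercising every pipeline branch.

    Contains one record of each class (the multi-publication varying record
    spans more than three orders of magnitude), one subset-A compound, one
    subset-C compound (six targets in one paper), and one row per curation
    rejection rule. The manifest mirrors :func:`generate`'s, with expected
    per-rule audit counts for the high-confidence policy.
    """
    HS, SP = "Homo sapiens", "SINGLE PROTEIN"
    clean = [
        # compound, assay, target, organism, ttype, conf, rel, atype, relation, value, units, doc
        ("C1", "A01", "T1", HS, SP, 9, "D", "Ki", "=", 5.0, "nM", "D1"),
        ("C3", "A02", "T3", HS, SP, 9, "D", "Ki", "=", 50.0, "nM", "D3"),
        ("C3", "A03", "T3", HS, SP, 9, "D", "IC50", "=", 50.0, "nM", "D4"),
        ("C4", "A04", "T4", HS, SP, 9, "D", "Ki", "=", 2.0, "nM", "D5"),
        ("C4", "A05", "T4", HS, SP, 9, "D", "Ki", "=", 30.0, "uM", "D6"),
        ("C5", "A06", "T5", HS, SP, 9, "D", "Ki", "=", 100.0, "nM", "D7"),
        ("C5", "A07", "T5", HS, SP, 9, "D", "Ki", "=", 0.4, "uM", "D7"),
        ("C5", "A08", "T6", HS, SP, 9, "D", "IC50", "=", 200.0, "nM", "D7"),
        ("C5", "A09", "T7", HS, SP, 9, "D", "Ki", "=", 150.0, "nM", "D7"),
        ("C5", "A10", "T8", HS, SP, 9, "D", "Ki", "=", 300.0, "nM", "D7"),
        ("C5", "A11", "T9", HS, SP, 9, "D", "IC50", "=", 1.0, "uM", "D7"),
        ("C5", "A12", "T10", HS, SP, 9, "D", "Ki", "=", 2.5, "uM", "D7"),
    ]
    contaminated = [
        ("C6", "A13", "T1", HS, SP, 9, "D", "Ki", ">", 1000.0, "nM", "D1"),
        ("C6", "A14", "T1", HS, SP, 8, "D", "Ki", "=", 1000.0, "nM", "D1"),
        ("C6", "A15", "T1", HS, SP, 9, "H", "Ki", "=", 1000.0, "nM", "D1"),
        ("C6", "A16", "T11", "Rattus norvegicus", SP, 9, "D", "Ki", "=", 1000.0, "nM", "D1"),
        ("C6", "A17", "T12", HS, "PROTEIN COMPLEX", 9, "D", "Ki", "=", 1000.0, "nM", "D1"),
        ("C6", "A18", "T1", HS, SP, 9, "D", "Ki", "=", 1000.0, "nM", "D9"),
        ("C6", "A19", "T1", HS, SP, 9, "D", "Ki", "=", 1000.0, "ug/mL", "D1"),
    ]
    measurements = pd.DataFrame(
        clean + contaminated, columns=list(MEASUREMENT_SCHEMA.columns)
    )
    publications = pd.DataFrame(
        [
            ("D1", "J. Med. Chem.", 2008, "PUBLICATION"),
            ("D3", "Bioorg. Med. Chem. Lett.", 2010, "PUBLICATION"),
            ("D4", "Bioorg. Med. Chem. Lett.", 2011, "PUBLICATION"),
            ("D5", "Eur. J. Med. Chem.", 2009, "PUBLICATION"),
            ("D6", "J. Med. Chem.", 2012, "PUBLICATION"),
            ("D7", "J. Med. Chem.", 2013, "PUBLICATION"),
            ("D9", "Deposited data set", 2013, "DATASET"),
        ],
        columns=list(PUBLICATION_SCHEMA.columns),
    )
    manifest = {
        "compounds": {
            "C1": {"degree": 1, "n_publications": 1, "subset": "A"},
            "C3": {"degree": 1, "n_publications": 2, "subset": "NONE"},
            "C4": {"degree": 1, "n_publications": 2, "subset": "NONE"},
            "C5": {"degree": 6, "n_publications": 1, "subset": "C"},
        },
        "records": {
            "C1|T1": {"record_class": "SINGLE_PUB_SINGLE_VALUE", "log_range": 0.0},
            "C3|T3": {"record_class": "MULTI_PUB_SAME_VALUE", "log_range": 0.0},
            "C4|T4": {
                "record_class": "MULTI_PUB_VARYING_VALUES",
                "log_range": math.log10(30_000.0 / 2.0),
            },
            "C5|T5": {
                "record_class": "SINGLE_PUB_MULTI_VALUE",
                "log_range": math.log10(400.0 / 100.0),
            },
            "C5|T6": {"record_class": "SINGLE_PUB_SINGLE_VALUE", "log_range": 0.0},
            "C5|T7": {"record_class": "SINGLE_PUB_SINGLE_VALUE", "log_range": 0.0},
            "C5|T8": {"record_class": "SINGLE_PUB_SINGLE_VALUE", "log_range": 0.0},
            "C5|T9": {"record_class": "SINGLE_PUB_SINGLE_VALUE", "log_range": 0.0},
            "C5|T10": {"record_class": "SINGLE_PUB_SINGLE_VALUE", "log_range": 0.0},
        },
        "n_clean_rows": len(clean),
        "n_contaminated_rows": len(contaminated),
        "expected_set1_rows": len(clean),
        "expected_set2_rows": len(clean) + 2,  # conf-8 and type-H rows pass set 2
        "expected_audit": {
            "doc_type": 1,
            "target_organism": 1,
            "target_type": 1,
            "exclude_approximate": 1,
            "activity_type": 0,
            "relationship_type": 1,
            "confidence_score": 1,
            "unconvertible_units": 1,
        },
        "subset_counts": {"A": 1, "C": 1, "NONE": 2},
    }
    return measurements, publications, manifest
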