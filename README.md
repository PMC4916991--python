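# promlit

Tools for analyzing compound bioactivity data **in light of its source
publications**. Public bioactivity databases are built by extracting
potency measurements (Ki, IC50) from the medicinal-chemistry literature,
but once the data are mined, the papers they came from are usually
forgotten. `promlit` keeps that provenance: it curates flat measurement
tables into confidence-tiered sets, aggregates them into
compound–target *activity records* carrying all of their publications and
potency values, profiles the publications themselves, and quantifies
compound promiscuity against publication frequency.

It is aimed at cheminformaticians and data curators who work with
ChEMBL-style activity exports and want reproducible, auditable curation
and promiscuity statistics — plus a synthetic-corpus generator with a
ground-truth manifest, so the whole pipeline is testable without any
database download.

## The core quantities

- **Curation policies.** "Set 1" keeps direct interactions (relationship
  type `D`) with single human protein targets at assay confidence score 9
  and exact (`=`) Ki/IC50 values from original publications; "set 2"
  relaxes the relationship-type and confidence requirements. Approximate
  values (`>`, `<`, `~`, ...) are always excluded. Every rejected row is
  charged to the first rule it fails: `kept + Σ audit = input`, exactly.
- **Activity record.** One row per unique compound–target pair, pooling
  all assays, documents and nM-normalized potencies. Each record falls in
  one of four classes: single publication with a single value, single
  publication with replicate values, multiple publications with varying
  values, or multiple publications repeating one identical value (a
  potency *referenced* from an earlier paper). Its potency spread is the
  logarithmic range log₁₀(max) − log₁₀(min), in orders of magnitude.
- **Promiscuity degree (PD).** The number of distinct targets a compound
  is reported active against; cross-tabulated against its number of
  source publications over the bins {1,…,5, 6–10, 11–20, >20}, with four
  corner subsets A–D ((PD, publications) = (1,1), (1,>5), (>5,1),
  (>5,>5)).

## Worked example

Generate a 5,000-compound synthetic corpus and run the full analysis for
both policies:

```python
from pathlib import Path
import promlit as pl
from promlit.io_tables import MEASUREMENT_SCHEMA, PUBLICATION_SCHEMA

measurements, publications, manifest = pl.generate(
    pl.GeneratorConfig(seed=7, n_compounds=5000)
)
out = Path("demo")
out.mkdir()
pl.write_table(measurements, out / "measurements.csv", MEASUREMENT_SCHEMA)
pl.write_table(publications, out / "publications.csv", PUBLICATION_SCHEMA)

report = pl.run_all(
    pl.RunConfig(out / "measurements.csv", out / "publications.csv", out / "run")
)
set1 = report["set1"]
print(set1["n_kept"], set1["n_records"], set1["mean_degree"])
print(set1["class_counts"])
```

which prints (the corpus has 12,005 rows, of which 2,323 are
contaminants the high-confidence policy must remove):

```
9682 7657 1.5
{'SINGLE_PUB_SINGLE_VALUE': 6626, 'SINGLE_PUB_MULTI_VALUE': 807,
 'MULTI_PUB_VARYING_VALUES': 142, 'MULTI_PUB_SAME_VALUE': 82}
```

So 9,682 measurements survive curation and collapse into 7,657
compound–target records over 5,000 compounds — a mean promiscuity degree
of 1.5 (median 1.0): most compounds are reported active against a single
target. 97% of records come from one publication, and of the
multi-publication records about a third repeat one identical, cited
value. The degree distribution confirms the single-target dominance:

```
>>> cp = pl.read_table(out / "run/set1/compound_profiles.csv", pl.COMPOUND_PROFILE_SCHEMA)
>>> print(pl.degree_distribution(cp).to_string(index=False))
  bin  count  percentage percentage_printed
    1   3494       69.88               69.9
    2    891       17.82               17.8
    3    381        7.62                7.6
    4    142        2.84                2.8
    5     39        0.78                0.8
 6-10     47        0.94                0.9
11-20      6        0.12                0.1
  >20      0        0.00               0.00
```

Every stage is also a subcommand of the `promlit` CLI
(`simulate`, `curate`, `records`, `pubstats`, `promiscuity`, `report`,
`check`); `promlit report` persists all intermediate tables and a
`report.json`, and `promlit check` verifies the arithmetic identities any
valid report must satisfy (class and category partitions, degree
conservation, matrix marginals).

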