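# Methods

`promlit` analyzes flat bioactivity tables of the kind extracted from the
medicinal-chemistry literature (one row per potency measurement, with
compound, assay, target, document, relation, value and unit fields) and
answers three linked questions: which measurements are trustworthy, how do
compound–target *activity records* distribute over source publications, and
how promiscuous are the compounds once publication provenance is taken into
account.

## Curation model

Two policies are shipped. The **high-confidence policy** ("set 1") keeps a
row only if the assay probes a direct interaction (relationship type `D`)
with a single human protein target at the top assay-to-target confidence
score (9), the activity type is Ki or IC50, the relation is exactly `=`,
the source document is an original publication, and the unit is one of
nM/uM/M. The **relaxed policy** ("set 2") drops the relationship-type and
confidence requirements but keeps everything else, so set-1 output is a
subset of set-2 output by construction. Approximate potencies (`>`, `<`,
`~`, and, as a deliberate widening of that open-ended list, `>=`/`<=`) are
excluded under both policies: a bound is not a value and cannot enter a
log-range or a value-identity comparison.

Rules are applied in a fixed coarse-to-fine order (document type →
organism → target type → relation → activity type → relationship type →
confidence → units) and each rejected row is charged to the first rule it
fails. The order affects only this audit attribution, never membership;
`kept + sum(audit) == input` holds exactly. The units rule is our
addition: rows in unconvertible units (e.g. `ug/mL`) cannot be normalized
to nM and are rejected with their own audit line rather than silently
propagated. Whether the relaxed policy should admit activity types beyond
Ki/IC50 is genuinely open ("defined potency values" can be read either
way); we default both policies to {Ki, IC50} for comparability and expose
the set in the policy config. Compound identity is taken from
`compound_id` as given — no salt stripping or parent-structure merging.

## Activity records

Curated rows are grouped by (compound, target). All potencies are
converted to nM (nM×1, uM×10³, M×10⁹) and pooled across assays and
documents. Two values count as *the same* iff they agree after rounding to
three significant figures — a cited potency re-printed as 1.23 µM vs
1230 nM must match, and no tolerance is stated in the source analyses, so
this is a documented choice. Mixed Ki/IC50 values within a record are
pooled and compared value-only.

Records are classified by a decision tree: a single publication splits on
the number of *reported* values (one vs several, duplicates included,
because replicate reporting within one paper is a feature of the
experiment count, not of value identity); multiple publications split on
whether a second *distinct* value exists — a multi-publication record with
one distinct value is the signature of a referenced (cited, not
re-measured) potency. The four classes partition the records.

The logarithmic potency range, log₁₀(max) − log₁₀(min), is computed over
the *rounded* values so that `log_range == 0 ⇔ n_distinct_values == 1`
holds as a strict invariant; at three significant figures the difference
from the raw-value range is below 0.005 log units, far inside the 1-log
display bins (≤1, (1,2], (2,3], >3). The range histogram defaults to
records with more than 10 publications, the regime where multi-log spreads
become common.

## Publication profiles and promiscuity

Per document we count distinct assays, targets and active (i.e. curated)
compounds, and classify: single assay / multiple assays on one target /
multiple assays on several targets. An assay is assumed to probe one
target and belong to one document; the profiler raises on the former
violation and warns on the latter, since only foreign data can break
them. Summary histograms use bins {1,2,3,4,5,>5}; journal rankings keep
journals above a publication-count threshold (default 100), ties broken
alphabetically.

A compound's **promiscuity degree** is its number of distinct targets
(= its record count), and its publication frequency is the size of the
union of its records' document sets. Both are binned over
{1,2,3,4,5,6–10,11–20,>20} and cross-tabulated in a degree × publication
matrix whose marginals equal the two binned distributions cell-exactly.
Four corner subsets are labelled, with "more than five" read as ≥ 6
(the binning separates "5" from "6–10", fixing the boundary): A = one
target in one publication, B = one target in > 5 publications, C = > 5
targets in one publication, D = > 5 targets in > 5 publications; all other
compounds are NONE, and the five labels partition the compounds.

Percentages are printed to one decimal, switching to two decimals below
0.1% (so a 0.02% cell is not flattened to 0.0%); means to one decimal;
full precision is retained internally.

## Synthetic corpus generator

The generator emits measurement/publication tables shaped like the curated
medicinal-chemistry literature, plus a ground-truth manifest. Default
conditions:

| parameter | default | meaning |
|---|---|---|
| degree distribution | ~69.7% degree 1 … 0.02% > 20 | observed compound counts per degree bin in the high-confidence literature set |
| publication-count distribution | ~94.5% singletons | observed compounds per number of source publications |
| assays per publication (mean) | 2.8 | sizes the shared document pool |
| log₁₀ potency | mean 2.0 (100 nM), between-record sd 1.2, within-record sd 0.5 | log-normal potency model; the within-record sd is a modelling choice justified only qualitatively by the multi-log ranges seen in heavily replicated records |
| multi-value probability | 0.107 | single-publication records with replicate values (the observed branch ratio 26,267/244,775) |
| referenced-value probability | 0.39 | multi-publication records repeating one identical cited value (4,828/12,363) |
| contamination fractions | 0.02–0.06 per rule | rows violating exactly one high-confidence rule each |
| target pool | 1566 | distinct targets available |

Degree and publication count are sampled independently per compound (the
real data shows no detectable correlation), each by drawing a bin and then
an integer uniformly within the band; the open `>20` band is capped at 80,
above the most promiscuous compounds on record. Documents are assigned to
a compound's records round-robin, which guarantees every record has at
least one document and every document is used — so any (degree,
publication-count) pair is realizable and no feasibility repair is needed
(documents carry no target cap). Each measurement gets its own assay,
tied to one document and one target, preserving the profiler's
assumptions. Units are drawn (70% nM, 25% uM, 5% M) and the emitted value
is the nM potency divided by the unit factor; the manifest stores the
value the pipeline will reconstruct (emitted × factor), so recovery is
exact to the bit. Referenced duplicates copy the identical emitted value
and unit. Contaminated rows clone a clean row under a fresh assay id and
mutate exactly one field, so the curation audit must count them per rule
exactly.

With these defaults the expected mean degree is ≈ 1.54 (the binned
distribution's mean under uniform within-band sampling), bracketing the
literature value of 1.5.

**What the generator does not emulate:** chemical structures and
structural series, target families, real assay heterogeneity (the
within-record scatter is i.i.d. log-normal, with no lab or protocol
effects), correlation between a compound's potency and its popularity,
journal-level differences beyond a categorical label, and the long
inter-document citation chains of real referenced values (duplication is
pairwise-exact but structureless). Passing tests therefore demonstrate
that the *pipeline arithmetic* is correct under realistic marginal
distributions — not that any scientific conclusion transfers to a given
real corpus.

## Numerical and design notes

- Tables are plain UTF-8 CSV/TSV; floats are written at full `repr`
  precision, so write→read round trips are exact and outputs are
  byte-stable (rows sorted by each schema's declared key).
- All randomness flows from one `numpy` `default_rng(seed)`; identical
  configs give byte-identical tables.
- The pipeline is deterministic given its input tables, which is what
  makes exact manifest recovery a meaningful contract.
- Problem sizes: the shared test corpus uses 1,500 compounds; the
  acceptance recomputation uses 10,000 compounds (≈ 24,000 rows), chosen
  to make per-bin sampling noise small while the whole suite stays
  interactive.
- Empty selections (e.g. a range histogram with no qualifying records)
  warn and return empty tables; empty inputs to distribution summaries
  raise, since a mean over nothing is undefined.
- The consistency checker verifies only arithmetic identities of a
  report (partitions, conservation, matrix marginals) and reports
  failures rather than raising, so it can also vet externally supplied
  summary numbers.

## Known limitations

- No adapter for ChEMBL SQLite dumps is included; the measurement-table
  schema is this package's own, and foreign exports must be mapped onto
  it by the caller.
- Journal names are not normalized; distinct abbreviations count as
  distinct journals.
- The value-identity rule (3 significant figures) and the within-record
  potency variance are modelling choices; both are exposed, documented
  and tested, but no claim is made that they match any specific
  database's internal standardization.
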