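# Methods

## Problem and scope

Spontaneous vaccine adverse-event reporting systems such as VAERS collect
unverified post-vaccination reports. A report names one or more
administered vaccines and one or more MedDRA-coded symptom terms; nothing
in a single report implies causation. `vaerslink` implements the standard
screening workflow over such data: count vaccine-symptom pair
occurrences, compute proportional reporting ratios (PRR) overall and per
calendar year with per-year age and gender breakdowns, publish the
associations as RDF/Turtle linked data, and analyse the topology of the
bipartite network formed by associations whose PRR exceeds 1.

## Counting model

The counting unit is the **pair occurrence**: one distinct
(report, vaccine, symptom) triple. A report listing j vaccines and k
symptoms contributes j·k occurrences. Duplicate vaccine codes or symptom
terms within one report are collapsed at join time, so a pair is counted
at most once per report; this makes "number of reports containing the
pair" well defined even when a vaccine is listed twice (e.g. two doses).
Reports are dated by the received date — the only date field carried by
the Data table — and only its year is used.

## The PRR statistic

For vaccine v and symptom s, with n_vs pair occurrences of (v,s), n_v
occurrences involving v, n_s involving s, and n_total occurrences in
scope:

- **paper mode (default):** PRR = (n_vs/n_v) / (n_s/n_total). The
  comparator frequency pools *all* vaccines, including v itself.
- **classic mode:** PRR = (n_vs/n_v) / ((n_s−n_vs)/(n_total−n_v)), the
  index-excluded 2×2 form (Evans' PRR); undefined when the comparator
  cell is empty.

The pooled form is the default because it matches the verbatim
definition the RDF vocabulary was built around; the two agree within 5%
whenever n_v/n_total ≤ 1% and n_vs/n_s ≤ 1% (the usual situation for any
single vaccine in a large corpus), which the suite checks analytically
via a property test. The ratio of the two forms is
(1 − n_v/n_total)/(1 − n_vs/n_s), so the bound is exact, not empirical.

A PRR is emitted only where the pair occurs in scope (n_vs ≥ 1). Yearly
PRRs recompute all four counts from that year's occurrences alone —
yearly denominators are the year's totals, not all-time totals.
Significance is the strict screen PRR > 1, applied either to the pooled
PRR ("overall") or to any single year ("any_year"). The two rules are
not nested: pooling can push a pair's PRR above 1 when no single year
does (a Simpson-type reversal, exercised by a hand-built two-year
fixture in the tests). Because published headline tallies of
"significant associations" can count either distinct pairs or
(pair, year) combinations, `significant_associations` always reports
both. Optional screening filters (minimum pair count, minimum PRR) exist
for the known weakness of PRR on singleton pairs, but are off by
default.

Demographic breakdowns: per (pair, year), counts by gender
(MALE/FEMALE/UNKNOWN) and by age group. Default age bins: [0,1), [1,6),
[6,18), [18,65), [65,∞), plus UNKNOWN for missing age; bins are
configurable. Percentages are stored as fractions in [0,1] and rendered
to 7 significant digits (single-precision style, e.g. 31/63 →
0.4920635).

## RDF representation

One OWL instance `vaers:VaccineSymptomMeta_<k>` per pair, numbered in
sorted (vaccine, symptom) order (the published instance numbers follow
no stated scheme, so a deterministic one is used). The instance links to
vaccine and symptom individuals via `hasVaccine`/`hasSymptom` and
carries `hasOverallPRR`; yearly PRRs and per-year demographic cells are
blank detail nodes under `hasPRRDetail`/`hasVAERSAgeDetail`/
`hasVAERSGenderDetail`. Datatypes: xsd:float for PRRs and percentages,
xsd:long for years and counts, xsd:string for group labels. Vaccine
individual IRIs are the raw code (`vaers:PNC`); symptom IRIs are the
lowercased term with whitespace → underscores (`vaers:intussusception`).

Choices where the published description is open:

- The association class is spelled `VaccineSymptomAssociation`; the
  originally printed `VaccineSymotomAssociation` spelling is available
  behind `legacy_class_name=True`.
- Where the property list shows case inconsistency
  (`hasOVerallPRR`/`hasOverallPRR`), the lowercase form is canonical.
- `declare_individuals` (default on) adds rdf:type triples for
  associations, vaccines and symptoms plus rdfs:label on the individuals
  preserving the original term case; switched off, the graph holds
  exactly 3 + 3·|years| + 5·|age cells| + 5·|gender cells| statements
  per pair.
- Blank nodes get deterministic labels so repeated serializations are
  byte-identical, which is stricter than the graph-isomorphism
  determinism actually required.
- Round-trip parsing (`from_rdf`) recovers yearly counts from the
  demographic cell sums (each complete breakdown sums to the yearly
  count; for partial documents the larger sum is used).
- `link_stub` adds owl:sameAs triples from vaccine individuals to
  caller-supplied external IRIs (e.g. Vaccine Ontology identifiers);
  no ontology is fetched or imported.

## Network analysis

The signal network for a scope is the undirected bipartite graph with an
edge per pair whose PRR (pooled, or that year's) strictly exceeds the
threshold (default 1); nodes exist only where incident to an edge.
Metrics are unweighted: average degree 2L/N; average path length the
mean BFS distance over unordered pairs of distinct reachable nodes
(cross-component pairs are excluded rather than counted as infinite,
matching common network-analysis tooling); diameter the largest finite
distance. Yearly networks filter by the yearly PRR computed from that
year's reports only. Cross-year comparison reports every exclusive
region of the node-set Venn decomposition, split by node type.

## Synthetic data generator

The generator emulates the three-table layout with known ground truth.
Per report (one deterministic RNG sub-stream each, spawned from the
dataset seed): a year uniform over the range; a received date uniform
within the year; sex from a configurable M/F/U mix (default
0.35/0.55/0.10, female-skewed as in real passive surveillance); age from
a uniform-band mixture (infant 25%, child 20%, adult 45%, elderly 10%)
with 10% missing; 1–3 distinct vaccines uniform over the vocabulary; and
1–5 distinct symptoms drawn without replacement from the baseline
weights. Baseline symptom weights default to a 1/rank (Zipf) law,
mimicking the heavy skew of MedDRA term frequencies. A **signal**
(vaccine, symptom, enrichment ≥ 1, optional active years) multiplies the
symptom's weight by the enrichment whenever the vaccine is present, then
renormalizes — a mechanism chosen because it maps directly onto a
relative reporting ratio. Defaults (5,000 reports, 25 vaccines, 150
symptoms, 1990–2013) are a desk-scale stand-in: no empirical
vaccines-per-report or symptoms-per-report distributions are published
for the corpus the schema was designed around, so these are configurable
choices, not estimates.

What the generator does **not** model: duplicate report submission,
report-quality variation, free-text narratives, MedDRA hierarchy
structure, co-administration correlation between specific vaccines, or
secular trends in reporting volume. Passing tests therefore demonstrate
correctness of the counting, the statistic, the serialization and the
graph metrics — not robustness to real-world reporting artifacts.

## Numerical and degenerate-input choices

- Probability vectors must sum to 1 within 1e-9.
- PRR is undefined (None, no value emitted) for n_vs = 0 and for an
  empty classic comparator; undefined PRRs never create network edges.
- An empty dataset flows through every stage as empty-but-valid
  artifacts (header-only CSVs, a prefix-only Turtle file, NaN network
  metrics flagged as undefined and serialized as JSON null).
- Orphan Vaccine/Symptom rows (no matching Data entry) are dropped with
  a warning tally, never an error.
- CSV encoding: UTF-8 with Latin-1 fallback, since real exports of this
  kind are Latin-1.
- Floats in RDF literals and the 7-significant-digit rendering: values
  equal after round-tripping up to that rendering, which the round-trip
  tests compare at.

## Problem sizes used by the test suite and acceptance script

The statistical suites use 100 replicates of 600 reports (null
calibration of the PRR: mean over pairs with ≥ 20 occurrences within
[0.8, 1.2]) and 100 replicates of 1,200 reports (injected enrichment-5
signal with ≥ 200 signal-vaccine occurrences recovered in ≥ 95% of
replicates). `scripts/acceptance.py` runs one 20,000-report study with
five injected signals plus a 50-replicate recovery-rate estimate; these
sizes keep a full run around a minute on one CPU while leaving every
screened quantity well away from small-sample noise.

## Known limitations

- Whether published per-year network rows filter by yearly PRR or by
  pooled PRR restricted to the year is not documented; the yearly-PRR
  reading is implemented and the alternative is not offered.
- Average path length over disconnected graphs depends on the
  excluded-pair convention; computing it on the largest component only
  would differ and is not offered.
- No confidence intervals or alternative disproportionality statistics
  (ROR, EBGM, chi-square) — the screen is the plain PRR > 1 rule.
- The pre-2007 single-symptom-column VAERS dialect is not parsed.
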