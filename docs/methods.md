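# Methods

## The mapping procedure and its assumptions

The toolkit operationalizes the standard claims-to-OMOP feasibility
workflow in four stages.

**1. Vocabulary state classification.** Each local code is looked up in the
concept store under the vocabularies declared compatible with its local
vocabulary, in precedence order (`DEFAULT_VOCAB_COMPAT`): ICD10-BMSG checks
the WHO-like `ICD10` vocabulary before the clinical-modification-like
`ICD10CM`; ATC checks `ATC`; professional groups check `Medicare
Specialty`. A *valid* verbatim hit whose standard concept is resolvable
(itself if standard, else the smallest-id standard `Maps to` target) is S1.
A verbatim hit that is deprecated (`invalid_reason` set) is not S1: its
`Concept replaced by` edges are followed transitively (breadth-first,
cycle-safe) and the nearest valid successor with a standard resolution
makes the code S2 — this is how vocabulary revisions such as a withdrawn
ingredient code pointing at its successor are resolved mechanically.
Failing that, a manual hint (a curated `local code → concept id` table, the
product of a human USAGI session) makes the code S2. Everything else is S3.
The classifier never auto-accepts a fuzzy lexical match: `suggest_candidates`
is a curation aid, not mapping evidence, because silent acceptance of
string similarity is how mis-mappings enter a CDM.

**2. Import.** S1/S2 codes become new non-standard concepts under their
*local* vocabulary id (so an S1 code can coexist with the store-side entry
it duplicates without violating `(vocabulary_id, concept_code)`
uniqueness). Ids are assigned from 2,000,000,000 upward — the OHDSI
convention for locally authored concepts — sequentially in sorted
`(vocabulary_id, code)` order, which makes ids reproducible. Each import
adds exactly one `Maps to` edge to the resolved standard concept. Import is
idempotent: codes already present under their local vocabulary are skipped.

**3. ETL.** All source rows are staged, stays and diagnoses are
deduplicated, then the CDM tables are built in a fixed order (person,
observation periods, providers, visits, drug exposures, clinical events,
SEI observations). Conventions:

* CDM v6.0: death is `person.death_datetime` (at midnight — the source has
  daily granularity), no separate death table.
* One observation period per person spanning the configured study period
  (default 2008-01-01..2011-12-31), because claims extracts carry no
  per-person enrolment window.
* One *virtual provider* per distinct prescriber specialty, ids in sorted
  specialty order; the CDM allows one specialty per provider and the source
  identifies prescribers only by specialty, so this loses nothing.
* Drug exposures are one-for-one with prescriptions (no dedup applies to
  drugs); the exposure end date, absent from claims, is set equal to the
  start date — the least-information choice satisfying end ≥ start. The
  product PRN is kept in `drug_source_value`; the ATC ingredient supplies
  `drug_concept_id` and the imported local ATC concept supplies
  `drug_source_concept_id`, which keeps the ATC code recoverable from the
  CDM alone.
* Deduplicated diagnoses are routed by the domain of their mapped standard
  concept (Condition/Procedure/Measurement/Observation); unmapped codes go
  to a configurable default table (`condition_occurrence` — in claims
  practice a diagnosis is a condition unless proven otherwise) with concept
  id 0. The event date is the diagnosis's own date when present, else the
  linked stay's admission date (prefer the more specific datum).
* The socio-economic index has no standard concept, so it lands in
  `observation` with concept id 0, its numeric value preserved, tagged
  `observation_source_value = "SEI"`, dated at the study start (it is a
  per-person attribute without a date of its own).
* Mandatory fields with no source counterpart (race, ethnicity, provider
  gender, all `*_type_concept_id`) carry concept id 0; the fixture store
  does not model type concepts, and the schema invariant is that every
  concept-valued field is 0 or resolves in the store.
* Ids are assigned sequentially per table in source row order; the whole
  transform is deterministic, and repeated runs write byte-identical CSVs.
* Unpopulated CDM tables (costs, locations, eras, ...) are emitted empty,
  never omitted, so the sink is a structurally complete instance.

**4. Validation.** Three checks, each computable from the run artifacts
alone. *Counts*: CDM row count must equal source count minus the duplicates
the ETL report claims, for person↔patient, drug_exposure↔prescription,
visit_occurrence↔hospital_stay and the four event tables↔diagnosis (SEI
observations excluded from the event tally via their source-value tag).
*Record-wise equivalence*: a source-shaped view is reconstructed from CDM
rows only — pseudonyms from `person_source_value`, stay keys from
`visit_source_value`, ATC codes through `drug_source_concept_id`,
specialties through the provider table — and diffed against the
deduplicated source; keyed tables (patients, deaths, stays) are compared
field by field, unkeyed ones (prescriptions, diagnoses) as row multisets,
which is unambiguous because deduplicated rows are unique on their full
field tuple. *Statistics*: the five indicators are computed with identical
conventions on both sides and must be exactly equal; there is no tolerance,
because both sides describe the same finite population.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `EtlConfig.study_start/end` | 2008-01-01 / 2011-12-31 | date | four-year claims study window |
| `inpatient_visit_concept_id` | 9201 | concept id | the fixture store's inpatient visit concept |
| `gender_map` | F→8532, M→8507 | concept ids | OMOP gender concepts; unmapped codes → 0 |
| `dedup_policy` | `full_row` | — | exact-duplicate semantics (see below) |
| `default_event_table` | `condition_occurrence` | — | unmapped diagnosis routing |
| local concept id start | 2,000,000,000 | concept id | OHDSI local-range convention |

Dedup key: all fields except the synthetic row key. Exact duplication is the
minimal reading of "duplicate records"; a `business_key` policy (dropping
the diagnosis date from the key) is available as a config option but makes
no fidelity claim.

Medians use the **lower-median** convention (element `(n−1)//2` of the
sorted values), so indicators on integer inputs are integers and no
interpolation convention can make the two sides differ spuriously. Age is
taken at the study-period start; length of stay is discharge − admission in
calendar days (same-day = 0); the per-person medians count persons with at
least one stay/prescription, and the all-persons variants are computed and
reported alongside since either denominator is defensible. All of these are
convention-invariant for the equality check, because both sides apply the
same rule.

Candidate suggestion normalizes names (lower-case, punctuation stripped,
token set sorted) and scores trigram-set Jaccard similarity; ranking is a
total order (score descending, concept id ascending), so store row order
can never change a ranking. Zero-score candidates are omitted.

## What the synthetic data emulates — and what it does not

The source generator emulates an elderly claims cohort: ages 70 plus a
truncated exponential (scale 12 years, capped at 100) putting the median
age in the late seventies; 50.82% female; 15% deaths inside the window;
Poisson counts of prescriptions (mean 30/person), stays (mean 2/person,
lengths Poisson with mean 5 days) and diagnoses (mean 2/stay plus sparse
ambulatory diagnoses); Zipf-like code usage so a small cohort exercises a
long tail of codes; a consistent product→ingredient (PRN→ATC) mapping;
missing-field noise (10% SEI, 1% sex, 30% of stay-linked diagnosis dates);
and 5% injected duplicate stay and diagnosis records, byte-identical copies
of existing rows. Natural rows are made unique on the dedup key before
injection, so the injected duplicates are *exactly* what an exact-duplicate
scan finds — this is what lets the dedup count be asserted to equality.

The vocabulary fixture gives each local vocabulary the state mix claims
vocabularies actually occupy: diagnosis codes 92% S1 / 8% S2 (with a small
share present only in the CM-like vocabulary and a share present in both,
to exercise the WHO-first precedence), ingredient codes 90% S1 / 10% S2
(the S2 share via deprecated concepts with replacement chains of length 1
or 2), product numbers and the SEI entirely S3, and professional groups
mapped by hints with a 20% unmappable remainder. Diagnosis standard
concepts are spread 85/5/5/5 over the four event domains.

Passing tests on this data therefore demonstrate the *mechanics* — no
record loss, exact reconstruction, exact classification against ground
truth — under realistic shape and noise. They do not demonstrate anything
about real Austrian epidemiology, real ICD10-BMSG↔ICD10 coverage rates, or
the semantic quality of any manual S2 mapping: those depend on the real
extract and the full vocabulary release, which do not travel with the
package. Volumes are desk-scale by default (500 patients, ~15k
prescriptions, seconds per run); paper-scale cohorts are reachable through
`SourceGenConfig` but buy no additional coverage for these properties.

## Numerical and degenerate-input choices

* Ties in standard resolution (several standard `Maps to` targets) break to
  the smallest concept id; replacement traversal prefers the nearest valid
  successor.
* A verbatim valid hit with *no* resolvable standard concept is not S1; it
  falls through to hint/S3 (an assessment in S1/S2 always carries a
  standard concept id).
* Empty inputs are first-class: zero patients give five empty tables, an
  empty CDM, all-zero reports; descriptive indicators on an empty person
  table are `undefined` (None), never zero.
* Scan-report frequency lists order by count descending then value
  ascending.
* CSV persistence uses ISO-8601 dates, empty string for missing text/dates
  and nullable integer columns for ids; the CDM write is all-or-nothing
  (staged in a temp directory, moved into place on success).

## Known limitations

* Record-wise ATC recovery relies on the ingredient code being imported
  (S1/S2). An S3 ingredient code — which does not occur under the default
  study conditions — would make the ATC column unrecoverable from the CDM
  and surface as equivalence diffs.
* Diagnosis row keys are not stored on CDM rows (no v6.0 column exists for
  them); the multiset comparison is sound because deduplicated rows are
  unique on their field tuple, but a single corrupted event row is reported
  as an unmatched source/CDM row pair rather than a named field.
* Single-field corruptions confined to source-value fields flip exactly
  the equivalence check; row deletions necessarily disturb counts (and
  possibly statistics) as well — "exactly one check fails" cannot hold for
  every conceivable corruption.
* S2 discovery is mechanical only where the store encodes it; the package
  deliberately provides no automatic semantic matching, and authoring
  genuinely new standard concepts for S3 terms is out of scope.
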