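# claims-omop

Map claims-style health data into the OMOP Common Data Model v6.0 and prove,
record by record, that nothing was lost on the way.

Claims databases such as the Austrian GAP-DRG hold pseudonymized social-
insurance and hospital-stay data in proprietary schemas, coded in *local
vocabularies*: the Austrian ICD-10 variant (ICD10-BMSG) for diagnoses, ATC
for drug ingredients, pharmaceutical registration numbers (PRN) for
products, free-text prescriber professional groups, and a socio-economic
index (SEI). Reusing such data across studies requires standardizing it
into the OMOP CDM, whose analyses key entirely on *standard concepts*.
This package is a toolkit for that feasibility workflow, aimed at health
informaticians preparing claims extracts for OHDSI-style research:

* **Vocabulary mapping** (`claims_omop.vocabulary`) — every local code is
  assigned one of three states against an Athena-style concept store:

  | state | meaning | resolution |
  |-------|---------|------------|
  | S1 | code exists verbatim (and valid) in an OMOP vocabulary | adopt its standard concept |
  | S2 | not validly present, but a semantically equivalent standard concept exists | follow `Concept replaced by` chains, or a manual (USAGI-assisted) hint |
  | S3 | no equivalent standard concept | cannot be imported in a standardized fashion |

  S1/S2 codes are imported as new non-standard concepts (ids from the
  reserved 2-billion range) carrying exactly one `Maps to` relationship to
  their standard concept. A USAGI-style lexical matcher (token-set trigram
  similarity) suggests candidate concepts for manual S2 curation.

* **Source model and scan** (`claims_omop.source_model`) — schema,
  integrity checking and CSV I/O for the five source tables (patients,
  deaths, prescriptions, hospital stays, diagnoses), plus a WhiteRabbit-
  style profile of tables, columns, types, missingness and value
  frequencies.

* **ETL** (`claims_omop.etl`, `claims_omop.cdm_model`) — deterministic
  transform into a CDM v6.0 subset: patients + deaths → `person` (death
  lives on the person row in v6.0); one observation period per person
  spanning the study period; *virtual providers*, one per prescriber
  specialty; exact-duplicate removal for stays and diagnoses; diagnoses
  routed by the domain of their mapped concept across
  `condition_occurrence` / `procedure_occurrence` / `measurement` /
  `observation`; unavailable mandatory fields filled with concept id 0.

* **Validation** (`claims_omop.validation`) — three checks: count
  reconciliation (CDM count = source count − removed duplicates),
  record-wise equivalence (a source-shaped view reconstructed purely from
  CDM rows is diffed against the deduplicated source), and exact equality
  of descriptive statistics (percent female, median age, hospitalizations
  and prescriptions per person, length of stay) computed on both sides.

* **Synthetic data** (`claims_omop.synthetic_data`) — seeded generators
  for an elderly claims cohort and a matching fixture concept store with
  known ground truth (true code states, injected duplicate row keys), so
  the whole chain is testable without any real data or vocabulary
  downloads.

## Worked example

```python
import claims_omop as co

# a seeded synthetic study: 500 patients aged 70+, four-year study period,
# long-tailed ICD/ATC/PRN coding, injected duplicate records
source, store, truth = co.generate_study(seed=1)

# classify -> import -> transform -> validate
result = co.run_pipeline(source, store, hints=truth.hints)

s = result.summary
print(f"local codes assessed: {s.n_codes} "
      f"(S1 {s.counts['S1']}, S2 {s.counts['S2']}, S3 {s.counts['S3']})")
print(f"imported as new concepts: {len(result.import_report.imported)}")
r = result.etl_report
print(f"persons {r.output_rows['person']}, drug exposures "
      f"{r.output_rows['drug_exposure']}, visits {r.output_rows['visit_occurrence']}")
print(f"duplicates removed: {r.stay_duplicates_removed} stays, "
      f"{r.diagnosis_duplicates_removed} diagnoses")
print(f"validation passed: {result.validation.passed}")
```

prints

```
local codes assessed: 140 (S1 63, S2 14, S3 63)
imported as new concepts: 77
persons 500, drug exposures 14630, visits 1000
duplicates removed: 50 stays, 113 diagnoses
validation passed: True
```

Reading the numbers: 140 distinct local codes occur in this cohort; the 63
S1 codes were found verbatim in the fixture vocabularies and the 14 S2
codes through replacement chains or manual hints, so 77 concepts were
imported with `Maps to` links; the 63 S3 codes (every PRN, the unmappable
professional groups, the SEI) stay unstandardized, exactly as reported by
the import step. All 500 patients and all 14,630 prescriptions arrive in
the CDM one-for-one; 1,050 source stay rows become 1,000 visits because 50
injected duplicates were removed — and the validator confirms counts,
record-wise equivalence and descriptive statistics against the source.

The same workflow is available from a shell:

```bash
claims-omop simulate --out study --seed 1
claims-omop scan --source study/source --out scan.json
claims-omop map-vocab --store study/store --codes codes.csv \
    --hints study/hints.csv --out assessments.csv
claims-omop run --source study/source --store study/store \
    --assessments assessments.csv --out study/cdm --report etl.json
claims-omop validate --source study/source --cdm study/cdm \
    --report etl.json --out validation.json   # exit code 0 iff all checks pass
```

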