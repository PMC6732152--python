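"""Seeded generators for claims-style source data and vocabulary fixtures.

The source generator emulates the shape of an elderly Austrian claims
cohort: patients over 70 with a long-tailed (Zipf-like) use of ICD-10-like
diagnosis codes, ATC-like ingredient codes and PRN-like product numbers,
prescriber professional groups, hospital stays with stay-linked and
ambulatory diagnoses, injected byte-identical duplicate stay/diagnosis
records, and missing-field noise (socio-economic index, sex, diagnosis
dates).  The vocabulary generator builds a miniature Athena-style concept
store in which every local code has a *known* state: verbatim present
(S1), reachable through "Concept replaced by" chains or a manual hint
(S2), or absent (S3).  Both return the ground truth needed to use them as
test oracles: the injected duplicate row keys and the true state and
standard concept of every code.

Everything is driven by a single integer seed; per-table substreams are
derived deterministically, so identical configs give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .source_model import CsvDialect, SourceDataset
from .vocabulary import ConceptStore, CONCEPT_COLUMNS, RELATIONSHIP_COLUMNS, VOCABULARY_COLUMNS

__all__ = [
    "SourceGenConfig",
    "VocabGenConfig",
    "GroundTruth",
    "GenerationError",
    "generate_source",
    "generate_vocabulary_fixture",
    "build_code_pools",
    "generate_study",
    "DEFAULT_PROFESSIONAL_GROUPS",
]


class GenerationError(ValueError):
    """Invalid generator configuration."""


DEFAULT_PROFESSIONAL_GROUPS = (
    "general medicine",
    "internal medicine",
    "cardiology",
    "neurology",
    "orthopedics",
    "radiology",
    "laboratory medicine",
    "pulmonology",
    "other facility",
    "transport service",
)

_ADJECTIVES = ("acute", "chronic", "mild", "severe", "recurrent", "unspecified")
_NOUNS = (
    "cardiomyopathy", "bronchitis", "fracture", "nephropathy", "dermatitis",
    "arthritis", "anemia", "hypertension", "ulcer", "migraine", "pneumonia",
    "embolism", "neuropathy", "cirrhosis", "glaucoma",
)
_DRUG_NOUNS = (
    "metoprolol", "simvastatin", "ramipril", "amlodipine", "furosemide",
    "pantoprazole", "warfarin", "insulin", "alitretinoin", "tretinoin",
    "diclofenac", "levothyroxine", "allopurinol", "amoxicillin", "tramadol",
)


@dataclass
class SourceGenConfig:
    """Study conditions of the emulated claims extract.

    Defaults describe a desk-scale elderly cohort: 500 patients aged 70+
    (age 70 plus a truncated exponential, so the cohort median age sits in
    the late seventies), 50.82% female, observed over a four-year study
    period, with long-tailed code usage and a 5% duplicate-injection rate
    on stays and diagnoses.
    """

    n_patients: int = 500
    age_range: tuple[int, int] = (70, 100)
    age_scale: float = 12.0  # exponential scale of (age - minimum age)
    female_probability: float = 0.5082
    death_probability: float = 0.15
    mean_prescriptions_per_person: float = 30.0
    mean_stays_per_person: float = 2.0
    mean_diagnoses_per_stay: float = 2.0
    mean_ambulatory_diagnoses_per_person: float = 0.5
    mean_length_of_stay: float = 5.0
    stay_duplicate_rate: float = 0.05
    diagnosis_duplicate_rate: float = 0.05
    sei_missing_rate: float = 0.10
    sex_missing_rate: float = 0.01
    diag_date_missing_rate: float = 0.30
    n_icd_codes: int = 50
    n_atc_codes: int = 30
    n_prn_codes: int = 60
    professional_groups: tuple[str, ...] = DEFAULT_PROFESSIONAL_GROUPS
    n_unmappable_groups: int = 2
    study_start: str = "2008-01-01"
    study_end: str = "2011-12-31"
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise GenerationError("n_patients must be >= 0")
        for name in ("female_probability", "death_probability", "stay_duplicate_rate",
                     "diagnosis_duplicate_rate", "sei_missing_rate",
                     "sex_missing_rate", "diag_date_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name}={v} outside [0, 1]")
        if self.age_range[0] > self.age_range[1]:
            raise GenerationError("age_range lower bound exceeds upper bound")
        if self.study_start > self.study_end:
            raise GenerationError("study_start after study_end")
        if self.n_unmappable_groups > len(self.professional_groups):
            raise GenerationError("more unmappable groups than groups")
        if min(self.n_icd_codes, self.n_atc_codes, self.n_prn_codes) < 1:
            raise GenerationError("code pools must be non-empty")


@dataclass
class VocabGenConfig:
    """Composition of the fixture concept store.

    ``fractions`` gives per-local-vocabulary (f_s1, f_s2, f_s3) shares of
    codes that are verbatim present / replacement- or hint-linked / absent.
    The defaults follow the states claims vocabularies actually occupy:
    diagnosis and ingredient codes are S1 with a small S2 remainder from
    vocabulary revisions, product numbers and the socio-economic index have
    no standard equivalents (S3), and professional groups are mapped
    manually (S2 hints) with an unmappable rest.
    """

    fractions: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "ICD10-BMSG": (0.92, 0.08, 0.0),
            "ATC-LOCAL": (0.90, 0.10, 0.0),
            "PRN": (0.0, 0.0, 1.0),
            "PROF-GROUP": (0.0, 0.8, 0.2),
            "SEI": (0.0, 0.0, 1.0),
        }
    )
    icd_cm_only_fraction: float = 0.06  # S1 codes present only in the CM-like vocabulary
    icd_both_fraction: float = 0.04  # S1 codes present in both (precedence exercised)
    s2_chain2_fraction: float = 0.3  # S2 codes whose replacement chain has length 2
    domain_probs: dict[str, float] = field(
        default_factory=lambda: {
            "Condition": 0.85, "Procedure": 0.05, "Measurement": 0.05, "Observation": 0.05,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        for vocab, (f1, f2, f3) in self.fractions.items():
            if min(f1, f2, f3) < 0 or abs(f1 + f2 + f3 - 1.0) > 1e-9:
                raise GenerationError(f"fractions for {vocab!r} must be >=0 and sum to 1")
        if abs(sum(self.domain_probs.values()) - 1.0) > 1e-9:
            raise GenerationError("domain_probs must sum to 1")


@dataclass
class GroundTruth:
    """What the generators know to be true about their output."""

    duplicate_stay_keys: list[str] = field(default_factory=list)
    duplicate_diag_keys: list[str] = field(default_factory=list)
    code_states: dict[tuple[str, str], dict] = field(default_factory=dict)
    hints: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "duplicate_stay_keys": self.duplicate_stay_keys,
            "duplicate_diag_keys": self.duplicate_diag_keys,
            "code_states": {
                f"{vocab}|{code}": info for (vocab, code), info in self.code_states.items()
            },
            "hints": self.hints,
        }


# ---------------------------------------------------------------------------
# code pools
# ---------------------------------------------------------------------------

def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def build_code_pools(config: SourceGenConfig) -> dict[str, list[str]]:
    """Deterministic local code pools (keyed by local vocabulary id).

    The PRN pool carries a consistent product->ingredient mapping: every
    PRN is tied to one ATC code, exposed under the ``"PRN->ATC"`` key.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 97])
    letters = [chr(ord("A") + i) for i in range(26)]

    icd: list[str] = []
    seen = set()
    while len(icd) < config.n_icd_codes:
        code = f"{rng.choice(letters)}{rng.integers(0, 100):02d}.{rng.integers(0, 10)}"
        if code not in seen:
            seen.add(code)
            icd.append(code)

    atc: list[str] = []
    seen = set()
    while len(atc) < config.n_atc_codes:
        code = (
            f"{rng.choice(letters[:14])}{rng.integers(0, 100):02d}"
            f"{rng.choice(letters)}{rng.choice(letters)}{rng.integers(0, 100):02d}"
        )
        if code not in seen:
            seen.add(code)
            atc.append(code)

    prn = [f"{1000000 + int(i)}" for i in rng.choice(9000000, size=config.n_prn_codes,
                                                     replace=False)]
    prn_to_atc = {p: atc[int(rng.choice(len(atc), p=_zipf_weights(len(atc))))] for p in prn}

    return {
        "ICD10-BMSG": icd,
        "ATC-LOCAL": atc,
        "PRN": prn,
        "PROF-GROUP": list(config.professional_groups),
        "SEI": ["SEI"],
        "PRN->ATC": prn_to_atc,  # type: ignore[dict-item]
    }


# ---------------------------------------------------------------------------
# source generation
# ---------------------------------------------------------------------------

def _random_dates(rng: np.random.Generator, n: int, start: date, end: date) -> list[str]:
    span = (end - start).days
    offsets = rng.integers(0, span + 1, size=n)
    return [(start + timedelta(days=int(o))).isoformat() for o in offsets]


def _inject_duplicates(
    df: pd.DataFrame, rate: float, rng: np.random.Generator, key_col: str
) -> tuple[pd.DataFrame, list[str]]:
    """Append byte-identical copies (row key included) of a sampled subset."""
    k = int(round(rate * len(df)))
    if k == 0 or len(df) == 0:
        return df, []
    idx = np.sort(rng.choice(len(df), size=min(k, len(df)), replace=False))
    copies = df.iloc[idx].copy()
    out = pd.concat([df, copies], ignore_index=True)
    return out, copies[key_col].tolist()


def generate_source(
    config: SourceGenConfig,
    code_pools: Optional[Mapping[str, list]] = None,
) -> tuple[SourceDataset, GroundTruth]:
    """Generate the five source tables plus duplicate ground truth.

    All event dates fall inside the study period; natural rows are unique
    on the deduplication key, so the injected duplicates are exactly the
    rows an exact-duplicate scan finds.
    """
    config.validate()
    pools = dict(code_pools) if code_pools is not None else build_code_pools(config)
    start = date.fromisoformat(config.study_start)
    end = date.fromisoformat(config.study_end)
    rngs = {name: np.random.default_rng([config.seed, i]) for i, name in enumerate(
        ("patient", "death", "prescription", "stay", "diagnosis", "dup"), start=1)}

    # patients ------------------------------------------------------------
    n = config.n_patients
    rng = rngs["patient"]
    keys = [f"P{i + 1:06d}" for i in range(n)]
    age_lo, age_hi = config.age_range
    ages = age_lo + np.minimum(
        np.floor(rng.exponential(config.age_scale, size=n)), age_hi - age_lo
    ).astype(int)
    sex = []
    for _ in range(n):
        if rng.random() < config.sex_missing_rate:
            sex.append("")
        else:
            sex.append("F" if rng.random() < config.female_probability else "M")
    sei = [
        pd.NA if rng.random() < config.sei_missing_rate else int(rng.integers(1, 11))
        for _ in range(n)
    ]
    patient = pd.DataFrame(
        {
            "patient_key": keys,
            "birth_year": (start.year - ages).astype("int64"),
            "sex_code": sex,
            "sei": pd.array(sei, dtype="Int64"),
        }
    )

    # deaths --------------------------------------------------------------
    rng = rngs["death"]
    died = [k for k in keys if rng.random() < config.death_probability]
    death = pd.DataFrame(
        {"patient_key": died, "death_date": _random_dates(rng, len(died), start, end)},
        columns=["patient_key", "death_date"],
    )

    # prescriptions -------------------------------------------------------
    rng = rngs["prescription"]
    prn_pool = list(pools["PRN"])
    prn_to_atc = pools["PRN->ATC"]
    groups = list(pools["PROF-GROUP"])
    w_prn = _zipf_weights(len(prn_pool))
    w_grp = _zipf_weights(len(groups))
    rx_rows = []
    for k in keys:
        for _ in range(int(rng.poisson(config.mean_prescriptions_per_person))):
            prn = prn_pool[int(rng.choice(len(prn_pool), p=w_prn))]
            rx_rows.append(
                {
                    "patient_key": k,
                    "prescription_date": _random_dates(rng, 1, start, end)[0],
                    "prn": prn,
                    "atc_code": prn_to_atc[prn],
                    "professional_group": groups[int(rng.choice(len(groups), p=w_grp))],
                }
            )
    prescription = pd.DataFrame(
        rx_rows,
        columns=["patient_key", "prescription_date", "prn", "atc_code", "professional_group"],
    ).astype(str) if rx_rows else pd.DataFrame(
        columns=["patient_key", "prescription_date", "prn", "atc_code", "professional_group"]
    )

    # hospital stays ------------------------------------------------------
    rng = rngs["stay"]
    stay_rows = []
    for k in keys:
        for _ in range(int(rng.poisson(config.mean_stays_per_person))):
            admission = date.fromisoformat(_random_dates(rng, 1, start, end)[0])
            los = int(rng.poisson(config.mean_length_of_stay))
            discharge = min(admission + timedelta(days=los), end)
            stay_rows.append(
                {
                    "patient_key": k,
                    "admission_date": admission.isoformat(),
                    "discharge_date": discharge.isoformat(),
                }
            )
    stays = pd.DataFrame(
        stay_rows, columns=["patient_key", "admission_date", "discharge_date"]
    )
    # natural rows must be unique on the dedup key so injected duplicates
    # are exactly what an exact-duplicate scan finds
    stays = stays.drop_duplicates().reset_index(drop=True)
    stays.insert(0, "stay_key", [f"HS{i + 1:06d}" for i in range(len(stays))])

    # diagnoses -----------------------------------------------------------
    rng = rngs["diagnosis"]
    icd_pool = list(pools["ICD10-BMSG"])
    w_icd = _zipf_weights(len(icd_pool))
    diag_rows = []
    for stay in stays.itertuples(index=False):
        admission = date.fromisoformat(stay.admission_date)
        discharge = date.fromisoformat(stay.discharge_date)
        n_diag = 1 + int(rng.poisson(max(config.mean_diagnoses_per_stay - 1.0, 0.0)))
        for _ in range(n_diag):
            if rng.random() < config.diag_date_missing_rate:
                diag_date = ""
            else:
                offset = int(rng.integers(0, (discharge - admission).days + 1))
                diag_date = (admission + timedelta(days=offset)).isoformat()
            diag_rows.append(
                {
                    "patient_key": stay.patient_key,
                    "icd10_code": icd_pool[int(rng.choice(len(icd_pool), p=w_icd))],
                    "stay_ref": stay.stay_key,
                    "diag_date": diag_date,
                }
            )
    for k in keys:
        for _ in range(int(rng.poisson(config.mean_ambulatory_diagnoses_per_person))):
            diag_rows.append(
                {
                    "patient_key": k,
                    "icd10_code": icd_pool[int(rng.choice(len(icd_pool), p=w_icd))],
                    "stay_ref": "",
                    "diag_date": _random_dates(rng, 1, start, end)[0],
                }
            )
    diagnosis = pd.DataFrame(
        diag_rows, columns=["patient_key", "icd10_code", "stay_ref", "diag_date"]
    )
    diagnosis = diagnosis.drop_duplicates().reset_index(drop=True)
    diagnosis.insert(0, "diag_key", [f"DG{i + 1:06d}" for i in range(len(diagnosis))])

    # duplicate injection -------------------------------------------------
    rng = rngs["dup"]
    stays, dup_stay_keys = _inject_duplicates(
        stays, config.stay_duplicate_rate, rng, "stay_key"
    )
    diagnosis, dup_diag_keys = _inject_duplicates(
        diagnosis, config.diagnosis_duplicate_rate, rng, "diag_key"
    )

    ds = SourceDataset(
        patient=patient,
        death=death,
        prescription=prescription,
        hospital_stay=stays,
        diagnosis=diagnosis,
        dialect=CsvDialect(),
    )
    ds.validate()
    truth = GroundTruth(
        duplicate_stay_keys=dup_stay_keys, duplicate_diag_keys=dup_diag_keys
    )
    return ds, truth


# ---------------------------------------------------------------------------
# vocabulary fixture generation
# ---------------------------------------------------------------------------

class _StoreBuilder:
    def __init__(self):
        self.concepts: list[dict] = []
        self.relationships: list[dict] = []
        self.vocabs: dict[str, int] = {}
        self._next_id = 1000

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id

    def concept(self, cid: int, name: str, domain: str, vocab: str, code: str,
                standard: str = "", invalid: str = "", cls: str = "Fixture") -> int:
        self.concepts.append(
            {
                "concept_id": cid,
                "concept_name": name,
                "domain_id": domain,
                "vocabulary_id": vocab,
                "concept_class_id": cls,
                "standard_concept": standard,
                "concept_code": code,
                "valid_start_date": "19700101",
                "valid_end_date": "20991231" if invalid == "" else "20111231",
                "invalid_reason": invalid,
            }
        )
        self.vocabs.setdefault(vocab, 0)
        return cid

    def relate(self, c1: int, c2: int, kind: str) -> None:
        self.relationships.append(
            {
                "concept_id_1": c1,
                "concept_id_2": c2,
                "relationship_id": kind,
                "valid_start_date": "19700101",
                "valid_end_date": "20991231",
                "invalid_reason": "",
            }
        )

    def build(self) -> ConceptStore:
        vocab_rows = [
            {
                "vocabulary_id": v,
                "vocabulary_name": f"{v} (fixture)",
                "vocabulary_reference": "synthetic fixture",
                "vocabulary_version": "fixture-1",
                "vocabulary_concept_id": 0,
            }
            for v in sorted(self.vocabs)
        ]
        return ConceptStore(
            pd.DataFrame(self.concepts, columns=CONCEPT_COLUMNS),
            pd.DataFrame(self.relationships, columns=RELATIONSHIP_COLUMNS),
            pd.DataFrame(vocab_rows, columns=VOCABULARY_COLUMNS),
        )


def _partition(codes: list[str], fractions: tuple[float, float, float],
               rng: np.random.Generator) -> tuple[list[str], list[str], list[str]]:
    n = len(codes)
    n_s2 = int(round(fractions[1] * n))
    n_s3 = int(round(fractions[2] * n))
    n_s1 = n - n_s2 - n_s3
    if n_s1 < 0:
        n_s3 += n_s1
        n_s1 = 0
    order = list(rng.permutation(n))
    shuffled = [codes[i] for i in order]
    return shuffled[:n_s1], shuffled[n_s1 : n_s1 + n_s2], shuffled[n_s1 + n_s2 :]


def _fixture_name(rng: np.random.Generator, nouns: tuple[str, ...], code: str) -> str:
    return f"{rng.choice(_ADJECTIVES)} {rng.choice(nouns)} {code}"


def generate_vocabulary_fixture(
    config: VocabGenConfig,
    code_pools: Mapping[str, list[str]],
) -> tuple[ConceptStore, GroundTruth]:
    """Build a fixture concept store with known per-code states.

    S1 codes exist verbatim as valid concepts mapped to standard concepts;
    S2 codes exist only as deprecated concepts whose "Concept replaced by"
    chain (length 1 or 2) ends in a valid concept with a standard mapping —
    except professional groups, whose S2 evidence is a manual hint; S3
    codes are absent.  The store also carries the gender, inpatient-visit
    and zero concepts the ETL configuration references.
    """
    config.validate()
    for vocab, (f1, f2, f3) in config.fractions.items():
        pool = code_pools.get(vocab, [])
        if not pool and (f1 + f2) > 0:
            raise GenerationError(f"empty code pool for {vocab!r} with non-S3 fractions")
    rng = np.random.default_rng([config.seed, 211])
    b = _StoreBuilder()
    truth = GroundTruth()

    b.concept(0, "No matching concept", "Metadata", "None", "No matching concept")
    b.concept(8507, "MALE", "Gender", "Gender", "M", standard="S")
    b.concept(8532, "FEMALE", "Gender", "Gender", "F", standard="S")
    b.concept(9201, "Inpatient Visit", "Visit", "Visit", "IP", standard="S")

    domains = list(config.domain_probs)
    domain_p = np.array([config.domain_probs[d] for d in domains])

    def make_standard(vocab: str, code_prefix: str, code: str, domain: str,
                      nouns: tuple[str, ...]) -> int:
        cid = b.new_id()
        b.concept(cid, _fixture_name(rng, nouns, code), domain, vocab,
                  f"{code_prefix}{code}", standard="S")
        return cid

    def populate(local_vocab: str, store_vocab: str, std_vocab: str,
                 std_prefix: str, nouns: tuple[str, ...], fixed_domain: str | None):
        codes = list(code_pools.get(local_vocab, []))
        s1, s2, s3 = _partition(codes, config.fractions[local_vocab], rng)
        for code in s1:
            domain = fixed_domain or domains[int(rng.choice(len(domains), p=domain_p))]
            std = make_standard(std_vocab, std_prefix, code, domain, nouns)
            placement = "primary"
            if local_vocab == "ICD10-BMSG":
                r = rng.random()
                if r < config.icd_cm_only_fraction:
                    placement = "cm_only"
                elif r < config.icd_cm_only_fraction + config.icd_both_fraction:
                    placement = "both"
            if placement in ("primary", "both"):
                cid = b.new_id()
                b.concept(cid, _fixture_name(rng, nouns, code), domain, store_vocab, code)
                b.relate(cid, std, "Maps to")
            if placement in ("cm_only", "both"):
                if placement == "both":
                    # the CM copy maps elsewhere; WHO-like precedence decides
                    domain_cm = fixed_domain or domains[int(rng.choice(len(domains), p=domain_p))]
                    std_cm = make_standard(std_vocab, std_prefix + "CM-", code,
                                           domain_cm, nouns)
                else:
                    std_cm = std
                cid = b.new_id()
                b.concept(cid, _fixture_name(rng, nouns, code), domain, "ICD10CM", code)
                b.relate(cid, std_cm, "Maps to")
                if placement == "cm_only":
                    std = std_cm
            truth.code_states[(local_vocab, code)] = {
                "state": "S1", "standard_concept_id": std,
            }
        for code in s2:
            domain = fixed_domain or domains[int(rng.choice(len(domains), p=domain_p))]
            std = make_standard(std_vocab, std_prefix, code, domain, nouns)
            successor = b.new_id()
            b.concept(successor, _fixture_name(rng, nouns, code), domain, store_vocab,
                      f"{code}R")
            b.relate(successor, std, "Maps to")
            deprecated = b.new_id()
            b.concept(deprecated, _fixture_name(rng, nouns, code), domain, store_vocab,
                      code, invalid="U")
            if rng.random() < config.s2_chain2_fraction:
                middle = b.new_id()
                b.concept(middle, _fixture_name(rng, nouns, code), domain, store_vocab,
                          f"{code}M", invalid="U")
                b.relate(deprecated, middle, "Concept replaced by")
                b.relate(middle, successor, "Concept replaced by")
            else:
                b.relate(deprecated, successor, "Concept replaced by")
            truth.code_states[(local_vocab, code)] = {
                "state": "S2", "standard_concept_id": std,
            }
        for code in s3:
            truth.code_states[(local_vocab, code)] = {
                "state": "S3", "standard_concept_id": None,
            }

    populate("ICD10-BMSG", "ICD10", "SNOMED", "SCT-", _NOUNS, None)
    populate("ATC-LOCAL", "ATC", "RxNorm", "RX-", _DRUG_NOUNS, "Drug")

    # professional groups: S2 evidence is a manual hint to a specialty concept
    groups = list(code_pools.get("PROF-GROUP", []))
    s1_g, s2_g, s3_g = _partition(groups, config.fractions["PROF-GROUP"], rng)
    for group in s1_g:
        cid = b.new_id()
        b.concept(cid, group, "Provider Specialty", "Medicare Specialty", group,
                  standard="S")
        truth.code_states[("PROF-GROUP", group)] = {
            "state": "S1", "standard_concept_id": cid,
        }
    for group in s2_g:
        cid = b.new_id()
        b.concept(cid, group.title(), "Provider Specialty", "Medicare Specialty",
                  f"MS-{len(b.concepts)}", standard="S")
        truth.hints[group] = cid
        truth.code_states[("PROF-GROUP", group)] = {
            "state": "S2", "standard_concept_id": cid,
        }
    for group in s3_g:
        truth.code_states[("PROF-GROUP", group)] = {
            "state": "S3", "standard_concept_id": None,
        }

    for vocab in ("PRN", "SEI"):
        _, _, s3 = _partition(
            list(code_pools.get(vocab, [])), config.fractions[vocab], rng
        )
        for code in s3:
            truth.code_states[(vocab, code)] = {
                "state": "S3", "standard_concept_id": None,
            }

    return b.build(), truth


# ---------------------------------------------------------------------------
# one-call study fixture
# ---------------------------------------------------------------------------

def generate_study(
    seed: int,
    source_config: Optional[SourceGenConfig] = None,
    vocab_config: Optional[VocabGenConfig] = None,
) -> tuple[SourceDataset, ConceptStore, GroundTruth]:
    """Generate a matched source dataset and vocabulary fixture.

    Source and vocabulary ground truths are merged into one object; the
    manual-mapping hints live on ``truth.hints``.
    """
    source_config = source_config or SourceGenConfig(seed=seed)
    if source_config.seed != seed:
        raise GenerationError("source_config.seed must equal the study seed")
    vocab_config = vocab_config or VocabGenConfig(seed=seed)
    pools = build_code_pools(source_config)
    store, vocab_truth = generate_vocabulary_fixture(vocab_config, pools)
    source, src_truth = generate_source(source_config, pools)
    truth = GroundTruth(
        duplicate_stay_keys=src_truth.duplicate_stay_keys,
        duplicate_diag_keys=src_truth.duplicate_diag_keys,
        code_states=vocab_truth.code_states,
        hints=vocab_truth.hints,
    )
    return source, store, truth
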