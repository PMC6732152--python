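"""Concept store and local-vocabulary mapping.

Claims extracts code their facts in *local vocabularies* — the Austrian
ICD-10 variant (ICD10-BMSG) for diagnoses, ATC for drug ingredients,
pharmaceutical registration numbers (PRN) for products, free-text prescriber
professional groups, and the socio-economic index (SEI).  Before the data
can live in an OMOP CDM instance every local code must be related to an
OMOP *standard concept*.  Each code is in exactly one of three states:

* **S1** — the code is present verbatim (and valid) in an OMOP vocabulary;
  its standard concept is adopted directly.
* **S2** — the code is not validly present, but a semantically equivalent
  standard concept exists.  Mechanically this is discovered only where the
  vocabulary release encodes it ("Concept replaced by" chains from a
  deprecated concept, followed transitively); otherwise it requires a
  manual hint (the human-curated, USAGI-assisted mapping step).
* **S3** — no equivalent standard concept exists; the code cannot be
  imported in a standardized fashion.

S1 and S2 codes are imported into the CDM vocabulary tables as new
non-standard concepts in a reserved local id range, each carrying exactly
one "Maps to" relationship to its standard concept.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Concept",
    "ConceptStore",
    "MappingAssessment",
    "CandidateMatch",
    "VocabularySummary",
    "ImportReport",
    "VocabularyError",
    "DEFAULT_VOCAB_COMPAT",
    "LOCAL_CONCEPT_ID_START",
    "classify_code",
    "classify_vocabulary",
    "suggest_candidates",
    "import_local_vocabulary",
    "name_similarity",
    "read_hints",
    "write_assessments",
    "read_assessments",
]

STATES = ("S1", "S2", "S3")

#: OHDSI convention: locally authored concepts live at and above 2 billion.
LOCAL_CONCEPT_ID_START = 2_000_000_000

CONCEPT_COLUMNS = [
    "concept_id",
    "concept_name",
    "domain_id",
    "vocabulary_id",
    "concept_class_id",
    "standard_concept",
    "concept_code",
    "valid_start_date",
    "valid_end_date",
    "invalid_reason",
]
RELATIONSHIP_COLUMNS = [
    "concept_id_1",
    "concept_id_2",
    "relationship_id",
    "valid_start_date",
    "valid_end_date",
    "invalid_reason",
]
VOCABULARY_COLUMNS = [
    "vocabulary_id",
    "vocabulary_name",
    "vocabulary_reference",
    "vocabulary_version",
    "vocabulary_concept_id",
]

#: which store-side vocabularies may satisfy a local vocabulary, in
#: precedence order (WHO-like ICD before the clinical modification).
DEFAULT_VOCAB_COMPAT: dict[str, tuple[str, ...]] = {
    "ICD10-BMSG": ("ICD10", "ICD10CM"),
    "ATC-LOCAL": ("ATC",),
    "PRN": ("RxNorm Extension", "RxNorm"),
    "PROF-GROUP": ("Medicare Specialty", "NUCC"),
    "SEI": ("SNOMED",),
}


class VocabularyError(ValueError):
    """Invalid concept-store content or mapping request."""


@dataclass(frozen=True)
class Concept:
    concept_id: int
    concept_name: str
    domain_id: str
    vocabulary_id: str
    concept_class_id: str
    standard_concept: str  # "S", "C" or ""
    concept_code: str
    invalid_reason: str  # "" when valid

    @property
    def is_standard(self) -> bool:
        return self.standard_concept == "S"

    @property
    def is_valid(self) -> bool:
        return self.invalid_reason == ""


class ConceptStore:
    """In-memory OMOP vocabulary subset: CONCEPT, CONCEPT_RELATIONSHIP, VOCABULARY.

    Persisted as Athena-style tab-separated files (``CONCEPT.csv`` etc. with
    ``\\t`` delimiters, dates as YYYYMMDD).
    """

    def __init__(
        self,
        concepts: pd.DataFrame,
        relationships: pd.DataFrame,
        vocabularies: pd.DataFrame,
    ):
        self.concepts = concepts.reset_index(drop=True)
        self.relationships = relationships.reset_index(drop=True)
        self.vocabularies = vocabularies.reset_index(drop=True)
        self._check()
        self._reindex()

    # -- construction -------------------------------------------------------

    @classmethod
    def empty(cls) -> "ConceptStore":
        return cls(
            pd.DataFrame(columns=CONCEPT_COLUMNS),
            pd.DataFrame(columns=RELATIONSHIP_COLUMNS),
            pd.DataFrame(columns=VOCABULARY_COLUMNS),
        )

    @classmethod
    def from_directory(cls, directory: str | Path) -> "ConceptStore":
        directory = Path(directory)

        def load(name: str, cols: list[str]) -> pd.DataFrame:
            path = directory / f"{name}.csv"
            if not path.exists():
                raise FileNotFoundError(path)
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
            if list(df.columns) != cols:
                raise VocabularyError(f"{path}: columns {list(df.columns)} != {cols}")
            return df

        concepts = load("CONCEPT", CONCEPT_COLUMNS)
        concepts["concept_id"] = concepts["concept_id"].astype("int64")
        rel = load("CONCEPT_RELATIONSHIP", RELATIONSHIP_COLUMNS)
        for c in ("concept_id_1", "concept_id_2"):
            rel[c] = rel[c].astype("int64")
        vocab = load("VOCABULARY", VOCABULARY_COLUMNS)
        return cls(concepts, rel, vocab)

    def to_directory(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.concepts.to_csv(directory / "CONCEPT.csv", sep="\t", index=False)
        self.relationships.to_csv(
            directory / "CONCEPT_RELATIONSHIP.csv", sep="\t", index=False
        )
        self.vocabularies.to_csv(directory / "VOCABULARY.csv", sep="\t", index=False)

    def copy(self) -> "ConceptStore":
        return ConceptStore(
            self.concepts.copy(), self.relationships.copy(), self.vocabularies.copy()
        )

    # -- invariants & indexes ------------------------------------------------

    def _check(self) -> None:
        ids = self.concepts["concept_id"]
        if ids.duplicated().any():
            raise VocabularyError(
                f"duplicate concept_id: {sorted(ids[ids.duplicated()])[:10]}"
            )
        pair_dup = self.concepts.duplicated(subset=["vocabulary_id", "concept_code"])
        if pair_dup.any():
            bad = self.concepts.loc[pair_dup, ["vocabulary_id", "concept_code"]]
            raise VocabularyError(
                f"duplicate (vocabulary_id, concept_code): {bad.values.tolist()[:10]}"
            )
        known = set(ids)
        for col in ("concept_id_1", "concept_id_2"):
            missing = set(self.relationships[col]) - known
            if missing:
                raise VocabularyError(
                    f"relationship endpoint(s) not in store: {sorted(missing)[:10]}"
                )
        trip = self.relationships.duplicated(
            subset=["concept_id_1", "concept_id_2", "relationship_id"]
        )
        if trip.any():
            raise VocabularyError("duplicate (source, target, kind) relationship triples")

    def _reindex(self) -> None:
        self._by_id: dict[int, Concept] = {}
        self._by_code: dict[tuple[str, str], Concept] = {}
        for row in self.concepts.itertuples(index=False):
            c = Concept(
                concept_id=int(row.concept_id),
                concept_name=row.concept_name,
                domain_id=row.domain_id,
                vocabulary_id=row.vocabulary_id,
                concept_class_id=row.concept_class_id,
                standard_concept=row.standard_concept,
                concept_code=row.concept_code,
                invalid_reason=row.invalid_reason,
            )
            self._by_id[c.concept_id] = c
            self._by_code[(c.vocabulary_id, c.concept_code)] = c
        self._edges: dict[tuple[int, str], list[int]] = {}
        for row in self.relationships.itertuples(index=False):
            key = (int(row.concept_id_1), row.relationship_id)
            self._edges.setdefault(key, []).append(int(row.concept_id_2))
        for targets in self._edges.values():
            targets.sort()

    # -- queries -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._by_id)

    def get(self, concept_id: int) -> Concept:
        try:
            return self._by_id[int(concept_id)]
        except KeyError:
            raise VocabularyError(f"concept_id {concept_id} not in store") from None

    def __contains__(self, concept_id: int) -> bool:
        return int(concept_id) in self._by_id

    def lookup(self, vocabulary_id: str, concept_code: str) -> Optional[Concept]:
        return self._by_code.get((vocabulary_id, concept_code))

    def related(self, concept_id: int, relationship_id: str) -> list[int]:
        """Targets of ``relationship_id`` edges from ``concept_id``, ascending."""
        return list(self._edges.get((int(concept_id), relationship_id), []))

    def resolve_standard(self, concept_id: int) -> Optional[int]:
        """The standard concept for ``concept_id``: itself if standard, else
        the smallest-id standard 'Maps to' target, else None."""
        concept = self.get(concept_id)
        if concept.is_standard:
            return concept.concept_id
        for target in self.related(concept_id, "Maps to"):
            if self.get(target).is_standard:
                return target
        return None

    # -- mutation (used by the import step) -----------------------------------

    def add_concepts(self, rows: pd.DataFrame) -> None:
        self.concepts = pd.concat([self.concepts, rows[CONCEPT_COLUMNS]], ignore_index=True)
        self._check()
        self._reindex()

    def add_relationships(self, rows: pd.DataFrame) -> None:
        self.relationships = pd.concat(
            [self.relationships, rows[RELATIONSHIP_COLUMNS]], ignore_index=True
        )
        self._check()
        self._reindex()

    def ensure_vocabulary(self, vocabulary_id: str, name: str = "") -> None:
        if vocabulary_id not in set(self.vocabularies["vocabulary_id"]):
            row = pd.DataFrame(
                [
                    {
                        "vocabulary_id": vocabulary_id,
                        "vocabulary_name": name or vocabulary_id,
                        "vocabulary_reference": "local",
                        "vocabulary_version": "local-import",
                        "vocabulary_concept_id": 0,
                    }
                ]
            )
            self.vocabularies = pd.concat([self.vocabularies, row], ignore_index=True)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappingAssessment:
    """Outcome of classifying one local code against the concept store."""

    local_code: str
    local_vocabulary_id: str
    state: str  # "S1" | "S2" | "S3"
    standard_concept_id: Optional[int] = None
    evidence: str = ""  # "verbatim" | "replacement" | "manual" | ""
    matched_concept_id: Optional[int] = None  # the store concept that carried the evidence

    def __post_init__(self):
        if self.state not in STATES:
            raise VocabularyError(f"unknown state {self.state!r}")
        if self.state in ("S1", "S2") and self.standard_concept_id is None:
            raise VocabularyError(f"{self.state} assessment requires standard_concept_id")
        if self.state == "S3" and self.standard_concept_id is not None:
            raise VocabularyError("S3 assessment must not carry a standard_concept_id")


def _follow_replacements(store: ConceptStore, concept_id: int) -> Optional[int]:
    """Walk 'Concept replaced by' edges transitively (BFS, cycle-safe) and
    return the standard concept of the nearest valid successor, if any."""
    seen = {concept_id}
    frontier = [concept_id]
    while frontier:
        nxt: list[int] = []
        for cid in frontier:
            for target in store.related(cid, "Concept replaced by"):
                if target in seen:
                    continue
                seen.add(target)
                tc = store.get(target)
                if tc.is_valid:
                    std = store.resolve_standard(target)
                    if std is not None:
                        return std
                nxt.append(target)
        frontier = nxt
    return None


def classify_code(
    code: str,
    vocab_id: str,
    store: ConceptStore,
    hints: Optional[Mapping[str, int]] = None,
    compat: Optional[Mapping[str, Sequence[str]]] = None,
) -> MappingAssessment:
    """Assign a local code its vocabulary state.

    S1: the code exists verbatim as a *valid* concept in a compatible
    store vocabulary (precedence order of ``compat``) and a standard
    concept is resolvable.  S2: a deprecated verbatim concept leads through
    "Concept replaced by" to a standard concept, or a manual hint supplies
    one.  Otherwise S3.
    """
    if code == "":
        raise VocabularyError("empty code cannot be classified")
    compat = compat or DEFAULT_VOCAB_COMPAT
    store_vocabs = compat.get(vocab_id, (vocab_id,))

    deprecated_hit: Optional[Concept] = None
    for sv in store_vocabs:
        concept = store.lookup(sv, code)
        if concept is None:
            continue
        if concept.is_valid:
            std = store.resolve_standard(concept.concept_id)
            if std is not None:
                return MappingAssessment(
                    local_code=code,
                    local_vocabulary_id=vocab_id,
                    state="S1",
                    standard_concept_id=std,
                    evidence="verbatim",
                    matched_concept_id=concept.concept_id,
                )
        elif deprecated_hit is None:
            deprecated_hit = concept

    if deprecated_hit is not None:
        std = _follow_replacements(store, deprecated_hit.concept_id)
        if std is not None:
            return MappingAssessment(
                local_code=code,
                local_vocabulary_id=vocab_id,
                state="S2",
                standard_concept_id=std,
                evidence="replacement",
                matched_concept_id=deprecated_hit.concept_id,
            )

    if hints and code in hints:
        target = int(hints[code])
        std = store.resolve_standard(target)
        if std is None:
            raise VocabularyError(
                f"hint for {code!r} points at concept {target} with no standard resolution"
            )
        return MappingAssessment(
            local_code=code,
            local_vocabulary_id=vocab_id,
            state="S2",
            standard_concept_id=std,
            evidence="manual",
            matched_concept_id=target,
        )

    return MappingAssessment(local_code=code, local_vocabulary_id=vocab_id, state="S3")


@dataclass
class VocabularySummary:
    """Per-state tallies plus the per-code assessments behind them."""

    assessments: dict[tuple[str, str], MappingAssessment]  # (vocab_id, code) -> assessment
    counts: dict[str, int]
    fractions: dict[str, float]

    @property
    def n_codes(self) -> int:
        return len(self.assessments)


def classify_vocabulary(
    codes: Iterable[tuple[str, str]],
    store: ConceptStore,
    hints: Optional[Mapping[str, int]] = None,
    compat: Optional[Mapping[str, Sequence[str]]] = None,
) -> VocabularySummary:
    """Classify a batch of (code, vocab_id) pairs.

    Duplicate pairs are collapsed with a warning.  Every distinct pair lands
    in exactly one state; fractions sum to 1 (empty summary for empty input).
    """
    seen: dict[tuple[str, str], MappingAssessment] = {}
    n_dup = 0
    for code, vocab_id in codes:
        key = (vocab_id, code)
        if key in seen:
            n_dup += 1
            continue
        seen[key] = classify_code(code, vocab_id, store, hints=hints, compat=compat)
    if n_dup:
        warnings.warn(f"collapsed {n_dup} duplicate (code, vocab_id) entries", stacklevel=2)
    counts = {s: 0 for s in STATES}
    for a in seen.values():
        counts[a.state] += 1
    total = len(seen)
    fractions = {s: (counts[s] / total if total else 0.0) for s in STATES}
    return VocabularySummary(assessments=seen, counts=counts, fractions=fractions)


# ---------------------------------------------------------------------------
# candidate suggestion (USAGI-style lexical matching)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateMatch:
    concept_id: int
    score: float
    matched_name: str


_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def _normalize(name: str) -> str:
    tokens = sorted(set(t for t in _NON_ALNUM.split(name.lower()) if t))
    return " ".join(tokens)


def _trigrams(s: str) -> frozenset[str]:
    if len(s) < 3:
        return frozenset([s]) if s else frozenset()
    return frozenset(s[i : i + 3] for i in range(len(s) - 2))


def name_similarity(a: str, b: str) -> float:
    """Token-set trigram Jaccard similarity on lower-cased, punctuation-
    stripped names; 1.0 for identical normalised token sets, 0.0 for no
    shared trigrams."""
    ga, gb = _trigrams(_normalize(a)), _trigrams(_normalize(b))
    if not ga or not gb:
        return 0.0
    inter = len(ga & gb)
    if inter == 0:
        return 0.0
    return inter / len(ga | gb)


def suggest_candidates(
    term: str,
    store: ConceptStore,
    k: int = 10,
    domain_filter: Optional[str] = None,
) -> list[CandidateMatch]:
    """Rank valid store concepts by lexical similarity to ``term``.

    Deterministic total order: score descending, concept_id ascending;
    zero-score candidates are omitted.
    """
    if term == "":
        raise VocabularyError("empty term")
    if k < 1:
        raise VocabularyError("k must be >= 1")
    scored = []
    for concept in iter_concepts(store):
        if not concept.is_valid:
            continue
        if domain_filter is not None and concept.domain_id != domain_filter:
            continue
        score = name_similarity(term, concept.concept_name)
        if score > 0.0:
            scored.append(CandidateMatch(concept.concept_id, score, concept.concept_name))
    scored.sort(key=lambda m: (-m.score, m.concept_id))
    return scored[:k]


def iter_concepts(store: ConceptStore) -> Iterable[Concept]:
    """Concepts in ascending concept_id order, independent of row order."""
    return (store._by_id[cid] for cid in sorted(store._by_id))


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

@dataclass
class ImportReport:
    imported: list[dict] = field(default_factory=list)  # vocab, code, concept_id, standard_concept_id
    skipped_existing: list[dict] = field(default_factory=list)
    unimported_s3: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def import_local_vocabulary(
    assessments: Iterable[MappingAssessment],
    store: ConceptStore,
    id_start: int = LOCAL_CONCEPT_ID_START,
) -> tuple[ConceptStore, ImportReport]:
    """Import classified S1/S2 local codes as new non-standard concepts.

    Each imported code gets a fresh id from the reserved local range,
    sequential in sorted (vocabulary_id, code) order, and exactly one
    "Maps to" relationship to its standard concept.  S3 codes are listed as
    unimported.  Idempotent: codes already present under their local
    vocabulary are skipped, so re-importing changes nothing.
    """
    new_store = store.copy()
    report = ImportReport()

    todo: list[MappingAssessment] = []
    for a in sorted(assessments, key=lambda a: (a.local_vocabulary_id, a.local_code)):
        if a.state == "S3":
            report.unimported_s3.append(
                {"vocabulary_id": a.local_vocabulary_id, "code": a.local_code}
            )
            continue
        if a.standard_concept_id is None:  # defensive; MappingAssessment enforces it
            raise VocabularyError(
                f"{a.state} assessment for {a.local_code!r} lacks standard_concept_id"
            )
        existing = new_store.lookup(a.local_vocabulary_id, a.local_code)
        if existing is not None:
            report.skipped_existing.append(
                {
                    "vocabulary_id": a.local_vocabulary_id,
                    "code": a.local_code,
                    "concept_id": existing.concept_id,
                }
            )
            continue
        todo.append(a)

    local_ids = [cid for cid in new_store._by_id if cid >= id_start]
    next_id = max(local_ids, default=id_start - 1) + 1

    concept_rows, rel_rows = [], []
    for a in todo:
        std = new_store.get(a.standard_concept_id)
        if not std.is_standard:
            raise VocabularyError(
                f"standard_concept_id {a.standard_concept_id} for {a.local_code!r} "
                "is not a standard concept"
            )
        new_store.ensure_vocabulary(a.local_vocabulary_id)
        concept_rows.append(
            {
                "concept_id": next_id,
                "concept_name": a.local_code,
                "domain_id": std.domain_id,
                "vocabulary_id": a.local_vocabulary_id,
                "concept_class_id": "Local Code",
                "standard_concept": "",
                "concept_code": a.local_code,
                "valid_start_date": "19700101",
                "valid_end_date": "20991231",
                "invalid_reason": "",
            }
        )
        rel_rows.append(
            {
                "concept_id_1": next_id,
                "concept_id_2": a.standard_concept_id,
                "relationship_id": "Maps to",
                "valid_start_date": "19700101",
                "valid_end_date": "20991231",
                "invalid_reason": "",
            }
        )
        report.imported.append(
            {
                "vocabulary_id": a.local_vocabulary_id,
                "code": a.local_code,
                "concept_id": next_id,
                "standard_concept_id": a.standard_concept_id,
            }
        )
        next_id += 1

    if concept_rows:
        new_store.add_concepts(pd.DataFrame(concept_rows))
        new_store.add_relationships(pd.DataFrame(rel_rows))
    return new_store, report


# ---------------------------------------------------------------------------
# file helpers (CLI surface)
# ---------------------------------------------------------------------------

def read_hints(path: str | Path) -> dict[str, int]:
    """Two-column CSV (local_code, standard_concept_id) -> dict."""
    df = pd.read_csv(path, dtype={"local_code": str}, keep_default_na=False)
    return {
        row.local_code: int(row.standard_concept_id) for row in df.itertuples(index=False)
    }


def write_assessments(
    assessments: Iterable[MappingAssessment], path: str | Path
) -> None:
    rows = [
        {
            "local_code": a.local_code,
            "local_vocabulary_id": a.local_vocabulary_id,
            "state": a.state,
            "standard_concept_id": "" if a.standard_concept_id is None else a.standard_concept_id,
            "evidence": a.evidence,
        }
        for a in assessments
    ]
    pd.DataFrame(rows, columns=["local_code", "local_vocabulary_id", "state",
                                "standard_concept_id", "evidence"]).to_csv(path, index=False)


def read_assessments(path: str | Path) -> list[MappingAssessment]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            MappingAssessment(
                local_code=row.local_code,
                local_vocabulary_id=row.local_vocabulary_id,
                state=row.state,
                standard_concept_id=int(row.standard_concept_id)
                if row.standard_concept_id != ""
                else None,
                evidence=row.evidence,
            )
        )
    return out
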