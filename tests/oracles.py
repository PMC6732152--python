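"""Independent brute-force oracles the implementation is checked against.

These deliberately avoid the package's own lookup structures: linear scans
over plain row dicts, exhaustive relationship traversal, Counter-based
duplicate grouping and straight-line statistic recomputation.
"""

from __future__ import annotations

from collections import Counter
from datetime import date
from typing import Mapping, Optional, Sequence


def oracle_standard(concept: dict, concepts: list[dict], rels: list[dict]) -> Optional[int]:
    if concept["standard_concept"] == "S":
        return int(concept["concept_id"])
    by_id = {int(c["concept_id"]): c for c in concepts}
    targets = [
        int(r["concept_id_2"])
        for r in rels
        if int(r["concept_id_1"]) == int(concept["concept_id"])
        and r["relationship_id"] == "Maps to"
        and by_id[int(r["concept_id_2"])]["standard_concept"] == "S"
    ]
    return min(targets) if targets else None


def oracle_classify(
    code: str,
    vocab_id: str,
    concepts: list[dict],
    rels: list[dict],
    hints: Optional[Mapping[str, int]],
    compat: Mapping[str, Sequence[str]],
) -> tuple[str, Optional[int]]:
    """Linear membership test, then exhaustive replacement traversal."""
    store_vocabs = compat.get(vocab_id, (vocab_id,))
    deprecated = None
    for sv in store_vocabs:
        hits = [c for c in concepts if c["vocabulary_id"] == sv and c["concept_code"] == code]
        for c in hits:
            if c["invalid_reason"] == "":
                std = oracle_standard(c, concepts, rels)
                if std is not None:
                    return "S1", std
            elif deprecated is None:
                deprecated = c
    if deprecated is not None:
        by_id = {int(c["concept_id"]): c for c in concepts}
        reachable, frontier = set(), {int(deprecated["concept_id"])}
        while frontier:
            nxt = set()
            for r in rels:
                if (
                    r["relationship_id"] == "Concept replaced by"
                    and int(r["concept_id_1"]) in frontier
                    and int(r["concept_id_2"]) not in reachable
                ):
                    nxt.add(int(r["concept_id_2"]))
            reachable |= nxt
            frontier = nxt
        candidates = sorted(
            std
            for cid in reachable
            if by_id[cid]["invalid_reason"] == ""
            for std in [oracle_standard(by_id[cid], concepts, rels)]
            if std is not None
        )
        if candidates:
            return "S2", candidates[0]
    if hints and code in hints:
        target = {int(c["concept_id"]): c for c in concepts}[int(hints[code])]
        std = oracle_standard(target, concepts, rels)
        if std is not None:
            return "S2", std
    return "S3", None


def oracle_duplicates(rows: list[tuple]) -> int:
    """Exhaustive group-and-count: how many rows exceed their group's first."""
    return sum(n - 1 for n in Counter(rows).values())


def _lower_median(values):
    vals = sorted(values)
    return vals[(len(vals) - 1) // 2] if vals else None


def oracle_stats(source, female_codes=("F",), study_start="2008-01-01"):
    """Straight-line recomputation of the descriptive indicators from raw
    source rows (applying exact-duplicate removal to stays)."""
    patients = source.patient.to_dict("records")
    stays = source.hospital_stay.to_dict("records")
    seen, stays_dedup = set(), []
    for s in stays:
        key = (s["patient_key"], s["admission_date"], s["discharge_date"])
        if key not in seen:
            seen.add(key)
            stays_dedup.append(s)
    rx = source.prescription.to_dict("records")
    year = date.fromisoformat(study_start).year
    stay_counts = Counter(s["patient_key"] for s in stays_dedup)
    rx_counts = Counter(r["patient_key"] for r in rx)
    n = len(patients)
    if n == 0:
        return None
    return {
        "percent_female": 100.0 * sum(p["sex_code"] in female_codes for p in patients) / n,
        "median_age": _lower_median([year - p["birth_year"] for p in patients]),
        "median_hospitalizations_per_person": _lower_median(
            [c for c in stay_counts.values() if c > 0]
        ),
        "median_prescriptions_per_person": _lower_median(
            [c for c in rx_counts.values() if c > 0]
        ),
        "median_length_of_stay_days": _lower_median(
            [
                (date.fromisoformat(s["discharge_date"]) - date.fromisoformat(s["admission_date"])).days
                for s in stays_dedup
            ]
        ),
    }
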