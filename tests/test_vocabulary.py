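"""Vocabulary state classification, candidate suggestion and import."""

import pandas.testing as pdt
import pytest

from claims_omop import (
    MappingAssessment,
    VocabularyError,
    classify_code,
    classify_vocabulary,
    import_local_vocabulary,
    suggest_candidates,
)
from claims_omop.synthetic_data import SourceGenConfig, VocabGenConfig, build_code_pools, generate_vocabulary_fixture
from claims_omop.vocabulary import DEFAULT_VOCAB_COMPAT, name_similarity

from .conftest import make_store
from .oracles import oracle_classify


# ---------------------------------------------------------------------------
# classify_code
# ---------------------------------------------------------------------------

def test_verbatim_code_is_s1_with_mapped_standard(drug_store):
    a = classify_code("D10AD01", "ATC-LOCAL", drug_store)
    assert (a.state, a.standard_concept_id, a.evidence) == ("S1", 11, "verbatim")


def test_replaced_code_is_s2_targeting_successor(drug_store):
    """A deprecated ingredient code resolves through its replacement:
    D11AX19 (alitretinoin) was altered into D11AH04."""
    a = classify_code("D11AX19", "ATC-LOCAL", drug_store)
    assert a.state == "S2"
    assert a.standard_concept_id == 10  # D11AH04's standard concept
    assert a.evidence == "replacement"


def test_unknown_code_without_hint_is_s3(drug_store):
    a = classify_code("SEI", "SEI", drug_store)
    assert a.state == "S3"
    assert a.standard_concept_id is None


def test_hint_gives_s2_with_manual_evidence(drug_store):
    a = classify_code("other facility", "PROF-GROUP", drug_store, hints={"other facility": 12})
    assert (a.state, a.standard_concept_id, a.evidence) == ("S2", 12, "manual")


def test_empty_code_is_an_error(drug_store):
    with pytest.raises(VocabularyError):
        classify_code("", "ATC-LOCAL", drug_store)


def test_who_variant_takes_precedence_over_cm():
    """A code present in both ICD10-like vocabularies resolves through the
    WHO-like entry."""
    store = make_store(
        concept_rows=[
            (1, "who standard", "Condition", "SNOMED", "S1c", "S", ""),
            (2, "cm standard", "Condition", "SNOMED", "S2c", "S", ""),
            (3, "code who", "Condition", "ICD10", "A00.1", "", ""),
            (4, "code cm", "Condition", "ICD10CM", "A00.1", "", ""),
        ],
        relationship_rows=[(3, 1, "Maps to"), (4, 2, "Maps to")],
    )
    a = classify_code("A00.1", "ICD10-BMSG", store)
    assert (a.state, a.standard_concept_id) == ("S1", 1)


def test_deprecated_verbatim_hit_is_not_s1():
    store = make_store(
        concept_rows=[
            (1, "std", "Condition", "SNOMED", "sct1", "S", ""),
            (2, "old", "Condition", "ICD10", "B01.1", "", "U"),
            (3, "new", "Condition", "ICD10", "B01.1R", "", ""),
        ],
        relationship_rows=[(3, 1, "Maps to"), (2, 3, "Concept replaced by")],
    )
    a = classify_code("B01.1", "ICD10-BMSG", store)
    assert a.state == "S2"


# ---------------------------------------------------------------------------
# classify_vocabulary
# ---------------------------------------------------------------------------

def test_all_verbatim_gives_pure_s1(drug_store):
    summary = classify_vocabulary(
        [("D11AH04", "ATC-LOCAL"), ("D10AD01", "ATC-LOCAL")], drug_store
    )
    assert summary.counts == {"S1": 2, "S2": 0, "S3": 0}
    assert summary.fractions["S1"] == 1.0


def test_empty_input_gives_empty_summary(drug_store):
    summary = classify_vocabulary([], drug_store)
    assert summary.n_codes == 0
    assert summary.counts == {"S1": 0, "S2": 0, "S3": 0}


def test_duplicates_collapsed_with_warning(drug_store):
    with pytest.warns(UserWarning, match="duplicate"):
        summary = classify_vocabulary(
            [("D11AH04", "ATC-LOCAL"), ("D11AH04", "ATC-LOCAL")], drug_store
        )
    assert summary.n_codes == 1


def test_known_7_2_1_partition():
    """A hand-built store with ground truth 7 S1 / 2 S2 / 1 S3."""
    rows = [(100 + i, f"std {i}", "Condition", "SNOMED", f"sct{i}", "S", "") for i in range(9)]
    rows += [(200 + i, f"c{i}", "Condition", "ICD10", f"C{i:02d}.0", "", "") for i in range(7)]
    rows += [(300 + i, f"old{i}", "Condition", "ICD10", f"D{i:02d}.0", "", "U") for i in range(2)]
    rows += [(310 + i, f"new{i}", "Condition", "ICD10", f"D{i:02d}.0R", "", "") for i in range(2)]
    rels = [(200 + i, 100 + i, "Maps to") for i in range(7)]
    rels += [(310 + i, 107 + i, "Maps to") for i in range(2)]
    rels += [(300 + i, 310 + i, "Concept replaced by") for i in range(2)]
    store = make_store(rows, rels)
    codes = [(f"C{i:02d}.0", "ICD10-BMSG") for i in range(7)]
    codes += [(f"D{i:02d}.0", "ICD10-BMSG") for i in range(2)]
    codes += [("Z99.9", "ICD10-BMSG")]
    summary = classify_vocabulary(codes, store)
    assert summary.counts == {"S1": 7, "S2": 2, "S3": 1}
    # state partition: every code in exactly one state
    assert sum(summary.counts.values()) == len(codes)
    assert sum(summary.fractions.values()) == pytest.approx(1.0)


def test_classifier_agrees_with_brute_force_oracle():
    """Mechanical classification equals linear membership scan plus
    exhaustive replacement traversal, over generated fixture stores."""
    for seed in (0, 1, 2):
        pools = build_code_pools(SourceGenConfig(seed=seed, n_icd_codes=25, n_atc_codes=15))
        store, truth = generate_vocabulary_fixture(VocabGenConfig(seed=seed), pools)
        concepts = store.concepts.to_dict("records")
        rels = store.relationships.to_dict("records")
        for (vocab, code), info in truth.code_states.items():
            a = classify_code(code, vocab, store, hints=truth.hints)
            expected = oracle_classify(code, vocab, concepts, rels, truth.hints,
                                       DEFAULT_VOCAB_COMPAT)
            assert (a.state, a.standard_concept_id) == expected
            assert a.state == info["state"]


# ---------------------------------------------------------------------------
# suggest_candidates
# ---------------------------------------------------------------------------

def test_identical_name_ranks_first_with_score_one(drug_store):
    matches = suggest_candidates("tretinoin", drug_store, k=3)
    assert matches[0].concept_id == 11
    assert matches[0].score == 1.0


def test_disjoint_term_yields_empty_list(drug_store):
    assert suggest_candidates("xylophone quartz", drug_store, k=5) == []


def test_empty_term_is_error(drug_store):
    with pytest.raises(VocabularyError):
        suggest_candidates("", drug_store)


def test_ranking_equals_exhaustive_pairwise_scoring(drug_store):
    term = "alitretinoin oral"
    matches = suggest_candidates(term, drug_store, k=10)
    brute = []
    for row in drug_store.concepts.itertuples(index=False):
        if row.invalid_reason != "":
            continue
        s = name_similarity(term, row.concept_name)
        if s > 0:
            brute.append((-s, int(row.concept_id)))
    brute.sort()
    assert [(m.concept_id) for m in matches] == [cid for _, cid in brute]
    assert all(
        matches[i].score >= matches[i + 1].score for i in range(len(matches) - 1)
    )


def test_ranking_invariant_under_store_row_permutation(drug_store):
    from claims_omop.vocabulary import ConceptStore

    shuffled = ConceptStore(
        drug_store.concepts.iloc[::-1],
        drug_store.relationships.iloc[::-1],
        drug_store.vocabularies,
    )
    a = suggest_candidates("tretinoin topical", drug_store, k=5)
    b = suggest_candidates("tretinoin topical", shuffled, k=5)
    assert a == b


def test_domain_filter_restricts_candidates(drug_store):
    assert suggest_candidates("tretinoin", drug_store, k=5, domain_filter="Condition") == []


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def test_single_s1_import_adds_one_concept_and_one_edge(drug_store):
    a = classify_code("D10AD01", "ATC-LOCAL", drug_store)
    new_store, report = import_local_vocabulary([a], drug_store)
    assert len(new_store) == len(drug_store) + 1
    assert len(report.imported) == 1
    imported = new_store.lookup("ATC-LOCAL", "D10AD01")
    assert imported is not None and imported.concept_id >= 2_000_000_000
    targets = new_store.related(imported.concept_id, "Maps to")
    assert targets == [11]
    assert new_store.get(11).is_standard


def test_s3_codes_are_reported_not_imported(drug_store):
    a = MappingAssessment("SEI", "SEI", "S3")
    new_store, report = import_local_vocabulary([a], drug_store)
    assert len(new_store) == len(drug_store)
    assert report.unimported_s3 == [{"vocabulary_id": "SEI", "code": "SEI"}]


def test_reimport_is_a_no_op(drug_store):
    assessments = [
        classify_code("D10AD01", "ATC-LOCAL", drug_store),
        classify_code("D11AX19", "ATC-LOCAL", drug_store),
    ]
    once, _ = import_local_vocabulary(assessments, drug_store)
    twice, report = import_local_vocabulary(assessments, once)
    pdt.assert_frame_equal(once.concepts, twice.concepts)
    pdt.assert_frame_equal(once.relationships, twice.relationships)
    assert report.imported == []
    assert len(report.skipped_existing) == 2


def test_imported_ids_sequential_in_sorted_order(drug_store):
    assessments = [
        classify_code("D11AX19", "ATC-LOCAL", drug_store),
        classify_code("D10AD01", "ATC-LOCAL", drug_store),
    ]
    new_store, report = import_local_vocabulary(assessments, drug_store)
    # sorted (vocabulary_id, code): D10AD01 before D11AX19
    assert [r["code"] for r in report.imported] == ["D10AD01", "D11AX19"]
    assert [r["concept_id"] for r in report.imported] == [2_000_000_000, 2_000_000_001]


def test_s2_assessment_without_standard_is_rejected():
    with pytest.raises(VocabularyError):
        MappingAssessment("X", "ATC-LOCAL", "S2", standard_concept_id=None)


def test_import_outdegree_property(study):
    """Every imported concept has out-degree exactly 1 on Maps to, and the
    target is standard."""
    store = study["result"].store
    for row in study["result"].import_report.imported:
        targets = store.related(row["concept_id"], "Maps to")
        assert len(targets) == 1
        assert store.get(targets[0]).is_standard
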