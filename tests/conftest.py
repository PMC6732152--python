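import pandas as pd
import pytest

from claims_omop import EtlConfig, SourceGenConfig, generate_study, run_pipeline
from claims_omop.vocabulary import (
    CONCEPT_COLUMNS,
    RELATIONSHIP_COLUMNS,
    VOCABULARY_COLUMNS,
    ConceptStore,
)


def make_store(concept_rows, relationship_rows=(), vocab_ids=()):
    """Hand-build a concept store from terse row tuples.

    concept_rows: (concept_id, name, domain, vocab, code, standard, invalid)
    relationship_rows: (id1, id2, relationship_id)
    """
    concepts = pd.DataFrame(
        [
            {
                "concept_id": cid,
                "concept_name": name,
                "domain_id": domain,
                "vocabulary_id": vocab,
                "concept_class_id": "Test",
                "standard_concept": standard,
                "concept_code": code,
                "valid_start_date": "19700101",
                "valid_end_date": "20991231",
                "invalid_reason": invalid,
            }
            for cid, name, domain, vocab, code, standard, invalid in concept_rows
        ],
        columns=CONCEPT_COLUMNS,
    )
    rels = pd.DataFrame(
        [
            {
                "concept_id_1": a,
                "concept_id_2": b,
                "relationship_id": kind,
                "valid_start_date": "19700101",
                "valid_end_date": "20991231",
                "invalid_reason": "",
            }
            for a, b, kind in relationship_rows
        ],
        columns=RELATIONSHIP_COLUMNS,
    )
    vocab_set = sorted(set(concepts["vocabulary_id"]) | set(vocab_ids))
    vocabs = pd.DataFrame(
        [
            {
                "vocabulary_id": v,
                "vocabulary_name": v,
                "vocabulary_reference": "test",
                "vocabulary_version": "1",
                "vocabulary_concept_id": 0,
            }
            for v in vocab_set
        ],
        columns=VOCABULARY_COLUMNS,
    )
    return ConceptStore(concepts, rels, vocabs)


@pytest.fixture(scope="session")
def study():
    """A small synthetic study with its full pipeline run."""
    config = SourceGenConfig(seed=42, n_patients=120, mean_prescriptions_per_person=12.0)
    source, store, truth = generate_study(42, source_config=config)
    result = run_pipeline(source, store, hints=truth.hints)
    return {
        "config": config,
        "etl_config": EtlConfig(),
        "source": source,
        "store": store,
        "truth": truth,
        "result": result,
    }


@pytest.fixture
def drug_store():
    """A miniature ATC/RxNorm-style store featuring a vocabulary revision:
    the deprecated ingredient code D11AX19 was replaced by D11AH04."""
    return make_store(
        concept_rows=[
            (10, "alitretinoin", "Drug", "RxNorm", "RX-1", "S", ""),
            (11, "tretinoin", "Drug", "RxNorm", "RX-2", "S", ""),
            (12, "insulin", "Drug", "RxNorm", "RX-3", "S", ""),
            (20, "alitretinoin", "Drug", "ATC", "D11AH04", "", ""),
            (21, "alitretinoin (deprecated)", "Drug", "ATC", "D11AX19", "", "U"),
            (22, "tretinoin", "Drug", "ATC", "D10AD01", "", ""),
        ],
        relationship_rows=[
            (20, 10, "Maps to"),
            (22, 11, "Maps to"),
            (21, 20, "Concept replaced by"),
        ],
    )
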