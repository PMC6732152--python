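"""End-to-end convenience: classify -> import -> ETL -> validate.

Thin orchestration over the module-level operations, so a full feasibility
run is one call (and so the CLI subcommands compose the same way).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .cdm_model import CdmDataset
from .etl import EtlConfig, EtlReport, run_etl
from .source_model import SourceDataset
from .validation import ValidationReport, validate
from .vocabulary import (
    ConceptStore,
    ImportReport,
    VocabularySummary,
    classify_vocabulary,
    import_local_vocabulary,
)

__all__ = ["PipelineResult", "collect_local_codes", "run_pipeline"]


def collect_local_codes(
    source: SourceDataset, config: EtlConfig = EtlConfig()
) -> list[tuple[str, str]]:
    """Distinct (code, local_vocabulary_id) pairs occurring in a source
    dataset, in deterministic sorted order."""
    pairs: set[tuple[str, str]] = set()
    pairs.update(
        (c, config.event_vocabulary_id) for c in source.diagnosis["icd10_code"] if c
    )
    pairs.update(
        (c, config.drug_vocabulary_id) for c in source.prescription["atc_code"] if c
    )
    pairs.update(
        (g, config.provider_vocabulary_id)
        for g in source.prescription["professional_group"]
        if g
    )
    pairs.update((p, "PRN") for p in source.prescription["prn"] if p)
    if source.patient["sei"].notna().any():
        pairs.add(("SEI", "SEI"))
    return sorted(pairs)


@dataclass
class PipelineResult:
    summary: VocabularySummary
    import_report: ImportReport
    store: ConceptStore  # post-import
    cdm: CdmDataset
    etl_report: EtlReport
    validation: ValidationReport


def run_pipeline(
    source: SourceDataset,
    store: ConceptStore,
    hints: Optional[Mapping[str, int]] = None,
    config: EtlConfig = EtlConfig(),
) -> PipelineResult:
    """Classify every local code, import S1/S2 codes, transform, validate."""
    codes = collect_local_codes(source, config)
    summary = classify_vocabulary(codes, store, hints=hints)
    new_store, import_report = import_local_vocabulary(
        summary.assessments.values(), store
    )
    cdm, etl_report = run_etl(source, new_store, summary.assessments, config)
    report = validate(source, cdm, etl_report, config)
    return PipelineResult(
        summary=summary,
        import_report=import_report,
        store=new_store,
        cdm=cdm,
        etl_report=etl_report,
        validation=report,
    )
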