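"""End-to-end convenience layer: simulated or external count data through
allele calling, maternal comparison, and per-cell classification."""

from __future__ import annotations

from dataclasses import dataclass, field

from .classification import CellVerdict, classify_cell
from .panel import Panel
from .simulator import CohortTruth, cohort_counts
from .snp_typing import (
    AlleleCallTable,
    ThresholdConfig,
    call_alleles,
    compare_to_maternal,
)


@dataclass
class CohortResult:
    verdicts: list[CellVerdict]
    cell_tables: dict[str, AlleleCallTable] = field(default_factory=dict)
    gdna_tables: dict[str, AlleleCallTable] = field(default_factory=dict)


def genotype_cohort(
    cohort: CohortTruth,
    panel: Panel,
    cfg: ThresholdConfig | None = None,
    readout_seed: int | None = None,
) -> CohortResult:
    """Counts-channel readout of a simulated cohort, then the full SNP
    typing and classification cascade against each case's maternal gDNA."""
    cfg = cfg or ThresholdConfig()
    cell_counts, gdna_counts = cohort_counts(cohort, panel, seed=readout_seed)
    gdna_tables = {
        case_id: call_alleles(counts, cfg, sample_id=f"{case_id}_gDNA")
        for case_id, counts in gdna_counts.items()
    }
    verdicts: list[CellVerdict] = []
    cell_tables: dict[str, AlleleCallTable] = {}
    for cell in cohort.cells:
        table = call_alleles(cell_counts[cell.cell_id], cfg, sample_id=cell.cell_id)
        cell_tables[cell.cell_id] = table
        cmp = compare_to_maternal(table, gdna_tables[cell.case_id], cfg)
        verdicts.append(classify_cell(cmp, cfg=cfg, case_id=cell.case_id))
    return CohortResult(verdicts=verdicts, cell_tables=cell_tables, gdna_tables=gdna_tables)
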