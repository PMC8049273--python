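"""Per-cell fetal/uninformative verdicts, case tabulation, and evaluation
against sex-by-sequencing truth.

A cell is scored fetal when at least two SNPs show a non-maternal allele
and those informative SNPs are at least 6% (profile-dependent: 6/8/10%)
of the comparable SNPs; a cell with fewer than 20 comparable SNPs is a
low-quality void.  Evaluation assumes sex chromosome calls from shallow
whole-genome sequencing are fully reliable and restricts to normal male
singleton pregnancies: a fetal-verdict cell that is male by sequencing is
a true positive, a non-fetal female cell a true negative, and so on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .snp_typing import SnpComparison, ThresholdConfig
from .util import pct, round_half_away, trunc_decimal

VERDICTS = ("fetal", "uninformative", "void_low_quality")
OUTCOMES = ("none_proven", "one_fetal", "two_plus_fetal")
PROFILES = (6, 8, 10)


@dataclass
class CellVerdict:
    cell_id: str
    case_id: str
    informative_snp_count: int
    comparable_snp_count: int
    haplotype_informative: bool | None = None
    verdict: str = "uninformative"
    threshold_profile: int = 6

    @property
    def informative_pct(self) -> float:
        if self.comparable_snp_count == 0:
            return 0.0
        return self.informative_snp_count / self.comparable_snp_count

    def fetal_at(self, cfg: ThresholdConfig) -> bool:
        """Re-evaluate the three-part fetal rule under another config."""
        return (
            self.comparable_snp_count >= cfg.min_comparable_snps
            and self.informative_snp_count >= cfg.min_informative_snps
            and self.informative_pct >= cfg.min_informative_pct_of_comparable
        )


@dataclass
class CaseOutcome:
    case_id: str
    n_cells_passing_wga: int
    n_fetal_cells: int

    @property
    def outcome(self) -> str:
        if self.n_fetal_cells == 0:
            return "none_proven"
        if self.n_fetal_cells == 1:
            return "one_fetal"
        return "two_plus_fetal"


@dataclass
class ContingencyTable:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def tp_rate(self) -> float:
        return self.tp / self.total

    @property
    def tn_rate(self) -> float:
        return self.tn / self.total

    @property
    def fp_rate(self) -> float:
        return self.fp / self.total

    @property
    def fn_rate(self) -> float:
        return self.fn / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp)

    def summary(self) -> dict[str, float]:
        """Printed-table view: percentages rounded half-away at 1 decimal."""
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "tp_rate_pct": round_half_away(100 * self.tp_rate),
            "tn_rate_pct": round_half_away(100 * self.tn_rate),
            "fp_rate_pct": round_half_away(100 * self.fp_rate),
            "fn_rate_pct": round_half_away(100 * self.fn_rate),
            "sensitivity_pct": round_half_away(100 * self.sensitivity),
            "precision_pct": round_half_away(100 * self.precision),
        }


def classify_cell(
    cmp: SnpComparison,
    hap_verdict: str | None = None,
    cfg: ThresholdConfig | None = None,
    case_id: str = "",
) -> CellVerdict:
    """Combine SNP evidence (and optionally a haplotype verdict) into a
    per-cell verdict.  Haplotype informativeness alone suffices for a
    fetal verdict in combined mode (it is immune to the low-depth SNP
    artifacts that motivate the quality gate)."""
    cfg = cfg or ThresholdConfig()
    hap_informative = None if hap_verdict is None else hap_verdict == "informative_fetal"
    v = CellVerdict(
        cell_id=cmp.cell_id,
        case_id=case_id,
        informative_snp_count=cmp.informative_sites,
        comparable_snp_count=cmp.comparable_sites,
        haplotype_informative=hap_informative,
        threshold_profile=round(cfg.min_informative_pct_of_comparable * 100),
    )
    if hap_informative:
        v.verdict = "fetal"
    elif cmp.void or cmp.comparable_sites < cfg.min_comparable_snps:
        v.verdict = "void_low_quality"
    elif v.fetal_at(cfg):
        v.verdict = "fetal"
    else:
        v.verdict = "uninformative"
    return v


def tabulate_outcomes(fetal_counts_per_case: Mapping[str, int]) -> dict:
    """Tabulate cases by fetal-cell count (0 / 1 / >=2) with percentages
    of total cases at 1-decimal rounding."""
    n_cases = len(fetal_counts_per_case)
    counts = Counter()
    for n_fetal in fetal_counts_per_case.values():
        if n_fetal == 0:
            counts["none_proven"] += 1
        elif n_fetal == 1:
            counts["one_fetal"] += 1
        else:
            counts["two_plus_fetal"] += 1
    return {
        "n_cases": n_cases,
        "counts": {k: counts.get(k, 0) for k in OUTCOMES},
        "percentages": {
            k: round_half_away(pct(counts.get(k, 0), n_cases)) for k in OUTCOMES
        },
    }


def tabulate_cases(
    verdicts: Iterable[CellVerdict],
    cfg: ThresholdConfig | None = None,
    profiles: Sequence[int] = PROFILES,
) -> dict[int, dict]:
    """Case-outcome table at each informative-percentage profile.

    Each cell's fetal status is re-derived from its stored informative /
    comparable counts under the profile's cutoff, so one pass over the
    cohort yields the whole profile family."""
    cfg = cfg or ThresholdConfig()
    verdicts = list(verdicts)
    out: dict[int, dict] = {}
    for profile in profiles:
        pcfg = cfg.with_profile(profile)
        fetal_per_case: dict[str, int] = {}
        for v in verdicts:
            fetal_per_case.setdefault(v.case_id, 0)
            if v.fetal_at(pcfg):
                fetal_per_case[v.case_id] += 1
        out[profile] = tabulate_outcomes(fetal_per_case)
    return out


def evaluate_vs_sex(
    verdicts: Iterable[CellVerdict],
    sex_truth: Mapping[str, str],
) -> ContingencyTable:
    """Contingency table of genotype verdict against male/female truth.

    Cells scored 'not fetal' pool the uninformative and void verdicts.
    Only cells present in sex_truth (i.e. from normal male singleton
    pregnancies under the intended use) are evaluated.
    """
    tp = tn = fp = fn = 0
    n = 0
    for v in verdicts:
        sex = sex_truth.get(v.cell_id)
        if sex is None:
            continue
        n += 1
        is_fetal = v.verdict == "fetal"
        if is_fetal and sex == "male":
            tp += 1
        elif is_fetal and sex == "female":
            fp += 1
        elif not is_fetal and sex == "female":
            tn += 1
        else:
            fn += 1
    if n == 0:
        raise ValueError("no cells with sex truth to evaluate")
    return ContingencyTable(tp=tp, tn=tn, fp=fp, fn=fn)


def count_cells_with_min_informative(
    verdicts: Iterable[CellVerdict],
    k: int,
) -> tuple[int, float]:
    """Count (and percentage of) genotyped cells with >= k informative
    SNPs.  The percentage is truncated at 1 decimal, matching the printed
    convention for this cell-level fraction."""
    verdicts = list(verdicts)
    n = sum(1 for v in verdicts if v.informative_snp_count >= k)
    total = len(verdicts)
    if total == 0:
        return 0, float("nan")
    return n, trunc_decimal(pct(n, total))
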