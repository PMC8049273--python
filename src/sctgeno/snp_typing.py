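"""Allele calling under read-count cutoffs and cell-vs-mother comparison.

A variant allele is accepted at a site when it is supported by at least
ten reads and at least 5% of the site's unmasked reads.  A putative fetal
cell is compared to the maternal gDNA control site by site: a site is
*informative* when the cell shows an allele the mother does not carry, at
an allele fraction of at least 10%.  The hemizygous "_B" pattern (the cell
shows only the non-maternal allele, the maternal allele having dropped
out) is informative under the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .util import BASES


@dataclass
class ThresholdConfig:
    """All tunable cutoffs of the SNP-typing stage.

    min_minor_reads / min_minor_fraction gate allele *calling*;
    informative_fraction gates scoring an allele as fetal-informative;
    min_informative_snps / min_informative_pct_of_comparable /
    min_comparable_snps gate the per-cell fetal verdict.
    """

    min_minor_reads: int = 10
    min_minor_fraction: float = 0.05
    informative_fraction: float = 0.10
    min_informative_snps: int = 2
    min_informative_pct_of_comparable: float = 0.06
    min_comparable_snps: int = 20
    min_coverage: int = 10

    def __post_init__(self) -> None:
        for name in ("min_minor_fraction", "informative_fraction",
                     "min_informative_pct_of_comparable"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_minor_reads", "min_informative_snps",
                     "min_comparable_snps", "min_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_profile(self, profile_pct: int) -> "ThresholdConfig":
        """The 6/8/10% informative-percentage profiles of the verdict rule."""
        if profile_pct not in (6, 8, 10):
            raise ValueError("profile must be 6, 8 or 10")
        return replace(self, min_informative_pct_of_comparable=profile_pct / 100.0)


@dataclass
class SiteCall:
    site_id: str
    counts: dict[str, int]
    depth: int  # unmasked depth (A+C+G+T)
    called: frozenset[str]
    scorable: bool
    multi_allelic: bool = False

    def fraction(self, base: str) -> float:
        if self.depth == 0:
            return 0.0
        return self.counts.get(base, 0) / self.depth


@dataclass
class AlleleCallTable:
    sample_id: str
    calls: dict[str, SiteCall] = field(default_factory=dict)

    def __getitem__(self, site_id: str) -> SiteCall:
        return self.calls[site_id]


@dataclass
class SnpComparison:
    cell_id: str
    maternal_id: str
    comparable_sites: int
    informative_sites: int
    informative_site_ids: list[str] = field(default_factory=list)
    discordant_detail: dict[str, dict] = field(default_factory=dict)
    void: bool = False


def call_alleles(
    counts: dict[str, dict[str, int]],
    cfg: ThresholdConfig | None = None,
    sample_id: str = "sample",
) -> AlleleCallTable:
    """Call 0-2 alleles per site from pileup base counts.

    The majority base of any site with adequate depth is always called;
    a minor base is added only when it clears both the absolute-read and
    fraction cutoffs.  Sites where three or more bases clear the cutoffs
    are flagged multi-allelic and excluded from downstream comparison.
    """
    cfg = cfg or ThresholdConfig()
    table = AlleleCallTable(sample_id=sample_id)
    for site_id, c in counts.items():
        base_counts = {b: int(c.get(b, 0)) for b in BASES}
        depth = sum(base_counts.values())
        scorable = depth >= cfg.min_coverage
        called: set[str] = set()
        multi = False
        if scorable:
            majority = max(BASES, key=lambda b: (base_counts[b], b))
            called.add(majority)
            passing_minors = [
                b
                for b in BASES
                if b != majority
                and base_counts[b] >= cfg.min_minor_reads
                and base_counts[b] / depth >= cfg.min_minor_fraction
            ]
            if len(passing_minors) >= 2:
                multi = True
                called = set()
            elif passing_minors:
                called.add(passing_minors[0])
        table.calls[site_id] = SiteCall(
            site_id=site_id,
            counts=base_counts,
            depth=depth,
            called=frozenset(called),
            scorable=scorable and not multi,
            multi_allelic=multi,
        )
    return table


def compare_to_maternal(
    cell: AlleleCallTable,
    mother: AlleleCallTable,
    cfg: ThresholdConfig | None = None,
) -> SnpComparison:
    """Count sites where the cell carries an allele absent from the mother.

    Only sites scorable in both samples are comparable; multi-allelic
    sites are excluded.  An informative site requires the non-maternal
    allele at fraction >= cfg.informative_fraction in the cell.
    """
    cfg = cfg or ThresholdConfig()
    comparable = 0
    informative: list[str] = []
    detail: dict[str, dict] = {}
    for site_id, cell_call in cell.calls.items():
        mother_call = mother.calls.get(site_id)
        if mother_call is None:
            continue
        if not (cell_call.scorable and mother_call.scorable):
            continue
        comparable += 1
        novel = [
            b
            for b in sorted(cell_call.called - mother_call.called)
            if cell_call.fraction(b) >= cfg.informative_fraction
        ]
        if novel:
            informative.append(site_id)
            detail[site_id] = {
                "cell_alleles": sorted(cell_call.called),
                "maternal_alleles": sorted(mother_call.called),
                "novel_alleles": novel,
                "novel_fractions": {b: cell_call.fraction(b) for b in novel},
            }
    return SnpComparison(
        cell_id=cell.sample_id,
        maternal_id=mother.sample_id,
        comparable_sites=comparable,
        informative_sites=len(informative),
        informative_site_ids=informative,
        discordant_detail=detail,
        void=comparable == 0,
    )


def count_scorable_snps(
    sample: AlleleCallTable,
    maf_cutoff: float = 0.05,
    depth_cutoff: int = 10,
) -> int:
    """Sites whose minor allele has >= depth_cutoff reads and >= maf_cutoff
    of the site's unmasked reads — the coverage-QC metric for comparing
    gDNA against single-cell WGA products."""
    n = 0
    for call in sample.calls.values():
        if call.depth == 0:
            continue
        ranked = sorted(call.counts.values(), reverse=True)
        minor = ranked[1] if len(ranked) > 1 else 0
        if minor >= depth_cutoff and minor / call.depth >= maf_cutoff:
            n += 1
    return n
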