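"""Synthetic cohorts: parental genotypes, Mendelian fetuses, and per-cell
amplicon readouts with whole-genome-amplification artifacts.

The generative model mirrors the assay's error structure stage by stage.
A family draws parental alleles at panel SNPs (haplotype regions as whole
haplotypes from a small pool, so multi-site diversity exists) and the
fetus inherits one haplotype per parent; Y-marker amplicons exist only in
male genomes.  Each picked cell is fetal or — at ~10% probability, the
empirical contamination rate of the capture workflow — maternal.  The WGA
product of a cell is drawn once: whole-amplicon (locus) dropout, loss of
one allele at heterozygous amplicons (allele dropout), rare pre-WGA
copy errors that then ride on essentially all reads of that allele, and
WGA-stage errors that affect a medium fraction (0.05-0.20) of one copy's
reads.  Sequencing readout — either per-site base counts or literal 2x76
read pairs — is then sampled from that product with negative-binomial
depth per amplicon and low per-read PCR error, so the same cell can be
read out repeatedly and the two readout channels agree in distribution.

The bulk maternal gDNA control is read out from the unamplified maternal
genome: no dropout and no WGA errors, higher depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .panel import Panel, SNPSite, default_panel
from .util import BASES, revcomp


@dataclass
class SimConfig:
    """Cohort-generator settings; defaults are the study conditions.

    152 pregnancies, 3-10 cells per case, ~10% chance a picked cell is
    maternal, very informative SNPs (population MAF 0.3-0.5), and allele
    dropout at the 15% rate measured for unfixed single lymphoblasts
    (8% for fixed ones).
    """

    seed: int
    n_cases: int = 152
    cells_per_case: tuple[int, int] = (3, 10)
    maternal_cell_prob: float = 0.10
    maf_range: tuple[float, float] = (0.30, 0.50)
    locus_dropout_prob: float = 0.10
    allele_dropout_prob: float = 0.15
    depth_mean: float = 100.0
    depth_dispersion: float = 3.0
    gdna_depth_factor: float = 4.0
    pre_wga_rate: float = 1e-4
    wga_stage_rate: float = 0.005
    wga_fraction_band: tuple[float, float] = (0.05, 0.20)
    pcr_rate: float = 0.002
    read_length: int = 76
    male_prob: float = 0.5
    haplotype_pool_size: int = 6
    doublet_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("maternal_cell_prob", "locus_dropout_prob", "allele_dropout_prob",
                     "pre_wga_rate", "wga_stage_rate", "pcr_rate", "male_prob",
                     "doublet_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.cells_per_case
        if not 1 <= lo <= hi:
            raise ValueError("cells_per_case must be an increasing range from >= 1")


@dataclass
class AmpliconProduct:
    """The surviving WGA product of one amplicon in one cell."""

    amplicon_id: str
    copies: list[str]
    # (copy index, offset, substituted base, fraction of that copy's reads)
    wga_events: list[tuple[int, int, str, float]] = field(default_factory=list)


@dataclass
class CellTruth:
    cell_id: str
    case_id: str
    origin: str  # fetal / maternal / doublet
    products: dict[str, AmpliconProduct] = field(default_factory=dict)
    dropped_amplicons: list[str] = field(default_factory=list)
    dropped_alleles: dict[str, int] = field(default_factory=dict)  # amplicon -> lost copy idx
    error_events: list[dict] = field(default_factory=list)


@dataclass
class FamilyTruth:
    case_id: str
    fetal_sex: str  # male / female
    # sample -> amplicon -> allele sequences (full amplicon length)
    alleles: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def genotype(self, sample: str, site: SNPSite) -> tuple[str, ...]:
        copies = self.alleles[sample].get(site.amplicon_id, [])
        return tuple(sorted(c[site.offset] for c in copies))


@dataclass
class CohortTruth:
    cfg: SimConfig
    families: list[FamilyTruth]
    cells: list[CellTruth]
    amplicon_bias: dict[str, float]

    def family(self, case_id: str) -> FamilyTruth:
        return next(f for f in self.families if f.case_id == case_id)

    def sex_truth(self, male_cases_only: bool = True) -> dict[str, str]:
        """Per-cell male/female label as shallow sequencing would report it:
        a fetal cell carries the fetal sex, a maternal cell is female."""
        fam = {f.case_id: f for f in self.families}
        out = {}
        for c in self.cells:
            f = fam[c.case_id]
            if male_cases_only and f.fetal_sex != "male":
                continue
            out[c.cell_id] = f.fetal_sex if c.origin == "fetal" else "female"
        return out


def _other_base(rng: np.random.Generator, base: str) -> str:
    options = [b for b in BASES if b != base]
    return options[rng.integers(len(options))]


def simulate_family(cfg: SimConfig, panel: Panel, rng: np.random.Generator,
                    case_id: str = "case") -> FamilyTruth:
    """Draw one family: parental allele sequences per amplicon and a
    Mendelian fetus.  Haplotype-region parents draw whole haplotypes from
    a per-region pool; identity sites draw alleles independently at a MAF
    sampled from the configured range."""
    sex = "male" if rng.random() < cfg.male_prob else "female"
    fam = FamilyTruth(case_id=case_id, fetal_sex=sex,
                      alleles={"mother": {}, "father": {}, "fetus": {}})
    for amp in sorted(panel.amplicons.values(), key=lambda a: a.amplicon_id):
        if amp.ref_seq is None:
            continue
        sites = panel.sites_for(amp.amplicon_id)
        if amp.category == "y_marker":
            y_hap = amp.ref_seq
            fam.alleles["mother"][amp.amplicon_id] = []
            fam.alleles["father"][amp.amplicon_id] = [y_hap]
            fam.alleles["fetus"][amp.amplicon_id] = [y_hap] if sex == "male" else []
            continue
        if amp.category == "haplotype_region" and len(sites) >= 2:
            pool = _haplotype_pool(amp.ref_seq, sites, cfg.haplotype_pool_size, rng)
            mother = [pool[rng.integers(len(pool))] for _ in range(2)]
            father = [pool[rng.integers(len(pool))] for _ in range(2)]
        else:
            mother, father = [], []
            for parent_copies in (mother, father):
                for _ in range(2):
                    seq = list(amp.ref_seq)
                    for site in sites:
                        maf = rng.uniform(*cfg.maf_range)
                        if rng.random() < maf:
                            seq[site.offset] = site.alt_allele or _other_base(rng, seq[site.offset])
                    parent_copies.append("".join(seq))
        fetus = [mother[rng.integers(2)], father[rng.integers(2)]]
        fam.alleles["mother"][amp.amplicon_id] = mother
        fam.alleles["father"][amp.amplicon_id] = father
        fam.alleles["fetus"][amp.amplicon_id] = fetus
    return fam


def _haplotype_pool(ref_seq: str, sites: list[SNPSite], k: int,
                    rng: np.random.Generator) -> list[str]:
    pool = []
    for _ in range(k):
        seq = list(ref_seq)
        for site in sites:
            if rng.random() < 0.5:
                seq[site.offset] = site.alt_allele or _other_base(rng, seq[site.offset])
        pool.append("".join(seq))
    return pool


def simulate_cell(fam: FamilyTruth, cfg: SimConfig, rng: np.random.Generator,
                  cell_id: str, panel: Panel) -> CellTruth:
    """Draw one picked cell's origin and its post-WGA amplicon products."""
    r = rng.random()
    if cfg.doublet_prob and r < cfg.doublet_prob:
        origin = "doublet"
    elif r < cfg.doublet_prob + cfg.maternal_cell_prob:
        origin = "maternal"
    else:
        origin = "fetal"
    cell = CellTruth(cell_id=cell_id, case_id=fam.case_id, origin=origin)
    genome = {"fetal": "fetus", "maternal": "mother"}.get(origin)
    for amp_id in sorted(fam.alleles["mother"]):
        if origin == "doublet":
            copies = list(fam.alleles["fetus"][amp_id]) + list(fam.alleles["mother"][amp_id])
        else:
            copies = list(fam.alleles[genome][amp_id])
        if not copies:
            continue
        if rng.random() < cfg.locus_dropout_prob:
            cell.dropped_amplicons.append(amp_id)
            continue
        if len(copies) == 2 and copies[0] != copies[1] and rng.random() < cfg.allele_dropout_prob:
            lost = int(rng.integers(2))
            cell.dropped_alleles[amp_id] = lost
            copies = [copies[1 - lost]]
        product = AmpliconProduct(amplicon_id=amp_id, copies=copies)
        sites = panel.sites_for(amp_id)
        for idx in range(len(copies)):
            for site in sites:
                if rng.random() < cfg.pre_wga_rate:
                    seq = list(product.copies[idx])
                    new = _other_base(rng, seq[site.offset])
                    seq[site.offset] = new
                    product.copies[idx] = "".join(seq)
                    cell.error_events.append(
                        {"stage": "pre_wga", "amplicon": amp_id,
                         "site": site.site_id, "base": new}
                    )
                if rng.random() < cfg.wga_stage_rate:
                    new = _other_base(rng, product.copies[idx][site.offset])
                    frac = float(rng.uniform(*cfg.wga_fraction_band))
                    product.wga_events.append((idx, site.offset, new, frac))
                    cell.error_events.append(
                        {"stage": "wga_stage", "amplicon": amp_id,
                         "site": site.site_id, "base": new, "fraction": frac}
                    )
        cell.products[amp_id] = product
    return cell


def gdna_products(fam: FamilyTruth, sample: str = "mother") -> dict[str, AmpliconProduct]:
    """Bulk gDNA: every amplicon present, both alleles, no WGA artifacts."""
    return {
        amp_id: AmpliconProduct(amplicon_id=amp_id, copies=list(copies))
        for amp_id, copies in fam.alleles[sample].items()
        if copies
    }


# ---------------------------------------------------------------------------
# readout channels

def _template_plan(product: AmpliconProduct, depth: int,
                   rng: np.random.Generator) -> list[tuple[str, int]]:
    """Split an amplicon's read budget across template sequences: reads per
    surviving copy, then WGA-stage events peel a sub-fraction of one
    copy's reads onto a mutated template."""
    if depth <= 0 or not product.copies:
        return []
    n_copies = len(product.copies)
    per_copy = rng.multinomial(depth, [1.0 / n_copies] * n_copies)
    plan: list[tuple[str, int]] = []
    for idx, (seq, n) in enumerate(zip(product.copies, per_copy)):
        if n == 0:
            continue
        variants: list[tuple[str, int]] = [(seq, int(n))]
        for copy_idx, offset, base, frac in product.wga_events:
            if copy_idx != idx:
                continue
            main_seq, main_n = variants[0]
            k = int(rng.binomial(main_n, frac))
            if k == 0:
                continue
            mutated = main_seq[:offset] + base + main_seq[offset + 1 :]
            variants[0] = (main_seq, main_n - k)
            variants.append((mutated, k))
        plan.extend((s, n) for s, n in variants if n > 0)
    return plan


def _draw_depth(cfg: SimConfig, bias: float, rng: np.random.Generator,
                factor: float = 1.0) -> int:
    mean = cfg.depth_mean * bias * factor
    r = cfg.depth_dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def readout_counts(
    products: dict[str, AmpliconProduct],
    panel: Panel,
    cfg: SimConfig,
    rng: np.random.Generator,
    amplicon_bias: dict[str, float],
    depth_factor: float = 1.0,
) -> dict[str, dict[str, int]]:
    """Per-site base counts: the fast readout channel (equivalent in
    distribution to pileup over simulated reads)."""
    counts: dict[str, dict[str, int]] = {
        s.site_id: {b: 0 for b in BASES} for s in panel.sites
    }
    for amp_id, product in products.items():
        sites = panel.sites_for(amp_id)
        if not sites:
            continue
        depth = _draw_depth(cfg, amplicon_bias.get(amp_id, 1.0), rng, depth_factor)
        plan = _template_plan(product, depth, rng)
        for seq, n in plan:
            for site in sites:
                base = seq[site.offset]
                n_err = int(rng.binomial(n, cfg.pcr_rate))
                counts[site.site_id][base] += n - n_err
                for _ in range(n_err):
                    counts[site.site_id][_other_base(rng, base)] += 1
    return counts


def readout_reads(
    products: dict[str, AmpliconProduct],
    panel: Panel,
    cfg: SimConfig,
    rng: np.random.Generator,
    amplicon_bias: dict[str, float],
    sample_id: str = "sample",
    depth_factor: float = 1.0,
) -> list[tuple[str, str, list[int], str, list[int]]]:
    """2x76 paired reads: read1 is the amplicon 5' end, read2 the reverse
    complement of the 3' end, in sequencing orientation."""
    out = []
    L = cfg.read_length
    qual = [37] * L
    serial = 0
    for amp_id in sorted(products):
        product = products[amp_id]
        depth = _draw_depth(cfg, amplicon_bias.get(amp_id, 1.0), rng, depth_factor)
        plan = _template_plan(product, depth, rng)
        for seq, n in plan:
            for _ in range(n):
                read_seq = list(seq)
                n_err = int(rng.binomial(len(read_seq), cfg.pcr_rate))
                for _ in range(n_err):
                    pos = int(rng.integers(len(read_seq)))
                    read_seq[pos] = _other_base(rng, read_seq[pos])
                s = "".join(read_seq)
                r1 = s[:L]
                r2 = revcomp(s[-L:])
                serial += 1
                out.append(
                    (f"{sample_id}:{amp_id}:{serial}", r1, qual[: len(r1)], r2, qual[: len(r2)])
                )
    return out


# ---------------------------------------------------------------------------
# cohort driver

def simulate_cohort(
    cfg: SimConfig,
    panel: Panel | None = None,
    outdir: str | Path | None = None,
) -> CohortTruth:
    """Simulate cfg.n_cases families with their picked cells.

    Returns the truth object; when outdir is given, additionally writes
    per-sample paired FASTQs, truth TSVs, and a manifest JSON.
    """
    if panel is None:
        panel = default_panel(reference_seed=cfg.seed)
    if any(a.ref_seq is None for a in panel.amplicons.values()):
        raise ValueError("panel must carry reference sequences for simulation")
    rng = np.random.default_rng(cfg.seed)
    bias = {
        amp_id: float(np.exp(rng.normal(0.0, 0.3)))
        for amp_id in sorted(panel.amplicons)
    }
    families: list[FamilyTruth] = []
    cells: list[CellTruth] = []
    for i in range(cfg.n_cases):
        case_id = f"case{i + 1:04d}"
        fam = simulate_family(cfg, panel, rng, case_id=case_id)
        families.append(fam)
        n_cells = int(rng.integers(cfg.cells_per_case[0], cfg.cells_per_case[1] + 1))
        for j in range(n_cells):
            cells.append(
                simulate_cell(fam, cfg, rng, cell_id=f"{case_id}_c{j + 1:02d}", panel=panel)
            )
    cohort = CohortTruth(cfg=cfg, families=families, cells=cells, amplicon_bias=bias)
    if outdir is not None:
        _write_cohort(cohort, panel, Path(outdir))
    return cohort


def cohort_counts(
    cohort: CohortTruth, panel: Panel, seed: int | None = None
) -> tuple[dict[str, dict], dict[str, dict]]:
    """Counts-channel readout of a whole cohort.

    Returns (per-cell counts, per-case maternal gDNA counts); a separate
    seed stream keeps readout independent of cohort construction.
    """
    rng = np.random.default_rng(cohort.cfg.seed + 1 if seed is None else seed)
    gdna = {
        fam.case_id: readout_counts(
            gdna_products(fam), panel, cohort.cfg, rng, cohort.amplicon_bias,
            depth_factor=cohort.cfg.gdna_depth_factor,
        )
        for fam in cohort.families
    }
    cell_counts = {
        cell.cell_id: readout_counts(
            cell.products, panel, cohort.cfg, rng, cohort.amplicon_bias
        )
        for cell in cohort.cells
    }
    return cell_counts, gdna


def _write_fastq_pair(reads, prefix: Path) -> None:
    with open(f"{prefix}_R1.fastq", "w") as f1, open(f"{prefix}_R2.fastq", "w") as f2:
        for rid, s1, q1, s2, q2 in reads:
            f1.write(f"@{rid}\n{s1}\n+\n{''.join(chr(q + 33) for q in q1)}\n")
            f2.write(f"@{rid}\n{s2}\n+\n{''.join(chr(q + 33) for q in q2)}\n")


def write_truth(cohort: CohortTruth, panel: Panel, outdir: Path) -> None:
    """Truth TSVs only (cell origins / dropout events, per-sample genotypes)."""
    outdir.mkdir(parents=True, exist_ok=True)
    fam_by_case = {f.case_id: f for f in cohort.families}
    with open(outdir / "truth_cells.tsv", "w") as fh:
        fh.write("cell_id\tcase_id\torigin\tfetal_sex\tdropped_amplicons\tdropped_alleles\n")
        for cell in cohort.cells:
            fam = fam_by_case[cell.case_id]
            fh.write(
                f"{cell.cell_id}\t{cell.case_id}\t{cell.origin}\t{fam.fetal_sex}\t"
                f"{','.join(cell.dropped_amplicons)}\t"
                f"{','.join(f'{k}:{v}' for k, v in sorted(cell.dropped_alleles.items()))}\n"
            )
    with open(outdir / "truth_genotypes.tsv", "w") as fh:
        fh.write("case_id\tsample\tsite_id\tgenotype\n")
        for fam in cohort.families:
            for sample in ("mother", "father", "fetus"):
                for site in panel.sites:
                    gt = "/".join(fam.genotype(sample, site)) or "."
                    fh.write(f"{fam.case_id}\t{sample}\t{site.site_id}\t{gt}\n")


def _write_cohort(cohort: CohortTruth, panel: Panel, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cohort.cfg.seed + 2)
    manifest = {"config": asdict(cohort.cfg), "samples": []}
    for fam in cohort.families:
        prefix = outdir / f"{fam.case_id}_gDNA"
        reads = readout_reads(
            gdna_products(fam), panel, cohort.cfg, rng, cohort.amplicon_bias,
            sample_id=f"{fam.case_id}_gDNA",
            depth_factor=cohort.cfg.gdna_depth_factor,
        )
        _write_fastq_pair(reads, prefix)
        manifest["samples"].append(
            {"sample": f"{fam.case_id}_gDNA", "case": fam.case_id, "kind": "maternal_gdna"}
        )
    for cell in cohort.cells:
        reads = readout_reads(
            cell.products, panel, cohort.cfg, rng, cohort.amplicon_bias,
            sample_id=cell.cell_id,
        )
        _write_fastq_pair(reads, outdir / cell.cell_id)
        manifest["samples"].append(
            {"sample": cell.cell_id, "case": cell.case_id, "kind": "cell"}
        )
    write_truth(cohort, panel, outdir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def simulate_het_variant_counts(
    n_obs: int,
    allele_dropout_prob: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """(ref, alt) read counts for known-heterozygous single cells at one
    variant — the control-cell experiment behind the dropout-rate
    estimate.  Dropout collapses the readout to one allele."""
    rng = rng or np.random.default_rng(cfg.seed)
    out = []
    for _ in range(n_obs):
        depth = _draw_depth(cfg, 1.0, rng)
        if rng.random() < allele_dropout_prob:
            keep_ref = rng.random() < 0.5
            out.append((depth, 0) if keep_ref else (0, depth))
        else:
            alt = int(rng.binomial(depth, 0.5))
            out.append((depth - alt, alt))
    return out
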