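"""Genotyping known disease-causing variants in single-cell WGA products.

Whole-genome amplification of a single cell skews allele balance badly and
drops alleles outright, so the heterozygote alternative-allele-fraction
(AAF) band is deliberately wide (0.10-0.90 by default: real fetal cells
have been called het at AAF 0.80 and 0.87), and a genotype from any one
cell is never trusted alone — the fetal genotype is a consensus across
cells, with single-allele cells reconciled as possible dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from statsmodels.stats.proportion import proportion_confint

from .read_processing import AlignedRead

GENOTYPES = ("hom_ref", "het", "hom_alt")
DROPOUT_FLAGS = ("none", "ref_dropout_suspected", "alt_dropout_suspected", "low_coverage")


@dataclass
class TargetVariant:
    variant_id: str
    amplicon_id: str
    offset: int  # 0-based on the amplicon
    ref_allele: str
    alt_allele: str  # substituted base(s), or "" for a pure deletion
    gene: str = ""
    del_len: int = 0  # > 0 for a deletion variant
    expected_parental: dict[str, str] | None = None  # {"mother": "het", ...}

    def __post_init__(self) -> None:
        if self.del_len == 0 and self.alt_allele == self.ref_allele:
            raise ValueError("alt equals ref")
        if self.del_len < 0:
            raise ValueError("deletion length must be >= 1 for a deletion")

    @property
    def is_deletion(self) -> bool:
        return self.del_len > 0


@dataclass
class VariantCall:
    cell_id: str
    variant_id: str
    ref_count: int
    alt_count: int
    genotype: str | None
    dropout_flag: str = "none"

    @property
    def aaf(self) -> float:
        total = self.ref_count + self.alt_count
        return self.alt_count / total if total else 0.0


@dataclass
class FetalConsensus:
    variant_id: str
    calls: list[VariantCall]
    consensus: str | None
    note: str = ""


def call_variant(
    ref_count: int,
    alt_count: int,
    floor: int = 10,
    het_band: tuple[float, float] = (0.10, 0.90),
    cell_id: str = "cell",
    variant_id: str = "variant",
    expected: str | None = None,
) -> VariantCall:
    """Genotype one cell at one variant from ref/alt read counts.

    AAF below the band is hom_ref, inside het, above hom_alt.  When the
    expected genotype (e.g. from parental carrier status) is het, a
    homozygous call is flagged as suspected dropout of the missing allele.
    """
    total = ref_count + alt_count
    if total < floor:
        return VariantCall(cell_id, variant_id, ref_count, alt_count,
                           genotype=None, dropout_flag="low_coverage")
    aaf = alt_count / total
    lo, hi = het_band
    if aaf < lo:
        genotype = "hom_ref"
    elif aaf <= hi:
        genotype = "het"
    else:
        genotype = "hom_alt"
    flag = "none"
    if expected == "het":
        if genotype == "hom_alt":
            flag = "ref_dropout_suspected"
        elif genotype == "hom_ref":
            flag = "alt_dropout_suspected"
    return VariantCall(cell_id, variant_id, ref_count, alt_count,
                       genotype=genotype, dropout_flag=flag)


def consensus_genotype(
    calls: Iterable[VariantCall],
    parental: dict[str, str] | None = None,
) -> FetalConsensus:
    """Multi-cell fetal consensus with allele-dropout reconciliation.

    A cell showing only one allele is compatible with a heterozygous
    fetus, so: any cell with both alleles observed -> het; single-allele
    cells in both directions -> het (each direction proves one allele);
    all passing cells single-allele in the same direction -> that
    homozygote, with an explicit caveat that dropout in every cell cannot
    be excluded.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no calls supplied")
    variant_id = calls[0].variant_id
    passing = [c for c in calls if c.genotype is not None]
    if not passing:
        return FetalConsensus(variant_id, calls, consensus=None,
                              note="no cell passed the coverage cutoff")
    has_het = any(c.genotype == "het" for c in passing)
    has_ref = any(c.genotype in ("het", "hom_ref") for c in passing)
    has_alt = any(c.genotype in ("het", "hom_alt") for c in passing)
    if has_het:
        return FetalConsensus(variant_id, calls, consensus="het",
                              note="both alleles directly observed in at least one cell")
    if has_ref and has_alt:
        return FetalConsensus(
            variant_id, calls, consensus="het",
            note="no single cell showed both alleles, but opposite single-allele "
                 "cells imply heterozygosity via dropout",
        )
    consensus = "hom_ref" if has_ref else "hom_alt"
    missing = "variant" if consensus == "hom_ref" else "normal"
    note = (
        f"all {len(passing)} passing cells showed a single allele; a small "
        f"probability remains that the fetus carries the {missing} allele "
        f"with dropout in every cell"
    )
    return FetalConsensus(variant_id, calls, consensus=consensus, note=note)


def estimate_dropout_rate(
    single_allele_flags: Sequence[bool],
) -> tuple[float, tuple[float, float]]:
    """Allele-dropout rate among known-heterozygous (cell, variant)
    observations: the fraction showing a single allele, with a Wilson 95%
    confidence interval."""
    n = len(single_allele_flags)
    if n == 0:
        raise ValueError("no observations")
    k = sum(bool(x) for x in single_allele_flags)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return k / n, (float(lo), float(hi))


def targets_from_table(df, panel) -> list[TargetVariant]:
    """Build TargetVariants from a targets table (variant_id, amplicon_id,
    offset, var_type, del_len, gene), resolving ref/alt against the
    panel's attached reference."""
    out = []
    for row in df.itertuples(index=False):
        amp = panel.amplicons[row.amplicon_id]
        if amp.ref_seq is None:
            raise ValueError(f"{row.amplicon_id}: panel has no reference sequence")
        is_del = row.var_type == "del"
        del_len = int(row.del_len) if is_del else 0
        ref = amp.ref_seq[row.offset : row.offset + max(1, del_len)]
        alt = "" if is_del else {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        out.append(
            TargetVariant(
                variant_id=row.variant_id, amplicon_id=row.amplicon_id,
                offset=int(row.offset), ref_allele=ref, alt_allele=alt,
                gene=row.gene, del_len=del_len,
            )
        )
    return out


def count_variant_reads(
    aligned_reads: Iterable[AlignedRead],
    variant: TargetVariant,
) -> tuple[int, int]:
    """Classify reads spanning the variant as ref- or alt-bearing.

    Substitutions compare the read base at the variant offset; deletion
    variants classify by whether the read's CIGAR deletes the variant
    span (deletions here are the allele of interest, exempt from the
    SNP-site indel mask).  Reads not covering the span are ignored.
    """
    from .read_processing import read_base_at

    ref_n = alt_n = 0
    span = range(variant.offset, variant.offset + max(1, variant.del_len))
    for aln in aligned_reads:
        if not aln.mapping_ok or aln.amplicon_id != variant.amplicon_id:
            continue
        states = [read_base_at(aln, off)[2] for off in span]
        if any(s == "uncovered" for s in states):
            continue
        if variant.is_deletion:
            if all(s == "del" for s in states):
                alt_n += 1
            elif all(s == "base" for s in states):
                ref_n += 1
        else:
            base, _q, kind = read_base_at(aln, variant.offset)
            if kind != "base":
                continue
            if base == variant.alt_allele:
                alt_n += 1
            elif base == variant.ref_allele:
                ref_n += 1
    return ref_n, alt_n
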