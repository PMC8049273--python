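"""Amplicon panel: loading, validation, and reference handling.

The assay genotypes ~90 highly polymorphic SNPs inside ~40 short PCR
amplicons, plus a handful of disease-gene amplicons.  Panel coordinates are
1-based inclusive on both ends, so ``stop - start + 1 == size``; internally
all per-amplicon site positions are 0-based offsets.  Rows whose printed
size disagrees with the coordinate span (the published HLA-A row is the
known offender) are retained but flagged rather than silently repaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .util import BASES

log = logging.getLogger(__name__)

CATEGORIES = ("identity_snp", "haplotype_region", "disease_variant", "y_marker")

#: gene symbols that mark a disease-variant amplicon in the annotation column
_DISEASE_GENES = {"HBB", "CFTR", "HEXA", "DHCR7", "RASPN", "RAPSN"}

# deterministic transversion partner used when an alt allele is unspecified
_ALT_OF = {"A": "C", "C": "A", "G": "T", "T": "G"}


class PanelFormatError(ValueError):
    """The panel table is structurally unreadable (missing columns etc.)."""


class PanelValidationError(ValueError):
    """The panel table violates a hard uniqueness constraint."""


@dataclass
class AmpliconDef:
    amplicon_id: str
    chrom: str
    start: int  # 1-based inclusive
    stop: int  # 1-based inclusive
    size_bp: int
    category: str
    annotation: str = ""
    ref_seq: str | None = None
    flagged: bool = False
    flag_reason: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        span_ok = self.start <= self.stop and self.stop - self.start + 1 == self.size_bp
        if not span_ok and not self.flagged:
            self.flagged = True
            self.flag_reason = (
                f"coordinate span {self.chrom}:{self.start}-{self.stop} "
                f"inconsistent with size {self.size_bp}"
            )
        if self.ref_seq is not None and len(self.ref_seq) != self.size_bp:
            raise ValueError(
                f"{self.amplicon_id}: ref_seq length {len(self.ref_seq)} != size {self.size_bp}"
            )


@dataclass
class SNPSite:
    site_id: str
    amplicon_id: str
    offset: int  # 0-based within the amplicon
    ref_allele: str | None = None
    alt_allele: str | None = None


@dataclass
class Panel:
    amplicons: dict[str, AmpliconDef]
    sites: list[SNPSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_amp: dict[str, list[SNPSite]] = {}
        seen: set[str] = set()
        for s in self.sites:
            if s.site_id in seen:
                raise PanelValidationError(f"duplicate site_id {s.site_id}")
            seen.add(s.site_id)
            amp = self.amplicons.get(s.amplicon_id)
            if amp is None:
                raise PanelValidationError(f"site {s.site_id} on unknown amplicon {s.amplicon_id}")
            if not 0 <= s.offset < amp.size_bp:
                raise PanelValidationError(
                    f"site {s.site_id} offset {s.offset} outside amplicon of size {amp.size_bp}"
                )
            by_amp.setdefault(s.amplicon_id, []).append(s)
        for sites in by_amp.values():
            sites.sort(key=lambda s: s.offset)
        self._sites_by_amplicon = by_amp

    def sites_for(self, amplicon_id: str) -> list[SNPSite]:
        return self._sites_by_amplicon.get(amplicon_id, [])

    @property
    def haplotype_regions(self) -> list[AmpliconDef]:
        return [
            a
            for a in self.amplicons.values()
            if a.category == "haplotype_region" and len(self.sites_for(a.amplicon_id)) >= 2
        ]

    @property
    def site_index(self) -> dict[str, SNPSite]:
        return {s.site_id: s for s in self.sites}

    def attach_reference(self, seqs: Mapping[str, str]) -> None:
        """Attach per-amplicon reference sequences and resolve '.' alleles."""
        for amp in self.amplicons.values():
            seq = seqs.get(amp.amplicon_id)
            if seq is None:
                continue
            if len(seq) != amp.size_bp:
                raise PanelValidationError(
                    f"{amp.amplicon_id}: reference length {len(seq)} != size {amp.size_bp}"
                )
            amp.ref_seq = seq.upper()
        for s in self.sites:
            ref_seq = self.amplicons[s.amplicon_id].ref_seq
            if ref_seq is None:
                continue
            if s.ref_allele is None:
                s.ref_allele = ref_seq[s.offset]
            if s.alt_allele is None:
                s.alt_allele = _ALT_OF[s.ref_allele]


def infer_category(chrom: str, annotation: str) -> str:
    if chrom.lower() == "chry":
        return "y_marker"
    if annotation.strip().lower() == "haplotype":
        return "haplotype_region"
    if annotation.strip().strip("*") in _DISEASE_GENES:
        return "disease_variant"
    return "identity_snp"


def load_panel(
    panel_table: str | Path,
    reference: str | Path | None = None,
    sites_table: str | Path | None = None,
) -> Panel:
    """Load a panel TSV (columns amplicon_id, chrom, start, stop, size,
    annotation) plus an optional reference FASTA and SNP-site TSV.

    The FASTA may hold one record per amplicon_id, or whole chromosomes
    from which unflagged amplicons are extracted by coordinate.
    """
    df = pd.read_csv(panel_table, sep="\t", dtype=str, keep_default_na=False)
    required = {"amplicon_id", "chrom", "start", "stop", "size"}
    missing = required - set(df.columns)
    if missing:
        raise PanelFormatError(f"panel table missing columns: {sorted(missing)}")
    if df["amplicon_id"].duplicated().any():
        dups = df.loc[df["amplicon_id"].duplicated(), "amplicon_id"].tolist()
        raise PanelValidationError(f"duplicate amplicon_id: {dups}")

    amplicons: dict[str, AmpliconDef] = {}
    for row in df.itertuples(index=False):
        annotation = getattr(row, "annotation", "") or ""
        amp = AmpliconDef(
            amplicon_id=row.amplicon_id,
            chrom=row.chrom,
            start=int(row.start),
            stop=int(row.stop),
            size_bp=int(row.size),
            category=infer_category(row.chrom, annotation),
            annotation=annotation,
        )
        if amp.flagged:
            log.warning("panel row %s flagged: %s", amp.amplicon_id, amp.flag_reason)
        amplicons[amp.amplicon_id] = amp

    sites: list[SNPSite] = []
    if sites_table is not None:
        sdf = pd.read_csv(sites_table, sep="\t", dtype=str, keep_default_na=False)
        for row in sdf.itertuples(index=False):
            sites.append(
                SNPSite(
                    site_id=row.site_id,
                    amplicon_id=row.amplicon_id,
                    offset=int(row.offset),
                    ref_allele=None if row.ref_allele == "." else row.ref_allele,
                    alt_allele=None if row.alt_allele == "." else row.alt_allele,
                )
            )

    panel = Panel(amplicons=amplicons, sites=sites)
    if reference is not None:
        panel.attach_reference(_read_reference(reference, panel))
    return panel


def _read_reference(path: str | Path, panel: Panel) -> dict[str, str]:
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    out: dict[str, str] = {}
    for amp in panel.amplicons.values():
        if amp.amplicon_id in records:
            out[amp.amplicon_id] = records[amp.amplicon_id]
        elif amp.chrom in records and not amp.flagged:
            out[amp.amplicon_id] = records[amp.chrom][amp.start - 1 : amp.stop]
    return out


def export_table(panel: Panel, path: str | Path) -> Path:
    """Write the panel back out in the loadable TSV layout."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("amplicon_id\tchrom\tstart\tstop\tsize\tannotation\n")
        for amp in panel.amplicons.values():
            fh.write(
                f"{amp.amplicon_id}\t{amp.chrom}\t{amp.start}\t{amp.stop}\t"
                f"{amp.size_bp}\t{amp.annotation}\n"
            )
    return path


def export_bed(panel: Panel, path: str | Path) -> Path:
    """Write unflagged amplicons as 0-based half-open BED intervals."""
    path = Path(path)
    with open(path, "w") as fh:
        for amp in panel.amplicons.values():
            if amp.flagged:
                log.warning("excluding flagged amplicon %s from BED: %s",
                            amp.amplicon_id, amp.flag_reason)
                continue
            fh.write(f"{amp.chrom}\t{amp.start - 1}\t{amp.stop}\t{amp.amplicon_id}\n")
    return path


def synthetic_reference(panel: Panel, seed: int) -> dict[str, str]:
    """Deterministic random reference sequences, one per amplicon.

    The assay never needs genome context beyond the amplicon itself, so a
    seeded synthetic sequence of the right length is a faithful stand-in
    for simulation and testing.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for amp in sorted(panel.amplicons.values(), key=lambda a: a.amplicon_id):
        out[amp.amplicon_id] = "".join(rng.choice(list(BASES), size=amp.size_bp))
    return out


def default_panel(reference_seed: int | None = None) -> Panel:
    """The bundled 49-amplicon panel with its synthetic SNP-site layout.

    Site offsets inside each amplicon are synthetic (real per-site
    coordinates are not part of the published table); pass reference_seed
    to attach a seeded synthetic reference and resolve ref/alt alleles.
    """
    data = resources.files("sctgeno") / "_data"
    with resources.as_file(data / "panel.tsv") as p, resources.as_file(data / "sites.tsv") as s:
        panel = load_panel(p, sites_table=s)
    if reference_seed is not None:
        panel.attach_reference(synthetic_reference(panel, reference_seed))
    return panel


def default_targets() -> pd.DataFrame:
    """Bundled disease-variant target table (synthetic offsets)."""
    data = resources.files("sctgeno") / "_data"
    with resources.as_file(data / "targets.tsv") as t:
        return pd.read_csv(t, sep="\t", dtype={"offset": int, "del_len": int})
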