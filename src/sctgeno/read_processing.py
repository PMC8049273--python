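"""Paired-read stitching, amplicon alignment, and per-site pileup.

Reads come off the sequencer as 2x76 pairs.  For amplicons shorter than
150 bp the pair overlaps and is merged into a consensus; for longer
amplicons the two reads cannot overlap and are joined with a 15-N pad.
Alignment is against the small amplicon reference set only: candidate
amplicons are found by exact 15-mer seeding, then each candidate is scored
with a Levenshtein-path (edit-distance) alignment that yields a CIGAR over
amplicon coordinates.  Padded reads are aligned arm-by-arm so that the pad
and the uncovered middle of a long amplicon cost nothing, mirroring an
aligner configured to tolerate a large unmatched internal gap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib
import pysam
from Bio import SeqIO

from .panel import Panel, SNPSite
from .util import revcomp

PAD_LEN = 15
PAD = "N" * PAD_LEN
#: sentinel quality carried by pad bases
PAD_QUAL = 0
#: amplicons at least this long cannot be covered by an overlapping 2x76 pair
NO_OVERLAP_SIZE = 150

_N_EQUALITIES = [("N", b) for b in "ACGT"]
_CIG_RE = re.compile(r"(\d+)([=XMIDS])")


class StitchFailure(Exception):
    """No acceptable overlap between the two reads of a short-amplicon pair."""


@dataclass
class StitchedRead:
    read_id: str
    sequence: str
    qualities: list[int]
    pad_present: bool = False
    source_amplicon: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")
        if self.pad_present and PAD not in self.sequence:
            raise ValueError("pad_present but no 15-N pad in sequence")


@dataclass
class AlignedRead:
    read_id: str
    amplicon_id: str
    start_offset: int  # 0-based on the amplicon
    cigar: str
    sequence: str
    qualities: list[int] = field(default_factory=list)
    mapping_ok: bool = True
    edit_distance: int = 0

    def cigar_ops(self) -> list[tuple[int, str]]:
        return [(int(n), op) for n, op in _CIG_RE.findall(self.cigar)]

    def query_consumed(self) -> int:
        return sum(n for n, op in self.cigar_ops() if op in "MIS=X")

    def ref_consumed(self) -> int:
        return sum(n for n, op in self.cigar_ops() if op in "MD=X")


def stitch_pair(
    read1: tuple[str, Sequence[int]],
    read2: tuple[str, Sequence[int]],
    amplicon_size: int,
    read_id: str = "read",
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.10,
) -> StitchedRead:
    """Merge a 2x76 pair. read2 is in sequencing orientation (reverse strand).

    Short amplicons (< 150 bp): maximal suffix/prefix overlap merge, taking
    the higher-quality base at each disagreement.  Longer amplicons: the
    reads cannot overlap, so read1 + 15 N + revcomp(read2) is emitted.
    """
    seq1, qual1 = read1[0].upper(), list(read1[1])
    seq2, qual2 = read2[0].upper(), list(read2[1])
    if min(len(seq1), len(seq2)) < 20:
        raise ValueError("reads shorter than 20 bp")
    seq2f = revcomp(seq2)
    qual2f = qual2[::-1]

    if amplicon_size >= NO_OVERLAP_SIZE:
        return StitchedRead(
            read_id=read_id,
            sequence=seq1 + PAD + seq2f,
            qualities=qual1 + [PAD_QUAL] * PAD_LEN + qual2f,
            pad_present=True,
        )

    best = _find_overlap(seq1, seq2f, min_overlap, max_mismatch_frac)
    if best is None:
        raise StitchFailure(f"{read_id}: no overlap >= {min_overlap} bp")
    olen = best
    merged_seq = []
    merged_qual = []
    off = len(seq1) - olen
    for i in range(olen):
        b1, q1 = seq1[off + i], qual1[off + i]
        b2, q2 = seq2f[i], qual2f[i]
        if b1 == b2:
            merged_seq.append(b1)
            merged_qual.append(max(q1, q2))
        elif q1 >= q2:
            merged_seq.append(b1)
            merged_qual.append(q1)
        else:
            merged_seq.append(b2)
            merged_qual.append(q2)
    return StitchedRead(
        read_id=read_id,
        sequence=seq1[:off] + "".join(merged_seq) + seq2f[olen:],
        qualities=qual1[:off] + merged_qual + qual2f[olen:],
        pad_present=False,
    )


def _find_overlap(seq1: str, seq2f: str, min_overlap: int, max_mismatch_frac: float) -> int | None:
    """Largest suffix(seq1)/prefix(seq2f) overlap within the mismatch budget."""
    for olen in range(min(len(seq1), len(seq2f)), min_overlap - 1, -1):
        tail = seq1[len(seq1) - olen :]
        head = seq2f[:olen]
        budget = int(max_mismatch_frac * olen)
        mismatches = 0
        for a, b in zip(tail, head):
            if a != b and a != "N" and b != "N":
                mismatches += 1
                if mismatches > budget:
                    break
        else:
            return olen
    return None


class AmpliconAligner:
    """Seed-and-extend aligner over a panel's amplicon references.

    Exact 15-mer seeding shortlists candidate amplicons; each candidate is
    scored by edit-distance path alignment (infix mode, N as wildcard).
    Both read orientations are tried.
    """

    SEED_K = 15

    def __init__(self, panel: Panel, max_divergence: float = 0.15):
        self.panel = panel
        self.max_divergence = max_divergence
        self._index: dict[str, set[str]] = {}
        for amp in panel.amplicons.values():
            if amp.ref_seq is None:
                continue
            for i in range(len(amp.ref_seq) - self.SEED_K + 1):
                self._index.setdefault(amp.ref_seq[i : i + self.SEED_K], set()).add(
                    amp.amplicon_id
                )
        if not self._index:
            raise ValueError("panel has no reference sequences to align against")

    def _candidates(self, seq: str) -> set[str]:
        hits: set[str] = set()
        for i in range(0, len(seq) - self.SEED_K + 1, 4):
            kmer = seq[i : i + self.SEED_K]
            if "N" in kmer:
                continue
            hits |= self._index.get(kmer, set())
        return hits

    def align(self, read: StitchedRead | str, read_id: str = "read") -> AlignedRead:
        if isinstance(read, str):
            read = StitchedRead(read_id=read_id, sequence=read,
                                qualities=[30] * len(read), pad_present=PAD in read)
        if not read.sequence:
            raise ValueError("empty sequence")

        best: AlignedRead | None = None
        for seq, quals in (
            (read.sequence, read.qualities),
            (revcomp(read.sequence), read.qualities[::-1]),
        ):
            for amp_id in sorted(self._candidates(seq)):
                aln = self._align_one(read.read_id, seq, quals, amp_id)
                if aln is not None and (best is None or aln.edit_distance < best.edit_distance):
                    best = aln
        if best is None:
            return AlignedRead(
                read_id=read.read_id, amplicon_id="*", start_offset=0,
                cigar="", sequence=read.sequence, qualities=list(read.qualities),
                mapping_ok=False, edit_distance=len(read.sequence),
            )
        return best

    def _align_one(
        self, read_id: str, seq: str, quals: list[int], amp_id: str
    ) -> AlignedRead | None:
        ref = self.panel.amplicons[amp_id].ref_seq
        assert ref is not None
        pad_at = seq.find(PAD)
        if pad_at > 0 and pad_at + PAD_LEN < len(seq):
            return self._align_padded(read_id, seq, quals, amp_id, ref, pad_at)
        res = edlib.align(seq, ref, mode="HW", task="path",
                          additionalEqualities=_N_EQUALITIES)
        if res["editDistance"] < 0 or not res["locations"]:
            return None
        start = res["locations"][0][0] or 0
        dist = res["editDistance"]
        ok = dist <= self.max_divergence * len(seq)
        return AlignedRead(
            read_id=read_id, amplicon_id=amp_id, start_offset=start,
            cigar=_to_samlike(res["cigar"]), sequence=seq, qualities=quals,
            mapping_ok=ok, edit_distance=dist,
        )

    def _align_padded(
        self, read_id: str, seq: str, quals: list[int], amp_id: str, ref: str, pad_at: int
    ) -> AlignedRead | None:
        """Arm-by-arm alignment: the 15-N pad and the skipped reference
        middle are free, emulating a large tolerated internal gap."""
        arm1, arm2 = seq[:pad_at], seq[pad_at + PAD_LEN :]
        r1 = edlib.align(arm1, ref, mode="HW", task="path",
                         additionalEqualities=_N_EQUALITIES)
        if r1["editDistance"] < 0 or not r1["locations"]:
            return None
        s1, e1 = r1["locations"][0]
        s1 = s1 or 0
        tail = ref[e1 + 1 :]
        r2 = edlib.align(arm2, tail, mode="HW", task="path",
                         additionalEqualities=_N_EQUALITIES)
        if r2["editDistance"] < 0 or not r2["locations"] or not tail:
            return None
        s2, _ = r2["locations"][0]
        s2 = s2 or 0
        gap = s2  # reference bases skipped between the arms
        cigar = _to_samlike(r1["cigar"])
        cigar += f"{PAD_LEN}I"
        if gap:
            cigar += f"{gap}D"
        cigar += _to_samlike(r2["cigar"])
        dist = r1["editDistance"] + r2["editDistance"]
        ok = dist <= self.max_divergence * (len(arm1) + len(arm2))
        return AlignedRead(
            read_id=read_id, amplicon_id=amp_id, start_offset=s1,
            cigar=_merge_runs(cigar), sequence=seq, qualities=quals,
            mapping_ok=ok, edit_distance=dist,
        )


def _to_samlike(cigar: str) -> str:
    """Collapse edlib's extended =/X ops into plain M runs."""
    out: list[tuple[int, str]] = []
    for n, op in _CIG_RE.findall(cigar):
        op = "M" if op in "=X" else op
        n = int(n)
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))
    return "".join(f"{n}{op}" for n, op in out)


def _merge_runs(cigar: str) -> str:
    return _to_samlike(cigar)


def align_read(read: StitchedRead | str, panel: Panel, **kwargs) -> AlignedRead:
    """One-shot convenience wrapper; build an AmpliconAligner for batches."""
    return AmpliconAligner(panel, **kwargs).align(read)


def read_base_at(aln: AlignedRead, offset: int) -> tuple[str | None, int, str]:
    """Base carried by an aligned read at a 0-based amplicon offset.

    Returns (base, quality, kind) with kind in {'base', 'del', 'uncovered'}.
    Pad/N bases report kind 'uncovered'.  An insertion immediately at the
    site marks the read indel-bearing there: kind 'del' is reserved for a
    deletion spanning the site.
    """
    ref_pos = aln.start_offset
    q_pos = 0
    for n, op in aln.cigar_ops():
        if op == "M":
            if ref_pos <= offset < ref_pos + n:
                i = q_pos + (offset - ref_pos)
                base = aln.sequence[i]
                qual = aln.qualities[i] if aln.qualities else 30
                if base == "N":
                    return None, qual, "uncovered"
                return base, qual, "base"
            ref_pos += n
            q_pos += n
        elif op == "D":
            if ref_pos <= offset < ref_pos + n:
                return None, 0, "del"
            ref_pos += n
        elif op in "IS":
            q_pos += n
    return None, 0, "uncovered"


def pileup_counts(
    aligned_reads: Iterable[AlignedRead],
    sites: Iterable[SNPSite],
    min_baseq: int = 13,
) -> dict[str, dict[str, int]]:
    """Per-site base counts over A/C/G/T plus a 'masked' bucket.

    Reads whose alignment has a deletion spanning the site are counted as
    masked (indel information is not allowed to masquerade as an allele);
    N/pad bases and sub-threshold base qualities are excluded entirely.
    Unmasked allele fractions are computed over the A/C/G/T counts only.
    """
    sites = list(sites)
    by_amp: dict[str, list[SNPSite]] = {}
    for s in sites:
        by_amp.setdefault(s.amplicon_id, []).append(s)
    counts: dict[str, dict[str, int]] = {
        s.site_id: {"A": 0, "C": 0, "G": 0, "T": 0, "masked": 0} for s in sites
    }
    for aln in aligned_reads:
        if not aln.mapping_ok:
            continue
        for site in by_amp.get(aln.amplicon_id, []):
            base, qual, kind = read_base_at(aln, site.offset)
            if kind == "del":
                counts[site.site_id]["masked"] += 1
            elif kind == "base" and qual >= min_baseq and base in "ACGT":
                counts[site.site_id][base] += 1
    return counts


# ---------------------------------------------------------------------------
# standard-format IO

def read_paired_fastq(path1: str | Path, path2: str | Path) -> Iterator[
    tuple[str, str, list[int], str, list[int]]
]:
    """Yield (read_id, seq1, qual1, seq2, qual2) from a FASTQ pair."""
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2):
        yield (
            r1.id,
            str(r1.seq).upper(),
            list(r1.letter_annotations["phred_quality"]),
            str(r2.seq).upper(),
            list(r2.letter_annotations["phred_quality"]),
        )


def write_sam(aligned_reads: Iterable[AlignedRead], panel: Panel, path: str | Path) -> Path:
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": amp.amplicon_id, "LN": amp.size_bp}
            for amp in panel.amplicons.values()
        ],
    }
    refs = [sq["SN"] for sq in header["SQ"]]
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in aligned_reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.sequence
            if aln.qualities:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(min(q, 60) + 33) for q in aln.qualities)
                )
            if aln.mapping_ok and aln.amplicon_id in refs:
                seg.reference_id = refs.index(aln.amplicon_id)
                seg.reference_start = aln.start_offset
                seg.cigarstring = aln.cigar
                seg.flag = 0
                seg.mapping_quality = 60
            else:
                seg.flag = 4
                seg.mapping_quality = 0
            out.write(seg)
    return path


def read_sam(path: str | Path) -> list[AlignedRead]:
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            quals = list(seg.query_qualities) if seg.query_qualities is not None else []
            out.append(
                AlignedRead(
                    read_id=seg.query_name or "read",
                    amplicon_id=seg.reference_name or "*",
                    start_offset=seg.reference_start,
                    cigar=seg.cigarstring or "",
                    sequence=seg.query_sequence.upper(),
                    qualities=quals,
                    mapping_ok=True,
                    edit_distance=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                )
            )
    return out


def stitch_auto(
    read1: tuple[str, Sequence[int]],
    read2: tuple[str, Sequence[int]],
    read_id: str = "read",
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.10,
) -> StitchedRead:
    """Stitch without knowing the source amplicon: try an overlap merge
    first, fall back to the 15-N pad join (the non-assembled-pair path)."""
    try:
        return stitch_pair(read1, read2, amplicon_size=0, read_id=read_id,
                           min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac)
    except StitchFailure:
        return stitch_pair(read1, read2, amplicon_size=NO_OVERLAP_SIZE, read_id=read_id)
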