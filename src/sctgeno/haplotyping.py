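"""Amplicon microhaplotyping by edit-distance grouping of concise reads.

Each read over a polymorphic amplicon is reduced to a *concise sequence*:
one character per SNP site of the region (28 characters for HLA-A), '-'
where the read does not cover the site.  Concise reads are tallied, the
top-ranked types are clustered by Levenshtein distance, and the one or two
major groups become the sample's called haplotypes.  Minor groups are
tiered by read fraction as a diagnostic of when the artifact arose: a high
fraction suggests a variant pre-existing in the cell, a medium fraction a
whole-genome-amplification error, and a low fraction a late PCR artifact.

'-' (missing data) is scored as distance 0 against any base, so the
uncovered arm of a padded read cannot inflate distances.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from .panel import SNPSite
from .read_processing import AlignedRead, read_base_at

#: wildcard characters that match anything at zero cost
_WILDCARDS = ("-", "N")
_EQUALITIES = [(w, b) for w in _WILDCARDS for b in "ACGT-N"] + [("-", "N")]

ARTIFACT_TIERS = ("preexisting", "wga_stage", "pcr_artifact")


@dataclass
class ConciseRead:
    read_id: str
    amplicon_id: str
    concise_seq: str


@dataclass
class HaplotypeGroup:
    representative: str
    members: dict[str, int]  # concise type -> read count
    count: int
    fraction: float
    mean_pairwise_dist: float = 0.0
    tier: str | None = None  # None for called haplotypes


@dataclass
class HaplotypeSet:
    sample_id: str
    amplicon_id: str
    groups: list[HaplotypeGroup] = field(default_factory=list)
    called_haplotypes: list[str] = field(default_factory=list)
    n_reads: int = 0


def hap_distance(a: str, b: str) -> int:
    """Levenshtein distance with '-' and 'N' free against anything."""
    if not a or not b:
        # wildcards are free only as substitutions; indels always cost 1
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance",
                       additionalEqualities=_EQUALITIES)["editDistance"]


def make_concise(aligned_read: AlignedRead, region_sites: Sequence[SNPSite]) -> ConciseRead:
    """Extract the read's base at each SNP site of the region, CIGAR-aware."""
    if not region_sites:
        raise ValueError("region has no sites")
    amp_id = region_sites[0].amplicon_id
    if aligned_read.amplicon_id != amp_id:
        raise ValueError(
            f"read aligned to {aligned_read.amplicon_id}, not region amplicon {amp_id}"
        )
    chars = []
    for site in sorted(region_sites, key=lambda s: s.offset):
        base, _qual, kind = read_base_at(aligned_read, site.offset)
        chars.append(base if kind == "base" else "-")
    return ConciseRead(
        read_id=aligned_read.read_id, amplicon_id=amp_id, concise_seq="".join(chars)
    )


def tally_and_group(
    concise_reads: Iterable[ConciseRead | str],
    top_k: int = 10,
    same_group_max_dist: int = 1,
    calling_fraction: float = 0.10,
    preexisting_min_fraction: float = 0.20,
    wga_min_fraction: float = 0.05,
    sample_id: str = "sample",
    amplicon_id: str | None = None,
) -> HaplotypeSet:
    """Tally concise reads, keep the top_k types, and group them.

    Types are visited in descending count order; a type merges into an
    established group when it is within same_group_max_dist of exactly one
    group representative (the typical single-nucleotide amplification
    artifact).  A type equally close to several groups is ambiguous and is
    left as its own minor group so it stays visible for artifact tiering.
    Groups with read fraction >= calling_fraction become called haplotypes
    (at most two, by count — the sample is diploid); the rest are tiered
    preexisting / wga_stage / pcr_artifact by fraction.
    """
    seqs: list[str] = []
    amp = amplicon_id
    for r in concise_reads:
        if isinstance(r, ConciseRead):
            seqs.append(r.concise_seq)
            amp = amp or r.amplicon_id
        else:
            seqs.append(r)
    result = HaplotypeSet(sample_id=sample_id, amplicon_id=amp or "?", n_reads=len(seqs))
    if not seqs:
        return result
    tally = Counter(seqs)
    # rank by count, ties lexicographic, keep top_k
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]

    groups: list[dict] = []
    for seq, count in ranked:
        near = [
            g for g in groups if hap_distance(seq, g["representative"]) <= same_group_max_dist
        ]
        if len(near) == 1:
            g = near[0]
            g["members"][seq] = count
            g["count"] += count
        else:
            groups.append({"representative": seq, "members": {seq: count}, "count": count})

    total = len(seqs)
    out_groups: list[HaplotypeGroup] = []
    for g in sorted(groups, key=lambda g: (-g["count"], g["representative"])):
        out_groups.append(
            HaplotypeGroup(
                representative=g["representative"],
                members=dict(g["members"]),
                count=g["count"],
                fraction=g["count"] / total,
                mean_pairwise_dist=_weighted_mean_dist(g["members"]),
            )
        )

    called = [g for g in out_groups if g.fraction >= calling_fraction][:2]
    called_set = {id(g) for g in called}
    for g in out_groups:
        if id(g) in called_set:
            g.tier = None
        elif g.fraction >= preexisting_min_fraction:
            g.tier = "preexisting"
        elif g.fraction >= wga_min_fraction:
            g.tier = "wga_stage"
        else:
            g.tier = "pcr_artifact"
    result.groups = out_groups
    result.called_haplotypes = [g.representative for g in called]
    return result


def _weighted_mean_dist(members: dict[str, int]) -> float:
    """Read-count-weighted mean pairwise distance within a group; reported
    as a diagnostic (a tight group of amplification artifacts sits well
    below 1)."""
    items = list(members.items())
    num = 0.0
    den = 0.0
    for i, (a, ca) in enumerate(items):
        for b, cb in items:
            w = ca * cb
            den += w
            if a != b:
                num += w * hap_distance(a, b)
    return num / den if den else 0.0


def compare_haplotypes(
    cell: HaplotypeSet,
    mother: HaplotypeSet,
    novelty_min_dist: int = 2,
) -> str:
    """'informative_fetal' if the cell carries a called haplotype at
    distance >= novelty_min_dist from every maternal called haplotype;
    distance-1 novelty is treated as an amplification artifact.  'void'
    when either sample has no called haplotype on this amplicon."""
    if not cell.called_haplotypes or not mother.called_haplotypes:
        return "void"
    for hap in cell.called_haplotypes:
        if all(hap_distance(hap, m) >= novelty_min_dist for m in mother.called_haplotypes):
            return "informative_fetal"
    return "uninformative"


def trio_inheritance(
    cell: HaplotypeSet,
    mother: HaplotypeSet,
    father: HaplotypeSet | None,
) -> dict:
    """Label each fetal called haplotype by parental origin (exact match)
    and decide whether the cell is confirmed fetal.

    true_fetal requires one maternal-match plus one paternal-match, or a
    paternal-match in a single-haplotype cell (the other haplotype having
    dropped out).  Without a father the decision degrades to the
    novelty-based maternal comparison.
    """
    if father is None or not father.called_haplotypes:
        verdict = compare_haplotypes(cell, mother)
        return {"origins": {}, "verdict": "true_fetal" if verdict == "informative_fetal" else verdict}
    if not cell.called_haplotypes or not mother.called_haplotypes:
        return {"origins": {}, "verdict": "void"}
    origins: dict[str, str] = {}
    for hap in cell.called_haplotypes:
        if hap in mother.called_haplotypes:
            origins[hap] = "maternal_match"
        elif hap in father.called_haplotypes:
            origins[hap] = "paternal_match"
        else:
            origins[hap] = "unmatched"
    labels = set(origins.values())
    if "maternal_match" in labels and "paternal_match" in labels:
        verdict = "true_fetal"
    elif "paternal_match" in labels and len(cell.called_haplotypes) == 1:
        verdict = "true_fetal"  # maternal haplotype dropout
    else:
        verdict = "not_confirmed"
    return {"origins": origins, "verdict": verdict}
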