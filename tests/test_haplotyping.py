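"""Concise-read extraction, edit-distance grouping, and haplotype
comparison, with a textbook dynamic-programming oracle for the distance
and an independent re-implementation of the grouping rule."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from sctgeno.haplotyping import (
    compare_haplotypes,
    hap_distance,
    make_concise,
    tally_and_group,
    trio_inheritance,
)
from sctgeno.read_processing import AlignedRead


# --- textbook Levenshtein with missing-data wildcards -----------------------

def _dp_distance(a: str, b: str) -> int:
    """Classic Wagner-Fischer; '-' and 'N' substitute free against anything."""
    wild = {"-", "N"}

    def sub(x, y):
        return 0 if x == y or x in wild or y in wild else 1

    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + sub(a[i - 1], b[j - 1]))
        prev = cur
    return prev[n]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGT-N", min_size=0, max_size=12),
    st.text(alphabet="ACGT-N", min_size=0, max_size=12),
)
def test_distance_matches_textbook_dp(a, b):
    assert hap_distance(a, b) == _dp_distance(a, b)


def test_wildcard_costs_nothing():
    assert hap_distance("TA--", "TAGC") == 0
    assert hap_distance("-A", "GC") == 1
    assert hap_distance("TA", "GC") == 2


# --- concise-read extraction ------------------------------------------------

def _sites(amp="H", offsets=(3, 7)):
    from sctgeno.panel import SNPSite
    return [SNPSite(f"{amp}_s{i}", amp, off) for i, off in enumerate(offsets)]


class TestMakeConcise:
    def test_extracts_site_bases(self):
        #      0123456789
        seq = "CCCTAGGATC"  # T at 3, A at 7
        aln = AlignedRead("r", "H", 0, "10M", seq, [37] * 10)
        assert make_concise(aln, _sites()).concise_seq == "TA"

    def test_deletion_upstream_shifts_coordinates_correctly(self):
        # read lacks ref base 1: CIGAR 1M1D8M; site offsets 3 and 7 still T, A
        seq = "C" + "CTAGGATC"
        aln = AlignedRead("r", "H", 0, "1M1D8M", seq, [37] * 9)
        assert make_concise(aln, _sites()).concise_seq == "TA"

    def test_deletion_at_site_is_missing(self):
        aln = AlignedRead("r", "H", 0, "3M1D6M", "CCCAGGATC"[:9], [37] * 9)
        assert make_concise(aln, _sites()).concise_seq[0] == "-"

    def test_uncovered_arm_yields_trailing_dashes(self):
        # read covers only offsets 0-4 of the region
        aln = AlignedRead("r", "H", 0, "5M", "CCCTA", [37] * 5)
        assert make_concise(aln, _sites()).concise_seq == "T-"

    def test_wrong_amplicon_rejected(self):
        aln = AlignedRead("r", "OTHER", 0, "10M", "A" * 10, [37] * 10)
        with pytest.raises(ValueError):
            make_concise(aln, _sites())


# --- tally and group --------------------------------------------------------

class TestTallyAndGroup:
    def test_two_major_haplotypes_plus_stray_artifact(self):
        reads = ["TA"] * 40 + ["GC"] * 45 + ["GA"]
        hs = tally_and_group(reads, amplicon_id="H")
        assert sorted(hs.called_haplotypes) == ["GC", "TA"]
        tiers = {g.representative: g.tier for g in hs.groups}
        # GA is equidistant from both called groups: kept separate, tiered
        assert tiers["GA"] == "pcr_artifact"

    def test_single_type_single_haplotype(self):
        hs = tally_and_group(["TA"] * 50, amplicon_id="H")
        assert hs.called_haplotypes == ["TA"]

    def test_one_nucleotide_artifact_merges(self):
        reads = ["TACG"] * 30 + ["TACT"] * 28
        hs = tally_and_group(reads, amplicon_id="H")
        assert len(hs.groups) == 1
        assert hs.groups[0].count == 58
        assert hs.groups[0].representative == "TACG"
        assert 0 < hs.groups[0].mean_pairwise_dist < 0.5

    def test_grouping_idempotent_on_representatives(self):
        reads = ["TACG"] * 30 + ["TACT"] * 28 + ["GGGG"] * 40
        hs = tally_and_group(reads, amplicon_id="H")
        reps = [g.representative for g in hs.groups]
        hs2 = tally_and_group(reps, amplicon_id="H")
        assert [g.representative for g in hs2.groups] == sorted(reps)

    def test_count_conservation_and_fraction_cap(self):
        reads = ["AA"] * 5 + ["AC"] * 4 + ["GG"] * 3 + ["GT"] * 2 + ["CC"]
        hs = tally_and_group(reads, amplicon_id="H")
        assert sum(g.count for g in hs.groups) == len(reads)
        assert sum(g.fraction for g in hs.groups) <= 1.0 + 1e-9

    def test_top_k_truncation(self):
        reads = []
        for i, c in enumerate("ACGT"):
            reads += [c * 4] * (20 - i)
        reads += ["AAAT", "AATT", "ATTT"]  # three singletons beyond top 4
        hs = tally_and_group(reads, top_k=4, amplicon_id="H")
        assert sum(g.count for g in hs.groups) == sum(20 - i for i in range(4))

    def test_zero_reads_empty_set(self):
        hs = tally_and_group([], amplicon_id="H")
        assert hs.groups == [] and hs.called_haplotypes == []


def _oracle_group(types_counts, max_dist=1):
    """Independent re-implementation of the grouping rule: visit types in
    count order (ties lexicographic); merge into a group when within
    max_dist of exactly one representative, else found a new group."""
    groups = []
    for seq, count in sorted(types_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        near = [g for g in groups if _dp_distance(seq, g["rep"]) <= max_dist]
        if len(near) == 1:
            near[0]["members"][seq] = count
        else:
            groups.append({"rep": seq, "members": {seq: count}})
    return sorted(
        (frozenset(g["members"]), sum(g["members"].values())) for g in groups
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.dictionaries(
        st.text(alphabet="ACGT", min_size=3, max_size=10),
        st.integers(1, 50),
        min_size=1,
        max_size=6,
    )
)
def test_grouping_matches_oracle(types_counts):
    hs = tally_and_group(
        [s for s, c in types_counts.items() for _ in range(c)], amplicon_id="H"
    )
    got = sorted((frozenset(g.members), g.count) for g in hs.groups)
    assert got == _oracle_group(types_counts)


@pytest.mark.parametrize("s", [1, 3, 6, 10])
def test_haplotype_space_exceeds_genotype_classes(s):
    """s biallelic sites give 2^s distinct haplotypes, always >= the 3
    genotype classes a single SNP offers — the power argument for
    microhaplotypes."""
    haps = set(itertools.product("AB", repeat=s))
    assert len(haps) == 2**s
    if s >= 2:
        assert len(haps) > 3


# --- sample comparison ------------------------------------------------------

def _hapset(called, amp="H", sample="s"):
    from sctgeno.haplotyping import HaplotypeSet
    return HaplotypeSet(sample_id=sample, amplicon_id=amp,
                        called_haplotypes=list(called))


class TestCompareHaplotypes:
    def test_distance_two_novelty_is_informative(self):
        assert compare_haplotypes(_hapset(["AAAA"]), _hapset(["TTTT"])) == "informative_fetal"

    def test_subset_of_maternal_uninformative(self):
        assert compare_haplotypes(_hapset(["GC"]), _hapset(["TA", "GC"])) == "uninformative"

    def test_distance_one_novelty_default_artifact(self):
        # the mocked fetal TA/GA vs maternal TA/GC example: GA is distance 1
        # from TA, so the default artifact-merging rule calls it uninformative
        assert compare_haplotypes(_hapset(["TA", "GA"]), _hapset(["TA", "GC"])) == "uninformative"

    def test_distance_one_novelty_with_strict_config(self):
        got = compare_haplotypes(_hapset(["TA", "GA"]), _hapset(["TA", "GC"]),
                                 novelty_min_dist=1)
        assert got == "informative_fetal"

    def test_empty_sample_void(self):
        assert compare_haplotypes(_hapset([]), _hapset(["TA"])) == "void"


class TestTrioInheritance:
    def test_biparental_match_confirms_fetal(self):
        r = trio_inheritance(_hapset(["AAAA", "TTTT"]),
                             _hapset(["AAAA", "CCCC"]),
                             _hapset(["TTTT", "GGGG"]))
        assert r["verdict"] == "true_fetal"
        assert r["origins"] == {"AAAA": "maternal_match", "TTTT": "paternal_match"}

    def test_two_maternal_haplotypes_not_confirmed(self):
        r = trio_inheritance(_hapset(["AAAA", "CCCC"]),
                             _hapset(["AAAA", "CCCC"]),
                             _hapset(["TTTT", "GGGG"]))
        assert r["verdict"] == "not_confirmed"

    def test_paternal_only_with_dropout_confirms(self):
        r = trio_inheritance(_hapset(["TTTT"]),
                             _hapset(["AAAA", "CCCC"]),
                             _hapset(["TTTT", "GGGG"]))
        assert r["verdict"] == "true_fetal"

    def test_missing_father_degrades_to_novelty_rule(self):
        r = trio_inheritance(_hapset(["AAAA", "TTTT"]), _hapset(["AAAA", "CCCC"]), None)
        assert r["verdict"] == "true_fetal"
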