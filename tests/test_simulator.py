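"""Generator contracts: Mendelian inheritance, determinism, dropout
semantics, and channel fidelity of the readout layers."""

import numpy as np
import pytest

from sctgeno.simulator import (
    SimConfig,
    cohort_counts,
    gdna_products,
    readout_counts,
    simulate_cell,
    simulate_cohort,
    simulate_family,
    write_truth,
)
from sctgeno.snp_typing import call_alleles, compare_to_maternal
from sctgeno.classification import classify_cell


def _bias(panel):
    return {a: 1.0 for a in panel.amplicons}


class TestFamily:
    def test_fetus_is_mendelian_everywhere(self, panel, rng):
        cfg = SimConfig(seed=2)
        for i in range(10):
            fam = simulate_family(cfg, panel, rng, case_id=f"c{i}")
            for amp_id, fetal in fam.alleles["fetus"].items():
                mother = fam.alleles["mother"][amp_id]
                father = fam.alleles["father"][amp_id]
                if not fetal:  # female fetus at a Y marker
                    continue
                if len(fetal) == 1:  # Y marker
                    assert fetal[0] in father
                else:
                    assert fetal[0] in mother and fetal[1] in father

    def test_zero_maf_collapses_to_reference(self, panel, rng):
        cfg = SimConfig(seed=2, maf_range=(0.0, 0.0))
        fam = simulate_family(cfg, panel, rng, case_id="c")
        for site in panel.sites:
            amp = panel.amplicons[site.amplicon_id]
            if amp.category in ("identity_snp", "y_marker"):
                for sample in ("mother", "father", "fetus"):
                    for gt in fam.genotype(sample, site):
                        assert gt == site.ref_allele

    def test_heterozygosity_matches_binomial_expectation(self, panel, rng):
        """At MAF 0.5 a parent allele pair is het with probability 1/2;
        the empirical rate over many draws sits within 3 standard errors."""
        cfg = SimConfig(seed=2, maf_range=(0.5, 0.5))
        site = next(s for s in panel.sites
                    if panel.amplicons[s.amplicon_id].category == "identity_snp")
        n, het = 600, 0
        for i in range(n):
            fam = simulate_family(cfg, panel, rng, case_id=f"c{i}")
            gt = fam.genotype("mother", site)
            het += gt[0] != gt[1]
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(het / n - 0.5) < 3 * se

    def test_y_markers_track_fetal_sex(self, panel, rng):
        cfg = SimConfig(seed=2)
        for i in range(8):
            fam = simulate_family(cfg, panel, rng, case_id=f"c{i}")
            for amp in panel.amplicons.values():
                if amp.category != "y_marker":
                    continue
                assert fam.alleles["mother"][amp.amplicon_id] == []
                n_fetal = len(fam.alleles["fetus"][amp.amplicon_id])
                assert n_fetal == (1 if fam.fetal_sex == "male" else 0)


class TestCell:
    def test_forced_allele_dropout_gives_single_allele(self, panel, rng):
        cfg = SimConfig(seed=2, allele_dropout_prob=1.0, locus_dropout_prob=0.0,
                        maf_range=(0.5, 0.5))
        fam = simulate_family(cfg, panel, rng, case_id="c")
        cell = simulate_cell(fam, cfg, rng, "c_cell", panel)
        genome = "fetus" if cell.origin == "fetal" else "mother"
        for amp_id, product in cell.products.items():
            copies = fam.alleles[genome][amp_id]
            if len(copies) == 2 and copies[0] != copies[1]:
                assert len(product.copies) == 1, f"het {amp_id} escaped forced dropout"
                assert amp_id in cell.dropped_alleles

    def test_dropout_bookkeeping(self, panel, rng):
        cfg = SimConfig(seed=2, allele_dropout_prob=0.5, locus_dropout_prob=0.3)
        fam = simulate_family(cfg, panel, rng, case_id="c")
        cell = simulate_cell(fam, cfg, rng, "c_cell", panel)
        for amp_id in cell.dropped_amplicons:
            assert amp_id not in cell.products
        for amp_id, lost in cell.dropped_alleles.items():
            assert len(cell.products[amp_id].copies) == 1

    def test_all_fetal_when_contamination_off(self, panel):
        cfg = SimConfig(seed=5, n_cases=6, maternal_cell_prob=0.0)
        cohort = simulate_cohort(cfg, panel)
        assert all(c.origin == "fetal" for c in cohort.cells)


class TestCohort:
    def test_truth_tables_byte_identical_under_seed(self, panel, tmp_path):
        cfg = SimConfig(seed=11, n_cases=3)
        for d in ("a", "b"):
            write_truth(simulate_cohort(cfg, panel), panel, tmp_path / d)
        for name in ("truth_cells.tsv", "truth_genotypes.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_cells_per_case_range(self, panel):
        cfg = SimConfig(seed=11, n_cases=10)
        cohort = simulate_cohort(cfg, panel)
        from collections import Counter
        per_case = Counter(c.case_id for c in cohort.cells)
        assert all(3 <= n <= 10 for n in per_case.values())

    def test_fastq_output_round_trips(self, panel, tmp_path):
        from sctgeno.read_processing import read_paired_fastq

        cfg = SimConfig(seed=11, n_cases=1, cells_per_case=(1, 1), depth_mean=5)
        cohort = simulate_cohort(cfg, panel, outdir=tmp_path)
        cell = cohort.cells[0]
        pairs = list(read_paired_fastq(tmp_path / f"{cell.cell_id}_R1.fastq",
                                       tmp_path / f"{cell.cell_id}_R2.fastq"))
        assert pairs, "cell FASTQ should contain reads"
        rid, s1, q1, s2, q2 = pairs[0]
        assert len(s1) <= 76 and len(s2) <= 76 and len(q1) == len(s1)
        assert (tmp_path / "manifest.json").exists()


class TestChannelFidelity:
    def test_noise_free_counts_recover_genotypes(self, panel, rng):
        """With every artifact off, allele calls from the counts channel
        equal the true genotypes at all scorable sites."""
        cfg = SimConfig(seed=4, pcr_rate=0.0, wga_stage_rate=0.0, pre_wga_rate=0.0,
                        locus_dropout_prob=0.0, allele_dropout_prob=0.0,
                        depth_mean=200, depth_dispersion=80)
        fam = simulate_family(cfg, panel, rng, case_id="c")
        cell = simulate_cell(fam, cfg, rng, "c_cell", panel)
        counts = readout_counts(cell.products, panel, cfg, rng, _bias(panel))
        table = call_alleles(counts)
        genome = "fetus" if cell.origin == "fetal" else "mother"
        for site in panel.sites:
            truth = set(fam.genotype(genome, site))
            call = table[site.site_id]
            if not truth:
                assert call.depth == 0
            else:
                assert call.scorable and set(call.called) == truth

    def test_wga_stage_error_visible_at_medium_fraction(self, panel, rng):
        """A forced WGA-stage event puts a third allele on a medium
        fraction of one copy's reads."""
        from sctgeno.simulator import AmpliconProduct

        amp = panel.amplicons["rs964681"]
        site = panel.sites_for("rs964681")[0]
        base = amp.ref_seq[site.offset]
        other = {"A": "G", "C": "T", "G": "A", "T": "C"}[base]
        product = AmpliconProduct("rs964681", [amp.ref_seq, amp.ref_seq],
                                  wga_events=[(0, site.offset, other, 0.2)])
        cfg = SimConfig(seed=4, pcr_rate=0.0, depth_mean=500, depth_dispersion=1e5)
        counts = readout_counts({"rs964681": product}, panel, cfg, rng, _bias(panel))
        c = counts[site.site_id]
        frac = c[other] / sum(c[b] for b in "ACGT")
        assert 0.05 < frac < 0.15  # ~20% of one of two copies


class TestEndToEnd:
    def test_noise_free_cohort_classifies_perfectly(self, panel):
        """Faithful-channel round trip: with noise and dropout off, every
        fetal cell with informative truth sites is called fetal and no
        maternal cell ever is."""
        cfg = SimConfig(seed=8, n_cases=6, pcr_rate=0.0, wga_stage_rate=0.0,
                        pre_wga_rate=0.0, locus_dropout_prob=0.0,
                        allele_dropout_prob=0.0, depth_mean=200, depth_dispersion=80)
        cohort = simulate_cohort(cfg, panel)
        cell_counts, gdna_counts = cohort_counts(cohort, panel)
        fam_by_case = {f.case_id: f for f in cohort.families}
        for cell in cohort.cells:
            table = call_alleles(cell_counts[cell.cell_id], sample_id=cell.cell_id)
            mom = call_alleles(gdna_counts[cell.case_id])
            verdict = classify_cell(compare_to_maternal(table, mom), case_id=cell.case_id)
            fam = fam_by_case[cell.case_id]
            truth_inf = _truth_informative(fam, panel)
            if cell.origin == "maternal":
                assert verdict.verdict != "fetal"
            elif truth_inf >= 2 and truth_inf / max(verdict.comparable_snp_count, 1) >= 0.06:
                assert verdict.verdict == "fetal"
                assert verdict.informative_snp_count == truth_inf


def _truth_informative(fam, panel):
    n = 0
    for site in panel.sites:
        mom = set(fam.genotype("mother", site))
        fet = set(fam.genotype("fetus", site))
        if mom and fet and (fet - mom):
            n += 1
    return n
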