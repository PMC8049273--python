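# sctgeno

Amplicon-sequencing genotyping of single circulating trophoblasts (SCTs)
for cell-based non-invasive prenatal testing (NIPT).

## The problem

Cell-based NIPT isolates a handful of putative fetal trophoblasts from
maternal blood, amplifies each cell's genome (WGA), and analyses the
products. Before any downstream interpretation, each cell must be proven
fetal rather than maternal — roughly one picked cell in ten is a maternal
white blood cell — and WGA products are riddled with allele dropout and
amplification errors that make naive genotyping unreliable. `sctgeno`
implements the amplicon-seq workflow that solves this for researchers and
assay developers working on single-cell prenatal genotyping:

1. **SNP typing.** ~90 highly polymorphic SNPs in ~40 short amplicons are
   pileup-genotyped per cell. An allele is called when supported by ≥ 10
   reads and ≥ 5% of the site's reads. A site is *informative* when the
   cell shows an allele the mother's gDNA does not carry (mother AA, cell
   AB or \_B) at ≥ 10% allele fraction; a cell is scored **fetal** when ≥ 2
   SNPs are informative and they make up ≥ 6% (configurable: 6/8/10%) of
   the comparable SNPs, with < 20 comparable SNPs voiding the cell as low
   quality.
2. **Microhaplotyping.** Four amplicons (HLA-A, HLA-B, 7q11, 11q22) carry
   8–28 common SNPs each. Every read is reduced to a *concise sequence*
   (one character per SNP), concise types are tallied and clustered by
   Levenshtein distance (single-nucleotide neighbours merge as
   amplification artifacts), and the 1–2 major groups become the cell's
   haplotypes. With *s* sites an amplicon distinguishes up to 2^s
   haplotypes — far more states than a single SNP's three genotypes — and
   minor-group read fractions date an artifact to the cell itself, the WGA
   step, or the final PCR.
3. **Monogenic variants.** Known disease variants (HBB, CFTR, HEXA, DHCR7,
   RASPN targets bundled) are genotyped per cell from ref/alt read counts
   with a deliberately wide het band (AAF 0.10–0.90 — WGA skews real
   heterozygotes as far as AAF 0.87), and a multi-cell consensus
   reconciles allele dropout before reporting the fetal genotype.
4. **Evaluation.** Per-case outcome tabulation (0 / 1 / ≥ 2 fetal cells)
   and a contingency table against sex-by-sequencing truth (TP = fetal
   verdict & male) with sensitivity TP/(TP+FN) and precision TP/(TP+FP).
5. **Simulation.** A seeded generator produces whole cohorts — parental
   genotypes, Mendelian fetuses, maternal-cell contamination, locus and
   allele dropout, stage-resolved errors — as either per-site counts or
   literal 2×76 FASTQ pairs, with full truth tables.

Reads are 2×76 paired-end: pairs from amplicons < 150 bp are merged by
overlap consensus, longer amplicons are joined with a 15-N pad and aligned
arm-by-arm so the uncovered middle costs nothing.

## Worked example

```python
import sctgeno as sg

panel = sg.default_panel(reference_seed=1)          # 49 amplicons, 96 SNP sites
cfg = sg.SimConfig(seed=1, n_cases=4)
cohort = sg.simulate_cohort(cfg, panel)
result = sg.genotype_cohort(cohort, panel)          # allele calls -> verdicts

for v in result.verdicts[:4]:
    print(v.cell_id, v.verdict, f"{v.informative_snp_count}/{v.comparable_snp_count}")
table = sg.evaluate_vs_sex(result.verdicts, cohort.sex_truth())
print(table.summary())
```

prints

```
case0001_c01 fetal 12/79
case0001_c02 fetal 28/86
case0001_c03 fetal 13/62
case0001_c04 fetal 23/85
{'tp': 3, 'tn': 0, 'fp': 0, 'fn': 0, 'tp_rate_pct': 100.0, 'tn_rate_pct': 0.0,
 'fp_rate_pct': 0.0, 'fn_rate_pct': 0.0, 'sensitivity_pct': 100.0, 'precision_pct': 100.0}
```

Each verdict line is a cell, its fetal/uninformative/void call, and its
informative/comparable SNP counts; the summary is the sex-truth
contingency over cells from male pregnancies (a fetal-verdict cell that is
male by sequencing truth is a true positive), with rates as percentages of
evaluated cells.

The same workflow is available as a CLI (`sctgeno simulate`, `type`,
`classify`, `evaluate`, `monogenic`, `run-sim-pipeline`, `panel-bed`); all
outputs are TSV/JSON.

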