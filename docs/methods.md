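# Methods

## Model and assumptions

`sctgeno` treats single-cell genotyping as a three-layer problem: a
diploid genome (haploid on chrY), a whole-genome-amplification (WGA)
product derived from it by a lossy stochastic channel, and a sequencing
readout of that product. All calling and classification logic is written
against the channel's known failure modes:

- **Locus dropout** — an amplicon's template fails to amplify entirely.
- **Allele dropout** — at a heterozygous amplicon one allele's template is
  lost, so the cell reads as homozygous. Measured rates in single
  lymphoblasts are ~15% (unfixed) and ~8% (fixed); the simulator defaults
  to 15%.
- **Stage-resolved errors** — a substitution arising before WGA rides on
  essentially all reads of that allele; one arising during WGA appears on
  a *medium* fraction of reads (operationalised as 0.05–0.20 of one
  copy's reads); a final-round PCR error appears on isolated reads. The
  haplotyping module uses exactly this fraction logic in reverse to tier
  minor read groups (`preexisting` ≥ 0.20, `wga_stage` 0.05–0.20,
  `pcr_artifact` < 0.05).

The fetal-vs-maternal decision assumes the maternal gDNA control is
artifact-free (it is bulk DNA) and that a cell showing alleles absent
from the mother is fetal; the converse cannot distinguish a maternal cell
from an uninformative fetal cell, which is why the negative verdict is
"uninformative" rather than "maternal".

## Thresholds and parameters

| parameter | default | role |
|---|---|---|
| `min_minor_reads` | 10 reads | minor-allele calling floor |
| `min_minor_fraction` | 0.05 | minor-allele calling fraction |
| `informative_fraction` | 0.10 | fraction for scoring a fetal-informative allele |
| `min_informative_snps` | 2 | fetal-verdict SNP count floor |
| `min_informative_pct_of_comparable` | 0.06 (profiles 0.08/0.10) | fetal-verdict percentage gate |
| `min_comparable_snps` | 20 | below this the cell is void (low quality) |
| `min_coverage` | 10 reads | site scorability |
| het AAF band | 0.10–0.90 | monogenic het call; WGA skews real hets to AAF ≥ 0.87, so a narrower band would miscall them |
| `same_group_max_dist` | 1 | concise types merging as amplification artifacts |
| `novelty_min_dist` | 2 | haplotype distance that counts as a genuinely new (fetal) haplotype |
| `calling_fraction` | 0.10 | read fraction for a called haplotype |

The two fraction thresholds (5% calling, 10% informative-scoring) are
deliberately distinct config fields: they play different roles and both
values are used by the workflow this package implements.

The `min_comparable_snps = 20` gate encodes the practice of voiding cells
with too few comparable sites (a 2-SNP difference in fewer than 20
comparable SNPs is low-quality evidence, not a fetal call); it is a
configurable quality gate rather than a hard rule of the assay.

## Numerical and algorithmic choices

- **Alignment.** The panel is tiny, so instead of a genome-scale aligner
  the package shortlists candidate amplicons by exact 15-mer seeding and
  scores each candidate by edit-distance path alignment (edlib, infix
  mode, both orientations, N as free wildcard), emitting a CIGAR over
  amplicon coordinates. Padded (15-N) joins of long amplicons are aligned
  arm-by-arm and recombined as `...M 15I gD ...M`, so the pad and the
  uncovered amplicon middle cost nothing — the moral equivalent of an
  aligner tuned to tolerate a large internal gap. A read maps when its
  edit distance is ≤ 15% of its non-pad length. External SAM from any
  aligner is accepted as an alternative input path.
- **Stitching.** Overlap merge requires ≥ 10 bp overlap with ≤ 10%
  mismatches, taking the higher-quality base at disagreements. These PEAR-
  style parameters are conservative choices, exposed in the function
  signature.
- **Pileup.** Bases below Q13, N/pad bases, and reads whose alignment has
  a deletion spanning the site are excluded from allele fractions; the
  deletion-spanning reads are tallied in a `masked` bucket so depth
  accounting stays visible. Indels are *not* masked for deletion-type
  disease variants, where the spanning-read CIGAR is the genotype signal.
- **Haplotype grouping.** Distances are integer Levenshtein with `-`
  (missing data) and N free as substitutions — an uncovered arm cannot
  inflate distance — computed by edlib with a textbook DP as the test
  oracle. Types are visited in descending count order; a type merges into
  a group when it is within distance 1 of exactly one representative. A
  type equally close to two groups is left as its own minor group: merging
  it into either would silently hide exactly the artifact the fraction
  tiers are meant to expose. Ties anywhere break lexicographically, so
  grouping is deterministic. A read-count-weighted mean pairwise distance
  is reported per group as a diagnostic (tight artifact groups sit well
  below 1). The reported per-group fraction uses all tallied reads as
  denominator, so fractions sum to ≤ 1 after top-10 truncation.
- **Distance-1 novelty.** A cell haplotype at distance 1 from a maternal
  haplotype is treated as an amplification artifact (uninformative) by
  default, consistent with merging 1-nt neighbours. A mock worked example
  in the source literature scores such a haplotype informative; both
  behaviours are reachable (`novelty_min_dist=1`), but the default keeps
  the artifact interpretation because it is the conservative one.
- **Rounding.** Printed percentages round half-away-from-zero at one
  decimal (the convention of the outcome and contingency tables, e.g.
  103/152 → 67.8); the cell-level ≥ 2-informative-SNP fraction truncates
  (408/518 → 78.7), mirroring the convention its printed value follows.
  The two helpers live in `util` and are used where each table style
  demands.
- **Degenerate inputs.** Zero comparable sites voids a comparison; zero
  reads gives an empty haplotype set; an empty contingency evaluation
  raises; consensus with no passing calls is an explicit no-call.

## The simulator

The generator's defaults are the study conditions: 152 cases, 3–10 cells
per case, 10% maternal-cell pickup, panel MAFs drawn 0.30–0.50 ("very
informative" SNPs), allele dropout 0.15, locus dropout 0.10 per amplicon
per cell (the workflow reports per-amplicon dropout as significant but
unquantified; 0.10 is this package's choice), negative-binomial depth
(mean 100, dispersion 3) with per-amplicon lognormal bias, maternal gDNA
at 4× cell depth, and error rates pre-WGA 1e-4, WGA-stage 0.005 (fraction
band 0.05–0.20) and PCR 0.002 per site per read. Haplotype regions draw
parental haplotypes from a 6-haplotype pool so that multi-site diversity
and Mendelian inheritance are both real.

The WGA product of a cell is drawn **once** (dropout events, pre-WGA and
WGA-stage errors), and two readout channels sample from it: per-site base
counts (fast; used for cohort-scale work) and literal 2×76 FASTQ pairs
(exercising stitching, alignment and pileup). The channels agree in
distribution but are sampled independently.

What the simulator does *not* model: WGA allelic imbalance short of
dropout (real het AAFs spread widely; here non-dropout hets are binomial
around 0.5), chimeric reads, primer artifacts, doublet cells (an optional
mode mixes two genomes, off by default since no doublet statistics exist
to calibrate it), quality-score error profiles, and CNVs/aneuploidy.
Consequently a passing simulated cohort demonstrates the pipeline's logic
and its behaviour under the *modelled* artifact rates — simulated
sensitivity (~99% at default rates) exceeds what heterogeneous real
cells yield (~91%), and that gap is expected, not a defect.

## Problem sizes used in the test suite and acceptance script

The acceptance script simulates the full 152-case cohort through the
counts channel (~1,000 cells; a few seconds). Read-channel tests use
small cohorts (single families, depth 4–80) because per-read stitching
and alignment in pure Python is the slow path; the fidelity properties
they check are size-independent. Dropout-rate recovery uses 1,500
known-het observations, comfortably above the 1,000 the Wilson-interval
check requires.

## Known limitations

- The HLA-A panel row is internally inconsistent in the published
  coordinate table (start > stop and neither orientation matches the
  printed size); it is flagged, kept out of BED export, and its reference
  sequence is taken by length. The true interval is not recoverable.
- SNP-site offsets within amplicons are synthetic (the published table
  lists amplicons, not per-site coordinates); real coordinates can be
  supplied via a sites TSV.
- The intra-group "distance < 0.5" reported for haplotype groups in the
  source literature implies a frequency-weighted metric that is not
  documented; this package reports the count-weighted mean pairwise
  distance as its diagnostic instead of guessing the original formula.
- Alignment is panel-anchored; off-panel reads are simply unmapped, and
  no duplicate marking or base-quality recalibration is attempted.
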