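# ampdel

Focal deletions nested inside amplifications: calling, event timing, and
gene-dosage expression modelling.

## The problem

In several tumor types, a dosage-sensitive gene (think *BRD4* on
chromosome 19) sits inside broad amplicons driven by a nearby oncogene
(a *CCNE1*-like driver). Because high expression of the bystander gene is
toxic, tumors recurrently acquire small (< 100 kbp) **focal deletions**
nested inside the amplification, typically hitting the gene's
exon1–intron1 regulatory window. Detecting these events, ordering them in
time, and quantifying their effect on expression requires three analyses
that this package implements as a tested, reusable pipeline:

1. **Focal-deletion calling** from copy-number segments and SV junctions.
   A segment-level (`scna`) call is a run of segments at least
   δ = 0.5 copies below both flanks, with a breakpoint within 50 kbp of
   the locus and an event span < 100 kbp. When the segment caller missed
   the event, a **read-depth rescue** pathway calls it from a
   deletion-consistent junction pair (lower breakend `+`, upper `-`)
   bounding a ≥ 20% drop in 200-bp tumor/normal depth ratio whose step
   locations match the breakends. Copy loss relative to a neighbor gene
   (`relative_loss`) is reported separately and excluded from the carrier
   set. Amplification status is any overlapping segment with total copy
   number > 2.
2. **Event timing** from allelic copy number. With total and minor-allele
   copy number, the amplified haplotype's state inside the deletion is
   decisive: loss of heterozygosity on an otherwise amplified allele ⇒
   the deletion came first; a non-zero reduced copy number ⇒ the
   amplification came first; deletions on the other allele, below allelic
   resolution, or on a uniparental-disomy background are ambiguous.
   Enrichment for one order among n informative carriers is tested with a
   one-sided exact binomial tail at p = ½:
   P(X ≥ max(a, b)), X ~ Bin(a + b, ½), computed by integer summation.
   For 11 amplification-first vs 2 deletion-first this is
   92/8192 ≈ 0.0112.
3. **Dosage modelling.** OLS of FPKM ~ copy number + focal-deletion
   status + tumor type (reference level "Other", per-patient means before
   fitting, t-based 95% CIs); copy-number-adjusted expression
   (FPKM × 2 / CN of the neighbor gene); a per-gene differential
   expression stage on log2(FPKM+1) with Bonferroni q < 0.1 and ≥ 2-fold
   change gates; and ORF-screen log2 fold-change utilities with a paired
   t test between isoform constructs.

Because the cohorts these methods were designed for are access-controlled,
the package ships a **synthetic cohort generator** (`ampdel.simulate`)
that emulates their statistical structure — a driver locus, a target gene
with an exon1–intron1 deletion window, a neighbor gene for normalization,
two-tier amplicons, deletion-consistent junctions, negative-binomial
200-bp depth bins, and a linear expression model (ovarian offset 26.1
FPKM, 3.6 FPKM per copy, −6.3 FPKM for deletion carriers) — together with
a ground-truth ledger that every caller and classifier is tested against.

## Worked example

```sh
ampdel run-all --seed 7 --n-samples 200 --out runs/demo
```

prints (and writes to `runs/demo/report.txt`):

```
samples simulated: 200
focal-deletion carriers: 36 (scna 24, rescued 12; relative-loss calls, non-focal: 0)
timing: 12 amplification-first vs 2 deletion-first of 14 informative (p = 0.00647, one-sided binomial, direction amp_first)
dosage model (FPKM): copy_number = 4.06 [3.17, 4.95], focal_deletion = -6.82 [-8.63, -5], intercept = 8.02 [5.35, 10.7], tumor_type[BRCA] = 11.5 [9.5, 13.4], tumor_type[OV] = 24.5 [22.8, 26.3], tumor_type[UCEC] = 9.16 [7.13, 11.2]
differential expression: pass list ['CCNE1L']
```

Reading this: of 200 simulated tumors, 36 carry a focal deletion at the
target gene — 24 found from segments alone and 12 rescued from read
depth + junction orientation. Among carriers with allelic information,
amplification-first histories dominate (12 vs 2; exact one-sided binomial
p = 0.006). The fitted dosage model recovers the generative coefficients
within their confidence intervals (copy number 4.06 ≈ 3.6, deletion
−6.82 ≈ −6.3, ovarian offset 24.5 ≈ 26.1), and the driver-gene analog is
the one differentially expressed gene between carriers and non-carriers,
as expected when deletions concentrate in driver-amplified genomes.

The run directory also contains `segments.seg`, `junctions.bedpe`,
`depth/<sample>.bedgraph`, `expression.tsv`, `metadata.tsv`,
`truth.json`, `calls.tsv`, `timing.tsv`, `fit.json`, `de.tsv` and a
`manifest.json` recording the config hash, seed and parameters; a rerun
with the same config and seed reproduces the stage outputs byte for
byte. Each stage is also available as its own subcommand
(`simulate`, `call-deletions`, `time-events`, `model`, `de`, `report`)
operating on the same plain-text formats, and as library functions.

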