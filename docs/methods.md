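# Methods

## Scope and data model

All logic is locus-relative, so the synthetic genome is a single
chromosome (`chrS`, 5 Mbp) carrying three named loci:

| locus | role | coordinates |
|---|---|---|
| `CCNE1L` | driver oncogene analog | 2,000,000–2,035,000 |
| `BRD4L` | dosage-sensitive target | 3,000,000–3,092,000 (deletion window 3,005,000–3,085,000, the exon1–intron1 analog) |
| `NOTCH3L` | neighbor gene used for copy-number normalization | 3,150,000–3,200,000 |

Coordinates are 0-based half-open everywhere. Copy-number segments carry
total and minor-allele (lesser haplotype) copy number; SV breakends carry
an orientation where `+` means the retained fragment lies at lower
coordinates. A junction is *deletion-consistent* when its lower breakend
is `+` and its higher breakend `-` on one chromosome — both ends point
outward from the lost interval. This operationalizes the otherwise
informal notion of "outgoing" breakpoint orientations.

## Synthetic cohort generator

Each sample draws a tumor type (`BRCA` 0.25, `OV` 0.35, `UCEC` 0.20,
`Other` 0.20 — an ovarian/breast/endometrial-enriched mix, since those
are the types in which the phenomenon concentrates), then:

* **Amplification** with probability 0.4, spanning driver, target and
  neighbor (1.9–3.4 Mbp). The amplicon is two-tiered: a driver peak
  (copy number uniform on 3–10, consistent with driver copy numbers
  around 6–7 in carriers) and a lower shoulder across the
  target/neighbor pair (uniform on 3–4, consistent with neighbor-gene
  copy numbers around 3.3 in carriers). The peak never falls below the
  shoulder. One haplotype carries all extra copies; the other stays at 1.
* **Focal deletion** with probability 0.5 given an amplification and
  0.02 otherwise, length uniform on 5–60 kbp, placed uniformly inside the
  deletion window. The deletion removes one copy-unit from one haplotype:
  with probability 0.8 it hits the amplified haplotype. When both events
  occur, the deletion precedes the amplification with probability 0.15
  (close to the 2/13 informative deletion-first fraction such cohorts
  show). Order determines the allelic state inside the deletion:
  amplification-first leaves the amplified haplotype at one copy less
  than its flank (non-zero); deletion-first propagates the deletion
  through every amplified copy, leaving that haplotype at zero (LOH).
  Deletions on the unamplified haplotype produce the same allelic
  pattern under either order and are recorded as uninformative.
* **Segment-call dropout**: with probability 0.25 a planted deletion is
  omitted from the emitted segment table (the fraction of carriers that
  real segment-level callers miss is about 6/22). Its junctions and its
  read-depth footprint are still emitted — the rescue scenario.
* **Read depth**: tumor/normal ratios over 200-bp bins across
  2.9–3.3 Mbp. Bin counts are negative-binomial with mean
  coverage · CN/2 (coverage 100 reads/bin, dispersion size 20;
  `inf` gives the Poisson limit). Dispersion is a free realism knob, not
  a claim about any particular dataset. Purity is 1.0 by default with an
  optional mixing parameter, since consensus copy-number inputs are
  purity-corrected.
* **Expression**: target FPKM = max(0, baseline(type) + 3.6 · CN −
  6.3 · 1{deletion} + N(0, 5)). Baselines are Other 8.0, OV 34.1
  (= 8.0 + the 26.1 ovarian offset), BRCA 20.0, UCEC 17.0; the non-ovarian
  offsets are invented since only the ovarian coefficient is published.
  CN is the true mean copy number across the target gene. Isoform rows
  split the gene value 70/25/5% into long, short-a and short-b
  transcripts, keeping the secondary short isoform far below the dominant
  one. Neighbor and driver genes follow simple dosage models
  (5 + 1.5 · CN and 4 + 2.5 · CN) so co-expression structure exists.

The truth ledger records, per sample, the planted intervals, copy
numbers, generative order, affected haplotype, dropout flag, true locus
copy numbers, the noiseless expression mean, and whether the history is
informative for timing (and if not, why). Everything is reconstructible
from (config, seed); identical configs give byte-identical outputs.

### What the generator does not emulate

No subclonality, germline variation, chromothripsis/BFB rearrangement
grammars, read-level data, or mappability/GC structure in depth. Passing
tests therefore demonstrate the correctness of the calling/timing/model
logic under idealized segment boundaries and stationary noise — not
performance on real tumor genomes, where segmentation error and impurity
dominate.

## Caller

`locus_cn` is the overlap-weighted mean of total copy number across a
locus (uncovered bases excluded; no coverage → missing). `is_amplified`
is true iff any overlapping segment has total CN strictly above 2,
irrespective of a concomitant deletion.

Segment-level events are maximal runs of segments at least
`rel_loss_delta` (0.5) copies below **both** flanking segments — the
quantitative stand-in for "relative copy-loss", which published analyses
left partly to manual review. Nested qualifying runs are each reported;
carrier status is per-sample. A run becomes an `scna` call when its span
is < 100 kbp, it overlaps the locus, and a boundary lies within 50 kbp of
the nearer locus edge.

The rescue pathway automates manual review of depth plots with explicit
thresholds. For each deletion-consistent junction bounding a < 100 kbp
interval that overlaps the locus window: the mean depth ratio inside must
be ≤ (1 − 0.2) × the mean over 50-kbp flanks (other candidate intervals
excluded from the baseline), and each breakend must pass a step-location
test. The step test fits a one-step piecewise-constant model to the bins
within ±10 kbp of the breakend (clipped at the opposite breakend so only
one true step can be in window) and accepts when the best changepoint
within `junction_match_bp` (1 kbp) of the breakend has a residual sum of
squares within 10 residual-variance units of the unconstrained best — a
likelihood-ratio location test. The slack absorbs the multi-bin jitter of
the argmax under counting noise (the raw argmax misses a true step by
> 5 bins a few percent of the time at one-copy drops on a 4-copy
background) while still rejecting drops whose boundaries sit more than
roughly a kilobase beyond the matching window; a noiseless fixture shifted
by 5 kbp is rejected. Rescued calls are only emitted for intervals without
an overlapping `scna` call, so evidence classes partition.

Relative loss (target CN ≤ neighbor CN − 0.5) is computed for samples
without a focal call, flagged non-focal, and excluded from the carrier
set used by downstream statistics.

## Event timing

Timing needs flank and inside allelic states. Flanks are the segments
covering the base immediately outside each deletion boundary (for
dropout samples this is the segment spanning the deletion, which
correctly yields "below allelic resolution"). If the two flanks disagree
the one overlapping the amplification more wins; an exact tie is
ambiguous. The amplified haplotype is the flank major allele
(flank CN > 1). With allelic tolerance 0.3 copies (the minimal
"discernible" difference, exposed as a parameter):

* inside total ≈ flank total → ambiguous, below allelic resolution;
* flank major ≈ flank minor, both > 1 → ambiguous, uniparental-disomy-like
  (the published analyses treated one such sample as a per-sample
  judgment call; no rule is encoded here);
* inside major ≈ flank major with minor reduced → ambiguous, different
  alleles;
* otherwise the amplified-haplotype CN inside is total − flank minor:
  ≈ 0 → deletion first (LOH on the amplified allele); strictly between 0
  and the flank value → amplification first.

Missing minor CN is ambiguous, not an error; an uncovered deletion
interval is an error. The enrichment test is the one-sided exact binomial
tail in the direction of the observed majority, by integer summation of
binomial coefficients. One-sided is the deliberate choice because the
worked 11-vs-2 example yields 0.0112 one-sided (rounding to the printed
0.01) versus 0.0225 two-sided; the summary records the sidedness and
direction.

## Statistics

* **Rank-sum**: exact enumeration of all C(n, n1) assignments (midranks,
  two-sided tail by distance from the null mean) for combined n ≤ 12 —
  at that size 924 subsets, microseconds — and a normal approximation
  with tie and continuity corrections above. Both paths are checked
  against brute-force enumeration and scipy.
* **Fisher**: two-sided by enumerating the hypergeometric support and
  summing probabilities ≤ the observed table's (relative tolerance 1e-9
  against rounding), odds ratio with Haldane 0.5 continuity only when a
  margin is zero (flagged).
* **CN-adjusted expression** multiplies by 2/CN(neighbor) rather than
  1/CN so adjusted and unadjusted values share units and diploid samples
  are unchanged; the neighbor gene supplies CN because the target's own
  CN is variable by definition in carriers.
* **Dosage model**: statsmodels OLS with explicit treatment coding
  (reference "Other"), per-patient collapsing before fitting (mean
  expression and CN, any-deletion, first tumor type), t-based 95% CIs.
  Rank-deficient designs raise an error naming the collinear columns.
* **Differential expression**: per-gene OLS on log2(FPKM + 1) with
  carrier status and tumor-type dummies, vectorized across genes via a
  shared design matrix. Bonferroni q = min(1, p · n_genes); pass requires
  q < 0.1 and |log2FC| ≥ 1 (the carrier coefficient). This is a plain
  fixed-effects stage: empirical-Bayes moderation and precision weights
  are deliberately out of scope, and planted-signal recovery — not
  numerical equivalence with moderated pipelines — is the test surface.
  Zero-variance genes get p = 1 and never pass.
* **ORF utilities**: log2((late + pc)/(early + pc)) with negative values
  meaning toxicity, and a paired two-tailed t test across cell lines for
  the isoform comparison.

## Problem sizes and determinism

Default verification runs use cohorts of 200 samples (caller recovery),
twelve 50-sample all-carrier cohorts (~600 timing histories), a
1000-sample cohort with 200 expression replicates (CI coverage), > 1000
enumeration cases for the exact tests, and a 2000-gene matrix with 100
label permutations (differential expression) — sizes at which every
stochastic check is stable across seeds while the whole suite runs in
seconds. One master seed drives everything through spawned
sub-sequences; all stage outputs and the acceptance JSON are
reproducible given (config, seed).

## Known limitations

The rescue thresholds (drop fraction, flank width, match distance, LR
slack) are design decisions, not reconstructions of any manual-review
protocol. The timing classifier assumes one amplification and at most
one nested deletion per sample; multi-event histories are out of scope.
The depth model has no positional covariates, so the step test's
calibration on real data would need re-examination. Whether the 50-kbp
proximity window should also gate SV breakends (it gates segment
boundaries here, with junctions used as corroborating evidence) is
ambiguous in the source analyses; the caller applies it to segment
boundaries only.
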