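# Methods

This note documents the statistical procedures, parameter defaults, and
design decisions behind each stage, and what the synthetic-data
generators do and do not emulate.

## Microsatellite instability

**Evidence model.** The unit of evidence is a per-locus histogram of
microsatellite repeat lengths observed in reads that span the repeat
with sufficient flanking sequence (5 bp; the upstream extractor is out
of scope, so profiles carry a `flank_ok` flag). A locus enters the
analysis only with ≥30 reads in the tumor and — in paired mode — ≥30 in
the normal (`msi_min_locus_reads`). At least 20 usable loci
(`msi_min_loci`) are required for any call; below that the result is
`QC_FAIL` with no probability, a deliberate distinct status.

**Per-locus test.** Tumor and normal histograms are compared with a
two-sample Kolmogorov–Smirnov statistic on read-weighted empirical
CDFs. Repeat-length data are massively tied (a histogram typically has
5–10 distinct lengths for hundreds of reads), and the continuous-sample
asymptotic null distribution is badly conservative there — in our
measurements the asymptotic p-value can exceed the permutation p-value
by 0.3–0.4 in the mid-range. The p-value is therefore computed
**exactly** under the permutation null: over all relabelings of the
pooled reads, the probability that the maximum ECDF gap reaches the
observed D. A ballot-path dynamic program over length bins (states =
cumulative tumor-read count; transition weights = binomial coefficients
per bin; states whose prefix gap reaches D are pruned; complement at
the end) computes this in O(bins × reads × bin-size) floating-point
work with running renormalization — about a millisecond per locus at
400 pooled reads — and is fully deterministic. A locus is unstable at
p ≤ 0.05 (`msi_locus_p_cutoff`).

**Classification.** Paired mode: the fraction of usable loci that are
unstable feeds a univariate logistic model (maximum-likelihood fit,
no regularization, tolerance 1e-8); its output probability is banded
as MSI-H (> 0.70), MSE (0.30–0.70, boundaries inclusive — the
conservative, equivocal class), MSS (< 0.30). Tumor-only mode:
per-locus read-weighted mean and variance of repeat length, ordered by
a fixed panel layout, scored by a linear-kernel SVM with sigmoid (Platt)
calibration fitted on held-out folds (`CalibratedClassifierCV`,
`ensemble=False`, 5 folds); the stored model is just the hyperplane and
the (A, B) sigmoid, so scoring needs no fitted estimator object.
Unusable/missing loci are imputed with training-cohort per-locus mean
features, keeping the feature length fixed.

**Training data.** Clinical training cohorts are not redistributable,
so shipped models are trained on the synthetic cohort (balanced
MSI-H/MSS at full purity, 40–50 per class) under a fixed seed;
`oncopanel msi train` reproduces them. The logistic slope is checked
positive, making the paired-mode probability monotone in the unstable
proportion.

## Tumor mutational burden

TMB = n / `panel_megabases`, where n counts variants that are somatic,
non-silent coding ({missense, nonsense, stop_loss, frameshift_indel,
inframe_indel} — a closed reading of "non-silent, including missense,
indel and stop-loss"; splice-region variants are excluded), with depth
strictly >100× and VAF strictly >5%. TMB is high iff strictly >9/Mb.
All three boundary inequalities are strict, matching the printed
symbols. Multi-nucleotide substitutions count once per record.

Threshold calibration: for each candidate t, the enrichment of MSI-H
among samples with TMB > t is the upper-tail hypergeometric
P[X ≥ k] (k MSI-H above t, n samples above t, K MSI-H total, N total),
computed by exact log-space summation of the PMF. The calibrated
threshold minimizes p, ties broken toward the smaller threshold; a
candidate with no samples above it scores p = 1.

## Copy number

**Log ratios.** Tumor and comparator (matched normal, or pooled-normal
depths in tumor-only mode) are scaled to equal totals, ratioed per
target, log2-transformed and median-centered. Optional GC correction
(off by default in matched-normal mode, where probe effects mostly
cancel) subtracts per-GC-decile medians. Targets with zero comparator
depth are dropped with a warning.

**Segmentation.** Circular binary segmentation: the arc maximizing the
circular two-sample t-statistic is accepted as a split when its
permutation p-value (seeded, default 10 000 permutations, α = 0.01) is
below α, recursing until no split is accepted; adjacent segments whose
means differ by <0.1 log2 units are re-merged. The permutation loop
early-stops once enough exceedances have accumulated that the final
p-value is guaranteed above α — a pure speed optimization that changes
no accept/reject decision. Minimum arc and complement width is 2
targets. The statistic is shift-invariant, so segment boundaries are
equivariant under adding a constant to all log ratios.

**Purity/ploidy fit.** Candidate grid: purity 0.05–1.00 step 0.01 ×
ploidy 1.5–5.0 step 0.1. For each candidate the expected segment ratio
for copy number c is (p·c + 2(1−p))/(p·ψ + 2(1−p)); expected BAF
deviation |f − ½| enumerates allelic configurations a ∈ {0..c} with
f = (p·a + (1−p))/(p·c + 2(1−p)). Goodness of fit is the
target-weighted squared distance of each segment's observed
(ratio, mean BAF deviation) to its nearest integer state (BAF weight
1.0; segments without overlapping het SNVs contribute ratio distance
only). The penalty is 0.1·|ψ−2| + 0.1·(distance of the fitted
genome-wide ploidy from the nearest integer) + 0.002·(weighted mean
|c−2|). The fitted genome-wide ploidy is the **target-weighted median**
assigned copy number: a weighted mean is non-integer whenever any focal
event exists and would mis-penalize correct fits, while the median is
robust to focal events and still rewards internally consistent
genome-doubled solutions. The aberration term breaks an intrinsic
degeneracy — a lone amplification constrains only p·(c−2), so
(p=0.6, c=4) and (p=0.3, c=6) explain the same ratio and the same BAF
deviation exactly — in favor of the more parsimonious (higher-purity,
lower-CN) reading. Exact score ties resolve toward ψ = 2, then higher
purity. With a diploid genome the purity is unidentifiable by
construction (every state is c = 2 at ratio 1 for any p); the penalty
then selects the ψ = 2 fit.

Purity is genuinely identifiable only when the genome contains events
whose ratio/BAF response is nonlinear in purity — in practice a
deletion or LOH block. The recovery simulations therefore use a
specimen with an arm-scale CN-1 loss plus focal CN-4 and CN-6
amplifications, which is also the typical constellation of the tumors
such assays validate against.

**Calls.** Integer CN per segment is the c minimizing |observed −
expected ratio| under the fit (ties to the smaller c). Focal
amplification: gene-level copy ratio ≥ 2.5 (`amplification_ratio`,
boundary inclusive). Arm events: loss/gain when ≥80%
(`arm_event_fraction`) of the arm's covered length is below/above CN 2.

## Fusions

Candidates (BEDPE with split/discordant read counts) pass the evidence
filter with total support ≥ 5 including ≥1 split read
(`fusion_min_support`; the threshold is configurable — the clinical
reporting threshold it mirrors is not published). Reportable-range
filtering intersects either breakpoint end with a BED of reportable
regions, half-open.

**Breakpoint placement.** Walking from the genomic breakpoint in the
direction of transcription — reversed for the inverted partner of an
inversion — the junction snaps to the boundary adjacent to the next
exon. The 5′ partner retains exons wholly upstream of the junction (in
the walking direction), the 3′ partner exons wholly downstream; a
breakpoint exactly on an exon boundary therefore resolves to the
intron side, keeping retention whole-exon. A 5′ breakpoint upstream of
every exon retains only the promoter (TMPRSS2–ERG-style promoter
swap). One designated (canonical) transcript per gene is annotated;
multi-isoform enumeration is out of scope.

**Chimeric product.** The fused CDS concatenates each partner's
retained coding sequence in its native reading orientation (inversion
changes which exons are retained, not how their sequence reads — a
productive inversion fusion transcribes both pieces 5′→3′). The
product is in frame iff the 5′ coding length is congruent mod 3 with
the CDS offset where the 3′ contribution begins, i.e. the 3′ partner
is read in its native frame; otherwise translation proceeds in the
shifted frame to the first stop. Promoter-swap products are the 3′
partner's intact native ORF. Domains are retained only when wholly
inside a partner's contributed region (junction-straddling domains are
ambiguous and dropped); out-of-frame products retain no 3′ domains
since the downstream peptide diverges from the native sequence.

**RNA normalization.** Genes are binned by GC and length deciles;
within each sample a full-quantile step maps every bin's value
distribution onto the mean quantile curve across bins (empirical
quantile functions interpolated at (r+½)/m; a single bin makes the
step an exact identity), then DESeq-style size factors (per-sample
median of ratios to the gene-wise geometric mean over genes expressed
in all samples) remove sequencing depth.

## Neoantigens

All windows of lengths 8–11 overlapping ≥1 mutated residue are
enumerated, clipped to the protein, de-duplicated by sequence. For
frameshift/stop-loss variants every novel residue counts as mutated.
Alleles unsupported by the affinity predictor fall back to the
supported allele with minimal global edit distance between
binding-domain amino-acid sequences (ties lexicographic). A mutation
is antigenic iff min over peptide×allele of predicted affinity is
strictly <500 nM (`affinity_cutoff_nm`). The repository ships only a
deterministic hash-based toy predictor mapping (peptide, allele) to
[1, 50000] nM — a synthetic stand-in carrying no biochemical
information, which keeps the determination logic testable and
download-free; real predictors plug in as a callable. HLA accuracy
bookkeeping compares allele names truncated to one field (two-digit)
or two fields (four-digit).

## Expression silencing

A gene (MLH1 being the motivating case) is flagged transcriptionally
silenced when its normalized expression falls below the 5th percentile
(`expression_percentile`, linear interpolation between order
statistics) of reference-labeled (default MSS) cohort samples; at
least two reference samples are required. The rule is an invented,
prominently configurable operationalization of "reduced RNA
expression" — no published rule exists to reproduce.

## Validation metrics

Sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp) are
kept as exact `Fraction`s and displayed as percentages rounded half-up
to one decimal; fractions above 99.9% display as ">99.9%". (Printed
clinical summaries sometimes mix rounding conventions — e.g. 347/349
is 99.4% at one decimal though it has been printed as 99.5% — which is
why the exact fraction always accompanies the percentage.) Dilution
series: expected VAFs halve exactly per 1:1 dilution step; the LOD is
the smallest expected VAF with consistent detection from the top of
the series; a least-squares line of observed vs expected VAF
quantifies linearity. Coverage uniformity: fraction of targeted
positions at ≥300× (`uniformity_depth`), passing at ≥95%
(`uniformity_fraction`), both inclusive ("minimum depth" implies
attainment).

## Synthetic data: what it does and does not emulate

Generators are pure functions of an explicit NumPy `default_rng` seed;
no global RNG state; identical output across runs and platforms.

- *MSI profiles*: normal reads = reference repeat count plus symmetric
  geometric stutter (default rate 0.10); MSI-H tumors shift affected
  loci (default 80% of the panel) down by 3 repeats with doubled
  stutter rate, admixed with normal process at 1−purity; read totals
  Poisson around depth 200. This captures what the KS caller consumes
  — distribution shift and broadening under admixture — but not
  locus-specific stutter profiles, PCR artifacts, or mapping bias.
- *Variant sets*: observed VAF is Binomial(depth, true VAF)/depth with
  Poisson depth; consequence classes from a fixed categorical mix.
  Serial dilution multiplies true VAFs by 2^−k and re-samples.
  No sequencing-error or strand-bias model, so LOD results reflect
  sampling noise only.
- *Coverage profiles*: tumor depth mean ∝ purity·CN/2 + (1−purity)
  with lognormal multiplicative noise (default σ = 0.03 at depth 500);
  het-SNV alt fractions binomial around the mixture expectation with
  the variant allele on 1 or CN−1 copies. Probe-affinity and
  GC-dependent coverage structure appears only when injected
  explicitly.
- *Fusion cases*: truth labels derive from direct interval arithmetic
  on the exon table, independent of the annotation walk, so placement
  tests are not circular. Toy transcripts use stop-free random codons
  (so chimeric ORFs terminate only at engineered stops) — real UTR
  structure, alternative isoforms and genomic repeat context are not
  modeled.

Consequently, passing tests demonstrate correctness of the
*computational* stages under their stated statistical assumptions, not
wet-lab assay performance on clinical specimens.

## Problem sizes and numerics

The test suite and acceptance script run at desk scale by design: MSI
accuracy over 100 simulated specimens per condition at depth 200; CNV
recovery over 20 seeds per purity (1.0, 0.6, 0.3) on 120-target
profiles with 1 000-permutation CBS; fusion placement over 100 cases;
the hypergeometric oracle enumerated exhaustively for N ≤ 12.
Tolerances: hypergeometric vs enumeration 1e-12 relative; KS p vs a
1e5-relabeling Monte-Carlo oracle ±0.02; purity recovery ±0.05; CBS
boundaries ±1 target of the exhaustive single-changepoint oracle.
Degenerate inputs are defined behavior: empty histograms, zero usable
loci, zero-denominator metrics and single-reference cohorts raise
typed errors; <4 targets yield a single trivial segment; empty peptide
sets are non-antigenic.

## Known limitations

- The MSI classifiers are trained on synthetic cohorts; coefficients
  will not match models trained on clinical specimens.
- Purity estimation reports a point estimate from a grid; no
  confidence measure, and sub-clonal copy number is out of scope.
- The CBS permutation test uses the max-t statistic without the
  overshoot correction some implementations apply to very long
  chromosomes; panels of a few hundred targets per chromosome are the
  intended regime.
- The fusion stage annotates one transcript per gene and assumes the
  supplied exon sequences; it does not discover SVs or validate them
  against reads.
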