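# Methods

## The inference chain

The package detects an "inhibitory effect" (IE) transcriptome across an
ordered allele-dosage genotype series (WT/WT → WT/null → WT/mutant).  The
biological hypothesis is that a dominant-negative missense p53 mutant
reduces WT p53 transcriptional output below what a simple null allele does,
so genes activated by WT p53 decrease monotonically along the series.  The
operational definition of the IE set: for each gene, ordinary least squares
of the three per-genotype means against x = (0, 1, 2); select genes with
slope < −1 and R² > 0.6, both strict, ranked by descending R² then |slope|.
R² is the primary ranking key; flat genes (zero variance of the three
means) are assigned slope 0, R² 0 and are excluded by construction.

### The trend scale

The slope threshold of 1 only has meaning relative to a scale.  Group
means of raw normalized counts have noise that grows with the mean
(SD ≈ √(μ/n) even at the Poisson floor), so a fixed absolute threshold
cannot separate a planted trend from sampling noise at any expression
level when groups have only 3 animals: a power analysis of the default
recovery scenario (50 genes planted at 3 units per step among 1,000)
shows that on the raw scale no negative-binomial regime reaches
recall ≥ 0.90 together with a false-positive rate ≤ 0.05 (the best
achievable is ≈ 0.88 recall at 6–10% FPR).  The default trend scale is
therefore **log2(group mean + 0.5)**: the slope is a log2 fold change per
allele step, the magnitude threshold 1 reads "at least 2-fold down per
step", and the group-mean noise is roughly variance-stabilized across
expression levels.  With this scale the same scenario is recovered at
recall 1.0 with FPR ≈ 0.  `scale="normalized"` (and the `trend_scale`
config key) reproduces the raw-count computation for users who want the
literal convention.

## Synthetic data: what it emulates, what it does not

`syndata` generates every input with recorded ground truth (`SimTruth`).

**Counts.**  Negative binomial, Var = μ + αμ², one shared dispersion α
(default 0.05, a typical bulk-RNA-seq scale; α < 1e−9 degenerates to
Poisson).  Defaults: 1,000 genes, three genotypes × 3 samples, base means
uniform on (50, 500), 5% IE genes planted with an equal log2 decrement of
3 per allele step (an 8-fold drop per step, geometric on the count scale,
floored at 0.1).  The planted trend is linear on the log2 scale on which
the selection operates; the decrement of 3 is deliberately strong — these
are recovery benchmarks for implementation correctness, not estimates of
biological effect sizes.

**Promoters.**  I.i.d. background DNA at GC 0.45 (nominally the 10 kb
window upstream of the TSS, TSS at the 3′ end); with probability 0.77
(IE genes) or 0.035 (background) one exact consensus instance of the PWM
is written at a uniform random offset and strand.  The planted rates are
the motif-positive fractions reported for the IE and random gene sets, so
the scanner should approximately reproduce those percentages on synthetic
data.  Real promoters are not i.i.d. (CpG islands, repeats, degenerate
motif instances, multiple sites); passing recovery tests shows the scanner
finds what was planted at the modeled background, not that real-genome hit
rates will match.

**Cohort.**  Per-animal Bernoulli lesion calls and exponential
time-to-event with administrative censoring; sexes alternate.  The default
design mirrors the two-null-allele comparison: n = 17 vs 11, hyperplasia
0.76 vs 0.55, adenoma/carcinoma 0.176 vs 0.45, exponential scales 879 and
1,020 days (medians near 609 and 707 days), censoring at day 800.
Exponential hazards are the simplest model sufficient to exercise KM and
log-rank; real tumor latency is not memoryless.

**Sanger peaks.**  WT peak = mutant peak × (1 − loss) + Gaussian noise
(default SD 10 on a 1,000-unit mutant peak, ~1% relative), negative draws
clamped at 0.  The default 19-tumor truth is the published breakdown
(13 none; partial 15/25/33/33/50%; 1 complete).

**Seeding.**  Every generator takes an explicit integer seed; the pipeline
fans one root seed into per-stage substreams via `SeedSequence.spawn`, so
reports are byte-identical across runs with the same config.

## Expression core

Size factors are the median-of-ratios estimator: factor_j = median over
genes of counts[g, j] / (geometric mean of gene g across samples), over
genes with no zero anywhere; all-zero genes are dropped first.  Factors
are *not* rescaled to product 1; consequently the estimator is equivariant,
not invariant, under depth changes — scaling one of m columns by c
multiplies its factor by c^((m−1)/m), the other factors by c^(−1/m), and
the whole normalized matrix by c^(1/m), leaving all relative expression
unchanged.  The tests assert exactly this equivariance.

The differential test is a deliberate simplification: Welch t on
log2(normalized + 0.5) per gene, BH adjustment, selection at |log2FC| ≥ 1
and q ≤ 0.05.  The dispersion-shrunk negative-binomial Wald machinery it
replaces pools information across genes and is substantially more powerful
at n = 3; every report this package writes states the substitution.  The
power cost is real: at the generator's default dispersion (0.05) a planted
4-fold change at n = 3 almost never reaches q ≤ 0.05 once BH corrects over
2,000 genes.  The DE recovery test therefore runs in a deep-coverage,
near-technical-noise regime (base means 200–2,000, dispersion 0.01, 10%
of genes planted) chosen by power analysis, where the ≥ 80% recovery
property meaningfully checks the implementation.  The IE trend selection —
the pipeline's primary statistic — consumes only normalized group means
and is unaffected by this choice.

ΔΔCt: fold = 2^−((Ct_t,case − Ct_ref,case) − (Ct_t,ctrl − Ct_ref,ctrl)).

## Motif scanning

A JASPAR PFM is converted with pseudocount 0.25 per cell to column
frequencies and log2-odds against a 0-order background, estimated from
the scanned promoter set with add-one smoothing (uniform fallback).
Scanning evaluates every window on both strands (the reverse strand via
the reverse-complemented matrix); `N` bases contribute 0 log-odds
(background-equivalent).  Ties resolve to the smallest offset, then the
+ strand; note the bundled consensus is palindromic, so +/− at the same
offset are exact ties up to float summation order.

Match significance is exact under a discretized score model: column
log-odds are rounded to multiples of the granularity (default 0.01 bits)
and the distribution of the window score under the background is built by
per-column convolution, so p_window = P(score ≥ s) involves no Gaussian or
extreme-value approximation (the discretization perturbs scores by at most
granularity × width / 2).  Per sequence, p_seq = 1 − (1 − p_window)^n with
n = 2(L − W + 1) windows treated as independent, and E = p_seq × N
sequences in the scanned set — the convention used by MAST-style per-
sequence E-values, stated here so users can compare with MEME-suite
output.  A promoter is motif-positive at E ≤ threshold (default 10).
Because E scales with N, the implied per-sequence p cutoff (and hence the
background false-hit rate, ≈ threshold/N) depends on how many sequences
are scanned together, exactly as in MAST runs.

The bundled matrix (`MA0106.3-like`, `data/p53_re_synthetic.jaspar`) is a
synthetic stand-in for the JASPAR p53 entry: two RRRCWWGYYY half-site
decamers with realistic degeneracy (information content ≈ 1.5 bits/column).
Any genuine JASPAR text matrix drops in via the `pwm` config path; the
code path is identical.

Enrichment: motif-positive fraction among IE promoters vs an equal-size
random draw (without replacement, seeded) from the non-IE universe;
two-sided Fisher exact on the 2×2 hit table.  The random control defaults
to a single draw (matching the published design); `n_draws > 1` pools hit
counts over draws.

## Cohort statistics

Incidence is count/n with the field's mixed rounding (integer headline,
one decimal elsewhere); the helpers return the unrounded percent.  Fisher
exact is two-sided by the point-probability rule (scipy's convention; the
tests verify it cell-by-cell against exhaustive hypergeometric enumeration
for every table with margins ≤ 30).  KM/log-rank use lifelines, with the
standard hypergeometric variance at tied event times; the log-rank p is
checked against a label-permutation null on a worked 12-animal cohort.
The KM median is the earliest time with S(t) ≤ 0.5 (None if never
reached).

LOH from a WT/mutant Sanger peak pair: loss = 1 − WT/mutant, clamped to
[0, 1].  loss ≤ 0.10 → no LOH; WT ≤ 0.10 × mutant → complete; otherwise
partial with the loss rounded to the nearest percent.  "Peak height
similar" is interpreted as a 10% relative tolerance (the criteria as
stated give none); a zero mutant peak is an assay failure, not LOH.
The classifier is monotone: lowering the WT peak never moves a call back
toward "none".

## Pre-ranked enrichment

Classic weighted running-sum statistic (weight exponent 1): genes ordered
by descending statistic (ties broken by gene id), hits advance the sum by
|stat|/Σ|stat in set|, misses retreat by 1/(#misses); ES is the maximum
deviation.  The null permutes set labels over the ranking (default 1,000
permutations, seeded); NES = ES / mean |null ES| of matching sign;
p = (1 + #{|null| ≥ |ES|}) / (1 + n_perm), so the floor is 1/(n_perm + 1).
A set equal to the whole ranking is rejected as degenerate.

## Numerical and degenerate-input conventions

- Flat trend profiles: slope 0, R² 0 (prevents 0/0, self-excluding).
- Log transforms use pseudocount 0.5; PFM parsing pseudocount 0.25.
- p_seq uses the log1p/expm1 formulation so p_window ≈ 1e−12 does not
  underflow across 20,000 windows.
- Size-factor computation refuses matrices with no gene positive in every
  sample (advising filtering) rather than returning zeros.
- BED output is 0-based half-open; promoter coordinates are record-local
  (the FASTA record is assumed to be the upstream window, TSS at 3′ end);
  the package never extracts promoters from a genome annotation.
- Fisher odds ratio ad/bc reports inf when bc = 0 with ad > 0, nan at 0/0.

## Problem sizes in the test and acceptance runs

Recovery and oracle checks run at: 1,000 random (sequence, PWM) pairs vs
the brute-force scanner oracle (W ≤ 8, L ≤ 300); full 4^W enumeration of
the p-value DP for W ≤ 6; all 2×2 tables with margins ≤ 30 against the
hypergeometric oracle; 100,000 label permutations for the log-rank check;
and the default 1,000-gene × 9-sample, 1,000 × 10 kb promoter scenario for
parameter recovery.  The whole suite and the acceptance script each run in
a few minutes on one CPU.

## Known limitations

- The Welch-t differential stage is underpowered at n = 3 relative to NB
  Wald tests (documented above); it is a supporting stage only.
- Window scores are treated as independent in p_seq; overlapping windows
  are positively dependent, so p_seq is slightly conservative for
  clustered or repetitive motifs.
- The promoter background model is 0-order; CpG structure and repeats in
  real promoters inflate false hits relative to the synthetic benchmark.
- Exponential survival and Bernoulli lesions ignore competing risks and
  within-animal correlation between lesion types.
- The LOH classifier assumes peak heights proportional to allele fraction;
  real chromatograms have sequence-context-dependent peak biases.
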