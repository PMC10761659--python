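# p53ie — allele-dosage inhibitory-effect transcriptome analysis

A missense p53 mutant co-expressed with a wild-type allele can suppress the
transcriptional output of the remaining WT protein (a dominant-negative
"inhibitory effect", IE).  In a liver-specific mouse model under metabolic
stress, this shows up as p53 target genes whose expression is highest in
WT/WT animals and falls progressively through WT/null to WT/mutant — an
allele-dosage series.  `p53ie` implements, as a tested and fully synthetic-
data-driven pipeline, the inference chain used to detect such an IE
transcriptome and to characterize the surrounding tumor biology:

1. **Expression core** — median-of-ratios size factors and normalization of
   a gene × sample count matrix; per-genotype group means; a lightweight
   two-group differential test (Welch t on log2(normalized + 0.5), BH
   adjustment, selection at |log2FC| ≥ 1 and q ≤ 0.05); ΔΔCt fold changes.
2. **IE trend selection** — per gene, ordinary least squares of the group
   means against the genotype coding x = 0, 1, 2; a gene joins the IE set
   when slope < −1 and R² > 0.6 (strict), ranked by descending R² then
   |slope|.  By default the fit is on log2(group mean + 0.5), so the slope
   is a log2 fold change per allele step.  A minimal pre-ranked running-sum
   enrichment statistic (permutation null) accompanies the selection.
3. **Promoter motif scanning** — JASPAR PFM parsing, log2-odds scanning of
   10 kb promoters on both strands, *exact* match p-values by dynamic
   programming over the discretized score distribution, MAST-style
   per-sequence E-values (E = p_seq × N sequences, hit at E ≤ 10), and an
   IE-vs-random-gene enrichment report with a two-sided Fisher exact test.
4. **Cohort statistics** — lesion incidence tables, Fisher exact 2×2,
   Kaplan–Meier curves and the log-rank (Mantel–Cox) test, and a Sanger
   peak-height LOH classifier (no / partial(f) / complete loss of the WT
   allele, with f = 1 − WT/mutant peak ratio).
5. **Synthetic data** — negative-binomial counts with planted monotone IE
   trends, promoters with motif instances planted at known rates, cohorts
   with genotype-dependent lesion probabilities and exponential survival,
   and Sanger peak pairs with planted loss fractions — all with recorded
   ground truth, so every stage is benchmarked against what was planted.

## Worked example

The five numbered scripts under `analysis/` run the whole chain on
synthetic data (each writes its tables under `results/`):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_expression.py
python analysis/03_ie_selection.py
python analysis/04_motif_enrichment.py --seed 1
python analysis/05_cohort_loh.py
```

Output of the IE and motif stages at seed 1:

```
IE selection: 50 of 1000 genes (slope < -1 log2/step, R^2 > 0.6)
vs planted truth: recall=1.00, false-positive rate=0.0000
scanned 1000 promoters with MA0106.3-like (width 20); 72 motif-positive at E <= 10
IE promoters: 43/50 motif-positive (86%)
random non-IE promoters: 2/50 (4.0%)
Fisher exact (two-sided): OR=147.4, p=4.01e-18
vs planted truth: consensus recall=1.00, background false-hit rate=0.007
```

Reading: all 50 genes planted with a decreasing dosage trend are recovered
with no false positives; the planted p53 response elements are found in
every promoter that received one, and the IE set is overwhelmingly enriched
for the motif relative to an equal-size random gene draw.  The cohort stage
prints incidence percentages, KM medians, the log-rank comparison, and the
LOH breakdown (e.g. `68% retained the WT allele` for the default 19-tumor
truth).

The same chain is available as a CLI over one YAML config:

```bash
p53ie all --seed 1 --out pipeline_out     # subcommands: simulate, normalize,
                                          # de, ie, scan, enrich, cohort, all
```

Fixed seeds give byte-identical `report.json` files.

The bundled PFM (`src/p53ie/data/p53_re_synthetic.jaspar`) is a *synthetic*
p53 response element matrix — two palindromic RRRCWWGYYY half sites —
constructed for tests; any JASPAR-format matrix (e.g. the genuine
Jaspar2022 p53 entry) can be supplied via the config instead.

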