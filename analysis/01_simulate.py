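"""Generate the synthetic study inputs with recorded ground truth.

Emulates the study design: bulk RNA-seq counts for an ordered p53
genotype series (3 samples per genotype), 10 kb promoter sequences with
p53 response elements planted at 77% in IE genes vs 3.5% elsewhere, a
two-genotype tumor-watch cohort, and WT/mutant Sanger peak pairs for 19
tumors.  Everything downstream (02-05) reads the files written here.

Usage: python analysis/01_simulate.py [--seed N] [--outdir DIR]
"""

import argparse
import pathlib

import numpy as np
from Bio import SeqIO

from p53ie import default_pwm, syndata
from p53ie.exprcore import write_counts
from p53ie.pipeline import DEFAULT_COHORT, DEFAULT_LOH_TRUTH


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/synthetic")
    args = ap.parse_args()
    out = pathlib.Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(args.seed).spawn(4)]

    pwm = default_pwm()
    cm, truth = syndata.simulate_counts(seed=seeds[0])
    write_counts(cm, out / "counts.tsv", out / "samples.tsv")
    print(f"counts: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples; "
          f"{len(truth.ie_gene_ids)} IE genes planted (3 log2 units down per allele step)")

    promoters, truth = syndata.simulate_promoters(
        cm.gene_ids, pwm=pwm, ie_genes=truth.ie_gene_ids, seed=seeds[1], truth=truth
    )
    SeqIO.write(promoters, out / "promoters.fasta", "fasta")
    n_ie_planted = len(truth.motif_bearing_genes & truth.ie_gene_ids)
    print(f"promoters: {len(promoters)} x 10 kb; motif planted in "
          f"{n_ie_planted}/{len(truth.ie_gene_ids)} IE genes and "
          f"{len(truth.motif_bearing_genes) - n_ie_planted} background genes")

    cohort = syndata.simulate_cohort(seed=seeds[2], **DEFAULT_COHORT)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    print(f"cohort: {len(cohort)} animals "
          f"({', '.join(f'{g} n={n}' for g, n in zip(DEFAULT_COHORT['genotypes'], DEFAULT_COHORT['n_per_genotype']))})")

    truth.loh_truth = list(DEFAULT_LOH_TRUTH)
    peaks = syndata.simulate_sanger_peaks(truth.loh_truth, noise_sd=10.0, seed=seeds[3])
    peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
    print(f"Sanger peaks: {len(peaks)} tumors "
          f"(13 none / 5 partial / 1 complete planted)")

    syndata.write_truth(truth, out / "truth.json")
    print(f"ground truth -> {out/'truth.json'}")


if __name__ == "__main__":
    main()
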