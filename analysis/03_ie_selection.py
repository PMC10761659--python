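"""Rank genes by allele-dosage trend and select the IE transcriptome.

For each gene: OLS slope and R^2 of log2(normalized group mean + 0.5)
against the genotype coding x = 0, 1, 2; selection at slope < -1 and
R^2 > 0.6 (strict), ranked by descending R^2 then |slope|.  With ground
truth available, reports recall and false-positive rate.

Usage: python analysis/03_ie_selection.py [--datadir DIR] [--outdir DIR]
"""

import argparse
import pathlib

from p53ie.exprcore import normalize, read_counts
from p53ie.ietrans import gene_trends, select_ie_genes, trends_table
from p53ie.syndata import read_truth


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", default="results/synthetic")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    data = pathlib.Path(args.datadir)
    out = pathlib.Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    cm = read_counts(data / "counts.tsv", data / "samples.tsv")
    nm = normalize(cm)
    order = list(dict.fromkeys(cm.sample_meta["genotype"]))
    trends = gene_trends(nm, order, scale="log2")
    selected = select_ie_genes(trends)
    trends_table(trends).to_csv(out / "trends.tsv", sep="\t")
    trends_table(selected).to_csv(out / "ie_genes.tsv", sep="\t")

    print(f"genotype series: {' -> '.join(order)} (x = 0, 1, 2)")
    print(f"IE selection: {len(selected)} of {len(trends)} genes "
          f"(slope < -1 log2/step, R^2 > 0.6)")
    print("top 5 by R^2:")
    for t in selected[:5]:
        print(f"  {t.gene_id}  slope={t.slope:+.2f}  R^2={t.r2:.4f}")

    truth_path = data / "truth.json"
    if truth_path.exists():
        truth = read_truth(truth_path)
        sel = {t.gene_id for t in selected}
        recall = len(sel & truth.ie_gene_ids) / len(truth.ie_gene_ids)
        fpr = len(sel - truth.ie_gene_ids) / (len(trends) - len(truth.ie_gene_ids))
        print(f"vs planted truth: recall={recall:.2f}, "
              f"false-positive rate={fpr:.4f}")


if __name__ == "__main__":
    main()
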