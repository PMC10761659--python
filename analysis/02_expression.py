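"""Normalize the count matrix and run the two-group differential test.

Median-of-ratios size factors, then a Welch t on log2(normalized + 0.5)
between the first and last genotype of the series, BH-adjusted, selecting
at |log2FC| >= 1 and q <= 0.05.  Writes results/size_factors.tsv and
results/de.tsv.

Usage: python analysis/02_expression.py [--datadir DIR] [--outdir DIR]
"""

import argparse
import pathlib

from p53ie.exprcore import DE_NOTE, differential_expression, normalize, read_counts


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
    nm.size_factors.to_csv(out / "size_factors.tsv", sep="\t")
    print("size factors:",
          ", ".join(f"{s}={f:.3f}" for s, f in nm.size_factors.items()))

    order = list(dict.fromkeys(cm.sample_meta["genotype"]))
    de = differential_expression(cm, order[0], order[-1])
    de.to_csv(out / "de.tsv", sep="\t")
    n_sel = int(de["selected"].sum())
    n_down = int((de["selected"] & (de["log2_fold_change"] < 0)).sum())
    print(f"{DE_NOTE}")
    print(f"DE {order[0]} vs {order[-1]}: {n_sel}/{len(de)} genes pass "
          f"|log2FC|>=1 and q<=0.05 ({n_down} down in {order[-1]})")


if __name__ == "__main__":
    main()
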