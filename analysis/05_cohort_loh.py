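"""Cohort outcome statistics and LOH calls.

Per-genotype lesion incidence (with a Fisher exact comparison), Kaplan-
Meier medians, the log-rank (Mantel-Cox) survival comparison, and LOH
classification of each tumor from its WT/mutant Sanger peak heights.

Usage: python analysis/05_cohort_loh.py [--datadir DIR] [--outdir DIR]
"""

import argparse
import json
import pathlib

import pandas as pd

from p53ie.cohortstats import (
    classify_loh_table,
    fisher_exact_2x2,
    incidence,
    km_curve,
    logrank_test,
    loh_summary,
    read_cohort,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", default="results/synthetic")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    data = pathlib.Path(args.datadir)
    out = pathlib.Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(data / "cohort.tsv")
    genos = list(dict.fromkeys(cohort["genotype"]))
    lesions = [c[len("lesion_"):] for c in cohort.columns if c.startswith("lesion_")]
    stats: dict = {"incidence": {}, "km": {}}

    for g in genos:
        stats["incidence"][g] = {}
        for lesion in lesions:
            k, n, pct = incidence(cohort, lesion, g)
            stats["incidence"][g][lesion] = {"count": k, "n": n, "percent": round(pct, 1)}
            print(f"{g}: {lesion} {k}/{n} ({pct:.1f}%)")
        sub = cohort[cohort["genotype"] == g]
        _, med = km_curve(sub["survival_days"], sub["event"])
        stats["km"][g] = {"n": int(len(sub)), "median_days": med}
        print(f"{g}: KM median {med if med is None else round(med)} days "
              f"({int(sub['event'].sum())} events / {len(sub)} animals)")

    if len(genos) >= 2:
        a = cohort[cohort["genotype"] == genos[0]]
        b = cohort[cohort["genotype"] == genos[-1]]
        chi2, p = logrank_test(a["survival_days"], a["event"],
                               b["survival_days"], b["event"])
        stats["logrank"] = {"groups": [genos[0], genos[-1]],
                            "chi_square": chi2, "p": p}
        print(f"log-rank {genos[0]} vs {genos[-1]}: chi2={chi2:.2f}, p={p:.3f}")
        for lesion in lesions:
            ka, na, _ = incidence(cohort, lesion, genos[0])
            kb, nb, _ = incidence(cohort, lesion, genos[-1])
            orr, fp = fisher_exact_2x2(ka, na - ka, kb, nb - kb)
            stats[f"fisher_{lesion}"] = {"odds_ratio": orr, "p": fp}
            print(f"Fisher exact {lesion}: OR={orr:.2f}, p={fp:.3f}")

    peaks = pd.read_csv(data / "peaks.tsv", sep="\t")
    calls = classify_loh_table(peaks)
    calls.to_csv(out / "loh_calls.tsv", sep="\t", index=False)
    summ = loh_summary(calls)
    stats["loh"] = summ
    print(f"LOH over {summ['n_tumors']} tumors: "
          f"{summ['n_none']} none / {summ['n_partial']} partial / "
          f"{summ['n_complete']} complete; "
          f"{summ['percent_retained_wt']:.0f}% retained the WT allele; "
          f"partial losses {summ['partial_losses_percent']}%")

    with open(out / "cohort_stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
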