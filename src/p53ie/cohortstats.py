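"""Cohort outcome statistics and the Sanger-peak LOH classifier.

Incidence tables with the field's mixed rounding conventions (integer
percentages for headline rates, one decimal where printed that way),
Fisher exact 2x2 tests, Kaplan-Meier survival curves with log-rank
(Mantel-Cox) comparison, and classification of tumor loss of
heterozygosity (LOH) from WT/mutant Sanger chromatogram peak heights:

  (i)   WT and mutant peaks of similar height  -> no LOH,
  (ii)  only the mutant peak observed          -> complete LOH,
  (iii) WT peak shorter than the mutant        -> partial LOH, with the
        loss fraction 1 - WT/mutant reported to the nearest percent.

"Similar" is within a 10% relative tolerance by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "read_cohort",
    "write_cohort",
    "incidence",
    "fisher_exact_2x2",
    "km_curve",
    "logrank_test",
    "classify_loh",
    "LOHCall",
    "classify_loh_table",
    "loh_summary",
]


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("animal_id", "genotype", "survival_days", "event"):
        if col not in df.columns:
            raise ValueError(f"cohort table missing required column {col!r}")
    if (df["survival_days"] < 0).any():
        raise ValueError("survival_days must be >= 0")
    df["event"] = df["event"].astype(bool)
    for col in df.columns:
        if col.startswith("lesion_"):
            df[col] = df[col].astype(bool)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def incidence(cohort: pd.DataFrame, lesion: str, genotype: str):
    """Lesion incidence for one genotype.

    Returns ``(count_positive, n, percent)`` where percent = 100*count/n
    (unrounded; use round() for the integer headline or round(., 1) for
    one-decimal reporting).
    """
    col = lesion if lesion in cohort.columns else f"lesion_{lesion}"
    if col not in cohort.columns:
        raise KeyError(f"unknown lesion {lesion!r}")
    sub = cohort[cohort["genotype"] == genotype]
    if len(sub) == 0:
        raise KeyError(f"unknown genotype {genotype!r}")
    count = int(sub[col].sum())
    n = len(sub)
    return count, n, 100.0 * count / n


def fisher_exact_2x2(a: int, b: int, c: int, d: int):
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Two-sidedness by the point-probability rule (tables whose
    hypergeometric probability does not exceed the observed table's are
    summed).  Returns (odds_ratio, p) with OR = ad/bc, inf when bc = 0
    and ad > 0, nan for the degenerate 0/0.
    """
    cells = [a, b, c, d]
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise ValueError("cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return odds, float(p)


def km_curve(times, events):
    """Kaplan-Meier product-limit estimate.

    Returns ``(curve, median)``: ``curve`` is a DataFrame with columns
    ``time`` and ``survival`` (right-continuous step values at the event
    times, S(0) = 1 in the first row), and ``median`` is the earliest time
    with S(t) <= 0.5, or None if the curve never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty sample")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    curve = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return curve, median


def logrank_test(times_a, events_a, times_b, events_b):
    """Log-rank (Mantel-Cox) comparison of two survival curves.

    Returns (chi_square, p) with p from the chi-square distribution on
    1 degree of freedom.  Ties are handled with the standard
    hypergeometric variance at tied event times.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (ea.any() or eb.any()):
        raise ValueError("no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class LOHCall:
    tumor_id: str
    status: str  # none | partial | complete
    loss_fraction: float  # 0 for none, 1 for complete, rounded percent/100 for partial


def classify_loh(
    wt_peak: float, mut_peak: float, similarity_tol: float = 0.10, tumor_id: str = ""
) -> LOHCall:
    """Call LOH status from a WT/mutant Sanger peak-height pair.

    loss = 1 - wt/mut, clamped to [0, 1].  loss <= tol -> none;
    wt <= tol * mut (WT peak indistinguishable from absent) -> complete;
    otherwise partial, with the loss fraction rounded to the nearest
    percent.  A zero mutant peak is an assay failure, not LOH.
    """
    if wt_peak < 0 or mut_peak < 0:
        raise ValueError("peak heights must be >= 0")
    if mut_peak == 0:
        raise ValueError("mutant peak is zero: assay failure, cannot call LOH")
    loss = min(max(1.0 - wt_peak / mut_peak, 0.0), 1.0)
    if loss <= similarity_tol:
        return LOHCall(tumor_id, "none", 0.0)
    if wt_peak <= similarity_tol * mut_peak:
        return LOHCall(tumor_id, "complete", 1.0)
    return LOHCall(tumor_id, "partial", round(loss, 2))


def classify_loh_table(peaks: pd.DataFrame, similarity_tol: float = 0.10) -> pd.DataFrame:
    """Apply :func:`classify_loh` to a (tumor_id, wt_peak, mut_peak) table."""
    calls = [
        classify_loh(row.wt_peak, row.mut_peak, similarity_tol, tumor_id=str(row.tumor_id))
        for row in peaks.itertuples(index=False)
    ]
    return pd.DataFrame(
        {
            "tumor_id": [c.tumor_id for c in calls],
            "status": [c.status for c in calls],
            "loss_fraction": [c.loss_fraction for c in calls],
        }
    )


def loh_summary(calls: pd.DataFrame) -> dict:
    """Headline LOH percentages from a table of calls."""
    n = len(calls)
    n_none = int((calls["status"] == "none").sum())
    n_partial = int((calls["status"] == "partial").sum())
    n_complete = int((calls["status"] == "complete").sum())
    return {
        "n_tumors": n,
        "n_none": n_none,
        "n_partial": n_partial,
        "n_complete": n_complete,
        "percent_retained_wt": 100.0 * n_none / n if n else float("nan"),
        "partial_losses_percent": sorted(
            int(round(100 * f)) for f in calls.loc[calls["status"] == "partial", "loss_fraction"]
        ),
    }
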