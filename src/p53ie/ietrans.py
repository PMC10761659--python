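"""Allele-dosage trend ranking: the inhibitory-effect (IE) transcriptome.

A gene activated by wild-type p53 should be expressed highest in WT/WT
animals and progressively lower in WT/null and WT/mutant animals if the
missense mutant inhibits the remaining WT allele.  Each gene's group-mean
profile over the ordered genotype series (coded x = 0, 1, 2) is summarized
by an ordinary least-squares slope and coefficient of determination R^2;
genes with a steeply, consistently decreasing profile (slope below minus
the slope-magnitude threshold AND R^2 above the R^2 threshold, both strict)
form the IE set, ranked by descending R^2 then |slope|.

By default the trend is fitted on log2(group mean + pseudocount), so the
slope is a log2 fold change per allele step and the magnitude threshold 1
means "at least a 2-fold drop per step".  ``scale='normalized'`` fits on
the raw normalized-count means instead, where the threshold is an absolute
change in normalized counts per step.

A minimal pre-ranked running-sum enrichment statistic (weighted KS style,
gene-label permutation null) accompanies the selection for gene-set level
readouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exprcore import NormalizedMatrix, group_means

__all__ = [
    "GeneTrend",
    "fit_gene_trend",
    "gene_trends",
    "select_ie_genes",
    "preranked_enrichment",
    "EnrichmentResult",
]


@dataclass
class GeneTrend:
    gene_id: str
    group_means: tuple[float, float, float]
    slope: float
    r2: float
    is_ie: bool = False


@dataclass
class EnrichmentResult:
    gene_set_id: str
    es: float
    nes: float
    p_perm: float
    k_over_K: float


def fit_gene_trend(means, x=(0.0, 1.0, 2.0)) -> tuple[float, float]:
    """OLS slope and R^2 for a three-point dosage profile.

    Flat profiles (zero variance across the three means) return
    (slope=0, r2=0) by convention, which excludes them from selection.
    """
    y = np.asarray(means, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != (3,) or not np.all(np.isfinite(y)):
        raise ValueError("means must be three finite values")
    xm = x.mean()
    ym = y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    sst = float(((y - ym) ** 2).sum())
    if sst == 0.0:
        return 0.0, 0.0
    slope = sxy / sxx
    fitted = ym + slope * (x - xm)
    sse = float(((y - fitted) ** 2).sum())
    return slope, 1.0 - sse / sst


def gene_trends(
    nm: NormalizedMatrix,
    genotype_order: list[str],
    scale: str = "log2",
    pseudocount: float = 0.5,
) -> list[GeneTrend]:
    """Fit a trend for every gene across the ordered genotype series.

    scale='log2' (default) fits on log2(group mean + pseudocount);
    scale='normalized' fits on the raw normalized group means.
    """
    if scale not in ("log2", "normalized"):
        raise ValueError("scale must be 'log2' or 'normalized'")
    gm = group_means(nm, genotype_order)
    vals = gm.to_numpy(dtype=float)
    if scale == "log2":
        fit_vals = np.log2(vals + pseudocount)
    else:
        fit_vals = vals
    trends = []
    for gid, raw, y in zip(gm.index, vals, fit_vals):
        slope, r2 = fit_gene_trend(y)
        trends.append(GeneTrend(gid, tuple(float(v) for v in raw), slope, r2))
    return trends


def select_ie_genes(
    trends: list[GeneTrend],
    slope_magnitude_threshold: float = 1.0,
    r2_threshold: float = 0.6,
) -> list[GeneTrend]:
    """Strictly-thresholded IE selection, ranked by descending R^2 then |slope|.

    A gene is selected iff slope < -slope_magnitude_threshold and
    r2 > r2_threshold (both strict, matching the selection rule
    "descending slope > 1 and R^2 > 0.6").  Mutates ``is_ie`` in place
    and returns the selected trends in rank order.
    """
    if not trends:
        raise ValueError("trends must be nonempty")
    for t in trends:
        t.is_ie = t.slope < -slope_magnitude_threshold and t.r2 > r2_threshold
    selected = [t for t in trends if t.is_ie]
    selected.sort(key=lambda t: (-t.r2, -abs(t.slope), t.gene_id))
    return selected


def trends_table(trends: list[GeneTrend]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in trends],
            "mean_g0": [t.group_means[0] for t in trends],
            "mean_g1": [t.group_means[1] for t in trends],
            "mean_g2": [t.group_means[2] for t in trends],
            "slope": [t.slope for t in trends],
            "r2": [t.r2 for t in trends],
            "is_ie": [t.is_ie for t in trends],
        }
    ).set_index("gene_id")


def _running_es(order_stats: np.ndarray, hit_mask: np.ndarray) -> float:
    """Max-deviation running sum: |stat|-weighted hits vs uniform misses."""
    weights = np.abs(order_stats) * hit_mask
    total_hit = weights.sum()
    n_miss = len(hit_mask) - int(hit_mask.sum())
    if total_hit == 0 or n_miss == 0:
        return 0.0
    step = np.where(hit_mask, weights / total_hit, -1.0 / n_miss)
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def preranked_enrichment(
    ranked_stats: list[tuple[str, float]],
    gene_set: set,
    n_perm: int = 1000,
    seed: int | None = None,
    gene_set_id: str = "gene_set",
) -> EnrichmentResult:
    """Pre-ranked gene-set enrichment with a gene-label permutation null.

    Genes are ordered by descending statistic (ties broken by gene id so
    the ranking is deterministic); ES is the maximum deviation of the
    weighted running sum; the null permutes which labels are in the set;
    NES divides ES by the mean |null ES| of matching sign; the permutation
    p-value uses the add-one rule, so its floor is 1/(1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ids = [g for g, _ in ranked_stats]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in ranking")
    overlap = gene_set & set(ids)
    if not overlap:
        raise ValueError("gene_set has empty overlap with the ranking")
    if set(ids) <= gene_set:
        raise ValueError("set equals universe")

    order = sorted(ranked_stats, key=lambda t: (-t[1], t[0]))
    stats_arr = np.array([s for _, s in order], dtype=float)
    hit = np.array([g in gene_set for g, _ in order], dtype=bool)
    es = _running_es(stats_arr, hit)

    rng = np.random.default_rng(seed)
    k = int(hit.sum())
    null_es = np.empty(n_perm)
    idx = np.arange(len(order))
    for i in range(n_perm):
        pick = rng.choice(idx, size=k, replace=False)
        mask = np.zeros(len(order), dtype=bool)
        mask[pick] = True
        null_es[i] = _running_es(stats_arr, mask)

    same_sign = null_es * np.sign(es) > 0
    denom = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / denom if denom and np.isfinite(denom) else np.nan
    p_perm = (1 + int(np.sum(np.abs(null_es) >= abs(es)))) / (1 + n_perm)
    k_over_K = len(overlap & gene_set) / len(gene_set)
    return EnrichmentResult(gene_set_id, es, float(nes), float(p_perm), float(k_over_K))
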