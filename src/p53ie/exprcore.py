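"""Count-matrix I/O, normalization, and simplified differential expression.

Normalization is the median-of-ratios method: each sample's size factor is
the median over genes of the ratio of that sample's count to the gene's
geometric mean across samples (genes with a zero anywhere are excluded via
the log-mean formulation).  Dividing a column by its size factor makes
samples comparable regardless of sequencing depth.

Differential expression here is deliberately lightweight: a Welch t test
on log2(normalized + pseudocount) per gene, Benjamini-Hochberg adjustment,
and selection at |log2FC| >= 1 and q <= 0.05.  It is a supporting stage --
the trend-selection analysis downstream consumes only normalized group
means -- and the simplification is stated in every report this package
writes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "read_counts",
    "write_counts",
    "size_factors",
    "normalize",
    "group_means",
    "differential_expression",
    "bh_adjust",
    "ddct_fold_change",
]

DE_NOTE = (
    "Differential expression: Welch t test on log2(normalized counts + 0.5); "
    "this replaces a negative-binomial Wald test."
)


class FormatError(ValueError):
    """Malformed input table (duplicate ids, non-integer cells, missing metadata)."""


@dataclass
class CountMatrix:
    """Raw integer counts (genes x samples) plus per-sample metadata.

    ``counts`` is indexed by gene_id with one column per sample_id;
    ``sample_meta`` is indexed by sample_id with at least a ``genotype``
    column (``sex`` optional).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"sample {missing[0]!r} absent from metadata")
        if "genotype" not in self.sample_meta.columns:
            raise FormatError("sample metadata must carry a 'genotype' column")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac = arr - np.floor(arr)
            if np.any(frac != 0) or np.any(~np.isfinite(arr)):
                bad = np.argwhere((frac != 0) | ~np.isfinite(arr))[0]
                raise FormatError(
                    f"non-integer count at gene {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        # canonical axis names so write/read round-trips compare equal
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        self.sample_meta.index.name = "sample_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class NormalizedMatrix:
    """Counts divided per-column by median-of-ratios size factors."""

    values: pd.DataFrame
    size_factors: pd.Series
    sample_meta: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def read_counts(path, meta_path) -> CountMatrix:
    """Read a counts TSV (first column gene_id) and its metadata sidecar."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        obj = counts.select_dtypes(exclude="number")
        raise FormatError(f"non-numeric count column(s): {list(obj.columns)}")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, sample_meta=meta)


def write_counts(cm: CountMatrix, path, meta_path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    cm.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def size_factors(cm: CountMatrix, drop_all_zero: bool = True) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    factor_j = median over genes g of counts[g, j] / geomean_g, taken over
    genes whose geometric mean is positive (i.e. no zero in any sample).
    """
    counts = cm.counts
    if drop_all_zero:
        counts = counts.loc[counts.sum(axis=1) > 0]
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    usable = np.all(np.isfinite(log_arr), axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has a positive count in every sample; filter low-coverage "
            "genes or samples before computing size factors"
        )
    log_geomean = log_arr[usable].mean(axis=1)
    ratios = np.exp(log_arr[usable] - log_geomean[:, None])
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=cm.counts.columns, name="size_factor")


def normalize(cm: CountMatrix) -> NormalizedMatrix:
    sf = size_factors(cm)
    values = cm.counts.div(sf, axis=1)
    return NormalizedMatrix(values=values, size_factors=sf, sample_meta=cm.sample_meta)


def group_means(nm: NormalizedMatrix, genotype_order: list[str]) -> pd.DataFrame:
    """Arithmetic mean of normalized values per gene per genotype, in order."""
    out = {}
    geno = nm.sample_meta["genotype"]
    for label in genotype_order:
        samples = geno.index[geno == label]
        samples = [s for s in samples if s in nm.values.columns]
        if len(samples) == 0:
            raise ValueError(f"genotype {label!r} has no samples")
        out[label] = nm.values[samples].mean(axis=1)
    return pd.DataFrame(out, columns=genotype_order)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
    log2fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression on normalized counts.

    Returns a DataFrame indexed by gene with columns log2_fold_change
    (B over A), p_value (Welch t on log2(normalized + pseudocount)),
    q_value (BH) and selected (|log2FC| >= 1 and q <= 0.05 by default).
    """
    nm = normalize(cm)
    geno = nm.sample_meta["genotype"]
    sa = [s for s in nm.values.columns if geno.get(s) == group_a]
    sb = [s for s in nm.values.columns if geno.get(s) == group_b]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs >= 2 samples (variance undefined otherwise)")
    va = nm.values[sa].to_numpy()
    vb = nm.values[sb].to_numpy()
    log2fc = np.log2(vb.mean(axis=1) + pseudocount) - np.log2(va.mean(axis=1) + pseudocount)
    la = np.log2(va + pseudocount)
    lb = np.log2(vb + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    # genes with zero variance in both groups and equal means: no evidence
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_adjust(p)
    selected = (np.abs(log2fc) >= log2fc_threshold) & (q <= q_threshold)
    return pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": p,
            "q_value": q,
            "selected": selected,
        },
        index=nm.values.index,
    )


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the delta-delta-Ct method.

    fold = 2 ** -((Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl))
    """
    cts = [ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl]
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
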