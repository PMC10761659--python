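"""Synthetic inputs with known ground truth.

Every downstream stage of the pipeline (normalization, trend selection,
promoter scanning, cohort statistics, LOH calling) is exercised against
data generated here, so each generator records exactly what it planted in
a :class:`SimTruth` object.

The count generator emulates a bulk RNA-seq allele-dosage series: three
genotype groups ordered by functional p53 dosage (WT/WT -> WT/null ->
WT/mutant), a small set of "inhibitory effect" (IE) genes whose expression
decreases monotonically along the series, and negative-binomial sampling
noise (Var = mu + alpha*mu^2) around group means.  The planted IE trend is
an equal log2 decrement per allele step, i.e. a geometric decrease of the
count-scale group means; this matches the scale on which the trend-fitting
stage operates by default.

All generators take an explicit seed.  A single root seed is fanned out to
per-generator substreams with ``numpy.random.SeedSequence.spawn`` so that
the individual generators stay reproducible when run through the pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exprcore import CountMatrix

__all__ = [
    "SimTruth",
    "simulate_counts",
    "simulate_promoters",
    "simulate_cohort",
    "simulate_sanger_peaks",
    "write_truth",
    "read_truth",
]

#: smallest group mean a planted trend is allowed to reach (counts scale)
MEAN_FLOOR = 0.1

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimTruth:
    """Ground truth recorded while simulating.

    Attributes
    ----------
    ie_gene_ids : set of str
        Genes planted with a monotone decreasing trend across the series.
    motif_bearing_genes : set of str
        Genes whose promoter received an exact motif consensus insertion.
    motif_positions : dict
        gene_id -> (0-based offset, strand) of the planted instance.
    per_gene_base_mean : dict
        gene_id -> expected count in the reference genotype.
    per_gene_slope : dict
        gene_id -> planted per-step change on the log2 trend scale
        (negative for IE genes, 0 otherwise).
    dispersion : float
        NB dispersion alpha shared by all genes (Var = mu + alpha*mu^2).
    loh_truth : list
        Per-tumor planted loss fraction labels, as ("none"|"partial"|"complete", f).
    """

    ie_gene_ids: set = field(default_factory=set)
    motif_bearing_genes: set = field(default_factory=set)
    motif_positions: dict = field(default_factory=dict)
    per_gene_base_mean: dict = field(default_factory=dict)
    per_gene_slope: dict = field(default_factory=dict)
    dispersion: float = float("nan")
    loh_truth: list = field(default_factory=list)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB(mean, alpha) draws; the alpha -> 0 limit degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-9:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    n_genes: int = 1000,
    genotypes: tuple[str, str, str] = ("WT_WT", "WT_null", "WT_mut"),
    n_per_group: int = 3,
    ie_fraction: float = 0.05,
    ie_step: float = 3.0,
    base_mean_range: tuple[float, float] = (50.0, 500.0),
    dispersion: float = 0.05,
    seed: int | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """Simulate a genes x samples NB count matrix with planted IE genes.

    IE genes receive group means ``mu, mu * 2**-ie_step, mu * 2**-2*ie_step``
    (an equal decrement of ``ie_step`` per allele step on the log2 scale),
    floored at a small positive value; background genes are flat.

    Parameters
    ----------
    ie_step : float
        Planted per-genotype-step decrease, in log2 units (3.0 = 8-fold
        down per step).  Must be positive.
    dispersion : float
        Shared NB dispersion alpha; Var = mu + alpha*mu^2.  Values below
        1e-9 are treated as the Poisson limit.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if len(genotypes) != 3 or len(set(genotypes)) != 3:
        raise ValueError("genotypes must be three distinct ordered labels")
    if not 0.0 <= ie_fraction <= 1.0:
        raise ValueError("ie_fraction must be in [0, 1]")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if ie_step <= 0:
        raise ValueError("ie_step must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    lo, hi = base_mean_range
    if not (0 < lo <= hi):
        raise ValueError("base_mean_range must satisfy 0 < lo <= hi")

    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    n_ie = int(round(ie_fraction * n_genes))
    ie_idx = rng.choice(n_genes, size=n_ie, replace=False)
    ie_mask = np.zeros(n_genes, dtype=bool)
    ie_mask[ie_idx] = True

    base_mean = rng.uniform(lo, hi, size=n_genes)

    # group means: genes x 3
    group_means = np.repeat(base_mean[:, None], 3, axis=1)
    steps = np.array([0.0, 1.0, 2.0])
    group_means[ie_mask] = base_mean[ie_mask, None] * 2.0 ** (-ie_step * steps)
    clamped = group_means < MEAN_FLOOR
    if clamped.any():
        warnings.warn(
            f"{int(clamped.any(axis=1).sum())} gene(s) had planted group means "
            f"clamped at the floor {MEAN_FLOOR}",
            stacklevel=2,
        )
        group_means = np.maximum(group_means, MEAN_FLOOR)

    sample_ids, sample_geno = [], []
    cols = []
    for g, label in enumerate(genotypes):
        for r in range(n_per_group):
            sample_ids.append(f"{label}_s{r + 1}")
            sample_geno.append(label)
            cols.append(_nb_draw(rng, group_means[:, g], dispersion))
    counts = pd.DataFrame(
        np.column_stack(cols).astype(np.int64), index=gene_ids, columns=sample_ids
    )
    sexes = ["M" if i % 2 == 0 else "F" for i in range(len(sample_ids))]
    meta = pd.DataFrame(
        {"genotype": sample_geno, "sex": sexes}, index=pd.Index(sample_ids, name="sample_id")
    )
    cm = CountMatrix(counts=counts, sample_meta=meta)

    truth = SimTruth(
        ie_gene_ids={gene_ids[i] for i in np.flatnonzero(ie_mask)},
        per_gene_base_mean={g: float(m) for g, m in zip(gene_ids, base_mean)},
        per_gene_slope={
            g: (-float(ie_step) if ie else 0.0) for g, ie in zip(gene_ids, ie_mask)
        },
        dispersion=float(dispersion),
    )
    return cm, truth


def simulate_promoters(
    gene_ids: list[str],
    length: int = 10_000,
    gc: float = 0.45,
    pwm=None,
    planted_rate_ie: float = 0.77,
    planted_rate_bg: float = 0.035,
    ie_genes: set | None = None,
    seed: int | None = None,
    truth: SimTruth | None = None,
) -> tuple[list[SeqRecord], SimTruth]:
    """Simulate promoter sequences with motif instances planted at known rates.

    Each promoter is i.i.d. background DNA at the requested GC content
    (nominally the 10 kb window upstream of the TSS, TSS at the 3' end).
    With probability ``planted_rate_ie`` (genes in ``ie_genes``) or
    ``planted_rate_bg`` (all others), one exact consensus instance of
    ``pwm`` is written over the background at a uniform-random offset and
    strand.  Planted genes, offsets and strands are recorded in the truth.
    """
    if pwm is None:
        raise ValueError("a PWMModel is required")
    if not (0.0 <= planted_rate_ie <= 1.0 and 0.0 <= planted_rate_bg <= 1.0):
        raise ValueError("planted rates must be in [0, 1]")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    if pwm.width >= length:
        raise ValueError(f"pwm width {pwm.width} must be < promoter length {length}")
    ie_genes = ie_genes or set()
    truth = truth if truth is not None else SimTruth()
    truth.ie_gene_ids |= set(ie_genes)

    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    consensus = pwm.consensus
    records: list[SeqRecord] = []
    for gid in gene_ids:
        codes = rng.choice(4, size=length, p=p)
        seq = BASES[codes].tobytes().decode("ascii")
        rate = planted_rate_ie if gid in ie_genes else planted_rate_bg
        if rng.random() < rate:
            pos = int(rng.integers(0, length - pwm.width + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            ins = consensus if strand == "+" else str(Seq(consensus).reverse_complement())
            seq = seq[:pos] + ins + seq[pos + pwm.width :]
            truth.motif_bearing_genes.add(gid)
            truth.motif_positions[gid] = (pos, strand)
        records.append(SeqRecord(Seq(seq), id=gid, description=""))
    return records, truth


def simulate_cohort(
    genotypes: list[str],
    n_per_genotype: list[int],
    lesion_probs: dict[str, dict[str, float]],
    survival_scale_days: dict[str, float],
    censor_day: float = 800.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a mouse cohort table.

    Per animal: Bernoulli lesion calls per lesion type, exponential
    time-to-event truncated by administrative censoring at ``censor_day``,
    and alternating sexes.  Returns a tidy DataFrame with one row per
    animal and one boolean column per lesion.
    """
    if len(genotypes) != len(n_per_genotype):
        raise ValueError("genotypes and n_per_genotype must align")
    if any(n < 1 for n in n_per_genotype):
        raise ValueError("each genotype needs n >= 1 animals")
    for g in genotypes:
        for lesion, prob in lesion_probs.get(g, {}).items():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"lesion prob for {g}/{lesion} outside [0, 1]")
    if censor_day < 0:
        raise ValueError("censor_day must be >= 0")

    rng = np.random.default_rng(seed)
    lesions = sorted({l for g in genotypes for l in lesion_probs.get(g, {})})
    rows = []
    counter = 0
    for g, n in zip(genotypes, n_per_genotype):
        scale = survival_scale_days[g]
        if scale <= 0:
            raise ValueError("survival_scale_days must be positive")
        for i in range(n):
            t = rng.exponential(scale)
            event = t <= censor_day
            row = {
                "animal_id": f"m{counter:04d}",
                "genotype": g,
                "sex": "M" if counter % 2 == 0 else "F",
                "survival_days": float(min(t, censor_day)),
                "event": bool(event),
            }
            probs = lesion_probs.get(g, {})
            for lesion in lesions:
                row[f"lesion_{lesion}"] = bool(rng.random() < probs.get(lesion, 0.0))
            rows.append(row)
            counter += 1
    return pd.DataFrame(rows)


def simulate_sanger_peaks(
    loh_truth: list[tuple[str, float]],
    mut_peak_height: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate WT/mutant Sanger peak-height pairs for a list of tumors.

    ``loh_truth`` entries are ``(status, loss_fraction)`` with status in
    {"none", "partial", "complete"}; the loss fraction is 0 for none,
    f in (0, 1) for partial, and 1 for complete.  The WT peak is the mutant
    peak scaled by (1 - loss), plus Gaussian noise; negative draws clamp to 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if mut_peak_height <= 0:
        raise ValueError("mut_peak_height must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for i, (status, f) in enumerate(loh_truth):
        if status == "none":
            loss = 0.0
        elif status == "complete":
            loss = 1.0
        elif status == "partial":
            if not 0.0 < f < 1.0:
                raise ValueError("partial loss fraction must be in (0, 1)")
            loss = float(f)
        else:
            raise ValueError(f"unknown LOH status {status!r}")
        mut = max(mut_peak_height + rng.normal(0.0, noise_sd), 0.0)
        wt = max(mut * (1.0 - loss) + rng.normal(0.0, noise_sd), 0.0)
        rows.append({"tumor_id": f"t{i:03d}", "wt_peak": wt, "mut_peak": mut})
    return pd.DataFrame(rows)


def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "ie_gene_ids": sorted(truth.ie_gene_ids),
        "motif_bearing_genes": sorted(truth.motif_bearing_genes),
        "motif_positions": {g: list(v) for g, v in sorted(truth.motif_positions.items())},
        "per_gene_base_mean": truth.per_gene_base_mean,
        "per_gene_slope": truth.per_gene_slope,
        "dispersion": truth.dispersion,
        "loh_truth": [list(t) for t in truth.loh_truth],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SimTruth(
        ie_gene_ids=set(d["ie_gene_ids"]),
        motif_bearing_genes=set(d["motif_bearing_genes"]),
        motif_positions={g: tuple(v) for g, v in d["motif_positions"].items()},
        per_gene_base_mean=d["per_gene_base_mean"],
        per_gene_slope=d["per_gene_slope"],
        dispersion=d["dispersion"],
        loh_truth=[tuple(t) for t in d["loh_truth"]],
    )
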