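"""PWM promoter scanning with exact match p-values and per-sequence E-values.

A position frequency matrix (JASPAR PFM text dialect) is converted to a
log2-odds position weight matrix against a 0-order background.  Each
promoter is scanned on both strands; the best window score is assigned an
exact p-value by dynamic programming over the discretized column scores
(the exact distribution of a single window score under the background
model), converted to a per-sequence p-value over all windows, and then to
an E-value:

    p_window  = P(window score >= s)                  (exact DP)
    p_seq     = 1 - (1 - p_window) ** n_windows,      n_windows = 2*(L-W+1)
    E         = p_seq * N_sequences

A promoter "has" the motif when its E-value is at or below the threshold
(default 10).  The IE-vs-random enrichment report compares motif-positive
fractions between the IE promoter set and an equally sized random draw of
non-IE genes with a two-sided Fisher exact test.

Coordinates are 0-based; BED output is 0-based half-open.  'N' bases score
0 log-odds (background-equivalent) and never beat informative matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PWMModel",
    "parse_jaspar",
    "load_jaspar",
    "scan_promoter",
    "score_distribution",
    "match_pvalue",
    "sequence_pvalue",
    "call_hits",
    "promoter_enrichment",
    "estimate_background",
]

ALPHABET = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)  # everything unknown scores as N
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

UNIFORM = np.array([0.25, 0.25, 0.25, 0.25])


class PFMFormatError(ValueError):
    """Malformed JASPAR PFM text."""


@dataclass
class PWMModel:
    """Position frequency/weight matrices for one motif.

    counts : 4 x W non-negative reals, rows in A, C, G, T order.
    frequencies : (counts + pseudocount) column-normalized.
    log_odds : log2(frequencies / background).
    """

    motif_id: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    pseudocount: float = 0.25

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise PFMFormatError("counts must have 4 rows (A, C, G, T)")
        if self.counts.shape[1] < 1:
            raise PFMFormatError("counts must have at least one column")
        if np.any(self.counts < 0):
            raise PFMFormatError("counts must be non-negative")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or np.any(self.background <= 0):
            raise ValueError("background must be 4 strictly positive frequencies")
        self.background = self.background / self.background.sum()
        totals = self.counts.sum(axis=0) + 4 * self.pseudocount
        self.frequencies = (self.counts + self.pseudocount) / totals
        self.log_odds = np.log2(self.frequencies / self.background[:, None])

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.counts, axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def with_background(self, background) -> "PWMModel":
        return PWMModel(self.motif_id, self.counts.copy(), np.asarray(background, float),
                        self.pseudocount)

    def int_scores(self, granularity: float) -> np.ndarray:
        """Column log-odds rounded to integer multiples of ``granularity``."""
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        return np.rint(self.log_odds / granularity).astype(np.int64)


def parse_jaspar(text: str, pseudocount: float = 0.25, background=None) -> PWMModel:
    """Parse one motif in JASPAR PFM text format.

    Expected layout: a ``>ID NAME`` header followed by four rows, one per
    base in A/C/G/T order, each optionally prefixed with the base letter
    and with the numbers optionally enclosed in brackets::

        >MA0106.3 TP53
        A [ 10  0 ... ]
        ...
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise PFMFormatError("empty PFM text")
    if lines[0].startswith(">"):
        motif_id = lines[0][1:].split()[0] if lines[0][1:].split() else "motif"
        rows_txt = lines[1:]
    else:
        motif_id = "motif"
        rows_txt = lines
    if len(rows_txt) != 4:
        raise PFMFormatError(f"expected 4 count rows (A, C, G, T), got {len(rows_txt)}")
    rows, letters = [], []
    for ln in rows_txt:
        m = re.match(r"^([ACGTacgt])[\s:|]", ln)
        if m:
            letters.append(m.group(1).upper())
            ln = ln[1:]
        ln = ln.replace("[", " ").replace("]", " ")
        try:
            vals = [float(tok) for tok in ln.split()]
        except ValueError as err:
            raise PFMFormatError(f"non-numeric count in row {ln!r}") from err
        if not vals:
            raise PFMFormatError("empty count row")
        rows.append(vals)
    if letters and letters != list(ALPHABET):
        raise PFMFormatError(f"rows must be labeled A, C, G, T in order, got {letters}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise PFMFormatError(f"rows have unequal widths {sorted(widths)}")
    counts = np.array(rows)
    return PWMModel(motif_id, counts, background if background is not None else UNIFORM,
                    pseudocount)


def load_jaspar(path, **kwargs) -> PWMModel:
    with open(path) as fh:
        return parse_jaspar(fh.read(), **kwargs)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, lo5: np.ndarray) -> np.ndarray:
    """Scores of every window; lo5 is the log-odds matrix with an N row of 0."""
    width = lo5.shape[1]
    n_win = codes.size - width + 1
    out = np.zeros(n_win)
    for j in range(width):
        out += lo5[codes[j : j + n_win], j]
    return out


def scan_promoter(seq: str, pwm: PWMModel, both_strands: bool = True):
    """Best log-odds window over all offsets (and both strands).

    Returns (best_score, position, strand) with the position the 0-based
    leftmost offset of the window in the given sequence.  Ties resolve to
    the smallest offset, then the + strand.  The reverse strand is scored
    with the reverse-complemented matrix, so a hit on '-' at position p
    covers seq[p : p + W] read on the opposite strand.
    """
    W = pwm.width
    if len(seq) < W:
        raise ValueError(f"sequence length {len(seq)} shorter than motif width {W}")
    codes = _encode(seq)
    lo5 = np.vstack([pwm.log_odds, np.zeros(W)])
    plus = _window_scores(codes, lo5)
    if not both_strands:
        pos = int(np.argmax(plus))
        return float(plus[pos]), pos, "+"
    lo_rc = pwm.log_odds[::-1, ::-1]  # complement rows, reverse columns
    lo_rc5 = np.vstack([lo_rc, np.zeros(W)])
    minus = _window_scores(codes, lo_rc5)
    best = max(plus.max(), minus.max())
    plus_at = plus >= best
    minus_at = minus >= best
    first_plus = int(np.argmax(plus_at)) if plus_at.any() else None
    first_minus = int(np.argmax(minus_at)) if minus_at.any() else None
    if plus_at.any() and (not minus_at.any() or first_plus <= first_minus):
        return float(plus[first_plus]), first_plus, "+"
    return float(minus[first_minus]), first_minus, "-"


def score_distribution(pwm: PWMModel, granularity: float = 0.01):
    """Exact distribution of a single window score under the background.

    The column log-odds are discretized to integer multiples of
    ``granularity``; the distribution of their sum over one window of
    background DNA is computed by dynamic programming (per-column
    shift-and-add convolution).  Returns ``(offset, pmf)`` where bin ``k``
    of ``pmf`` is the probability of integer score ``offset + k``.
    """
    ints = pwm.int_scores(granularity)
    lo_min = int(ints.min(axis=0).sum())
    lo_max = int(ints.max(axis=0).sum())
    size = lo_max - lo_min + 1
    pmf = np.zeros(size)
    # running offset: minimum achievable partial sum so far
    pmf[0] = 1.0
    cur_min = 0
    cur_len = 1
    for j in range(pwm.width):
        col = ints[:, j]
        cmin, cmax = int(col.min()), int(col.max())
        new_len = cur_len + (cmax - cmin)
        new = np.zeros(size)
        for base in range(4):
            shift = int(col[base]) - cmin
            new[shift : shift + cur_len] += pwm.background[base] * pmf[:cur_len]
        pmf = new
        cur_min += cmin
        cur_len = new_len
    return lo_min, pmf[:cur_len]


def match_pvalue(pwm: PWMModel, score: float, granularity: float = 0.01) -> float:
    """P(single background window scores >= ``score``), exact by DP.

    Exact under the discretized score model (columns rounded to
    ``granularity``); the discretization perturbs scores by at most
    ``granularity * width / 2``.
    """
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    offset, pmf = score_distribution(pwm, granularity)
    t = int(np.rint(score / granularity))
    k = t - offset
    if k <= 0:
        return 1.0
    if k >= pmf.size:
        return 0.0
    # sum the tail from the small end for numerical stability
    return float(min(1.0, pmf[k:].sum()))


def sequence_pvalue(pwm: PWMModel, score: float, length: int,
                    granularity: float = 0.01, both_strands: bool = True) -> float:
    """Per-sequence p-value of a best-window score over a length-L promoter.

    Treats the n_windows = 2*(L-W+1) window scores as independent:
    p_seq = 1 - (1 - p_window)^n_windows.
    """
    n_windows = (2 if both_strands else 1) * (length - pwm.width + 1)
    if n_windows < 1:
        raise ValueError("sequence shorter than motif")
    p_win = match_pvalue(pwm, score, granularity)
    # log1p formulation keeps tiny p_win from underflowing to 0
    return float(-np.expm1(n_windows * np.log1p(-min(p_win, 1.0 - 1e-16))))


def estimate_background(seqs: list[str]) -> np.ndarray:
    """0-order background from observed A/C/G/T counts.

    Add-one smoothed so every base keeps positive probability; sequences
    with no unambiguous bases fall back to the uniform background.
    """
    counts = np.zeros(4)
    for s in seqs:
        codes = _encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return UNIFORM.copy()
    return (counts + 1.0) / (counts.sum() + 4.0)


@dataclass
class MotifHitSet:
    """Per-promoter best hits with p-values, E-values and hit flags."""

    pwm: PWMModel
    e_threshold: float
    table: pd.DataFrame  # index gene_id; best_score, best_position, strand, p_value, e_value, is_hit

    @property
    def n_sequences(self) -> int:
        return len(self.table)

    @property
    def hit_genes(self) -> set:
        return set(self.table.index[self.table["is_hit"]])

    def to_bed(self) -> str:
        """Hit windows as BED lines (0-based half-open), one per hit."""
        lines = []
        W = self.pwm.width
        for gid, row in self.table[self.table["is_hit"]].iterrows():
            start = int(row["best_position"])
            lines.append(
                f"{gid}\t{start}\t{start + W}\t{self.pwm.motif_id}\t"
                f"{row['best_score']:.3f}\t{row['strand']}"
            )
        return "\n".join(lines) + ("\n" if lines else "")


def call_hits(
    promoters,
    pwm: PWMModel,
    e_threshold: float = 10.0,
    granularity: float = 0.01,
    background: str | np.ndarray = "promoters",
) -> MotifHitSet:
    """Scan every promoter and call motif presence at the E-value threshold.

    ``promoters`` is a list of Biopython SeqRecords (or (id, seq) pairs).
    The background model is estimated from the scanned set by default
    (``background='promoters'``); pass 'uniform' or a 4-vector to override.
    E = p_seq * N_sequences; is_hit iff E <= e_threshold.
    """
    pairs = []
    for rec in promoters:
        if isinstance(rec, tuple):
            pairs.append((rec[0], str(rec[1])))
        else:
            pairs.append((rec.id, str(rec.seq)))
    if not pairs:
        raise ValueError("no promoter sequences supplied")
    ids = [g for g, _ in pairs]
    if len(set(ids)) != len(ids):
        dup = next(g for g in ids if ids.count(g) > 1)
        raise ValueError(f"duplicate FASTA id {dup!r}")

    if isinstance(background, str):
        if background == "promoters":
            bg = estimate_background([s for _, s in pairs])
        elif background == "uniform":
            bg = UNIFORM.copy()
        else:
            raise ValueError("background must be 'promoters', 'uniform', or a 4-vector")
    else:
        bg = np.asarray(background, dtype=float)
    pwm_bg = pwm.with_background(bg)

    offset, pmf = score_distribution(pwm_bg, granularity)
    tail = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])  # tail[k] = P(K >= offset+k)
    n = len(pairs)
    rows = []
    for gid, seq in pairs:
        score, pos, strand = scan_promoter(seq, pwm_bg)
        k = int(np.rint(score / granularity)) - offset
        p_win = 1.0 if k <= 0 else (0.0 if k >= tail.size else float(min(1.0, tail[k])))
        n_windows = 2 * (len(seq) - pwm_bg.width + 1)
        p_seq = float(-np.expm1(n_windows * np.log1p(-min(p_win, 1.0 - 1e-16))))
        e_val = p_seq * n
        rows.append((gid, score, pos, strand, p_seq, e_val, e_val <= e_threshold))
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "best_score", "best_position", "strand", "p_value",
                 "e_value", "is_hit"],
    ).set_index("gene_id")
    return MotifHitSet(pwm=pwm_bg, e_threshold=e_threshold, table=table)


def promoter_enrichment(
    ie_genes: set,
    universe: set,
    hits: MotifHitSet,
    n_random: int | None = None,
    n_draws: int = 1,
    seed: int | None = None,
) -> dict:
    """Motif-positive fraction in IE promoters vs a random non-IE gene draw.

    Draws ``n_random`` genes (default |ie_genes|) without replacement from
    universe minus ie_genes, ``n_draws`` times; hit counts are pooled over
    draws for the 2x2 Fisher exact test (two-sided).
    Returns a dict with fraction_ie, fraction_random, fisher_p, odds_ratio
    and the underlying counts.
    """
    ie_genes = set(ie_genes)
    universe = set(universe)
    if not ie_genes <= universe:
        raise ValueError("ie_genes must be a subset of the universe")
    n_random = n_random if n_random is not None else len(ie_genes)
    pool = sorted(universe - ie_genes)
    if len(pool) < n_random:
        raise ValueError(
            f"universe has only {len(pool)} non-IE genes; cannot draw {n_random}"
        )
    hit_genes = hits.hit_genes
    rng = np.random.default_rng(seed)
    ie_sorted = sorted(ie_genes)
    ie_hits = sum(g in hit_genes for g in ie_sorted)
    rand_hits_total = 0
    for _ in range(n_draws):
        draw = rng.choice(len(pool), size=n_random, replace=False)
        rand_hits_total += sum(pool[i] in hit_genes for i in draw)
    n_ie = len(ie_sorted)
    n_rand_total = n_random * n_draws
    table = [
        [ie_hits, n_ie - ie_hits],
        [rand_hits_total, n_rand_total - rand_hits_total],
    ]
    odds_ratio, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "n_ie": n_ie,
        "ie_hits": int(ie_hits),
        "fraction_ie": ie_hits / n_ie,
        "n_random": n_rand_total,
        "random_hits": int(rand_hits_total),
        "fraction_random": rand_hits_total / n_rand_total,
        "odds_ratio": float(odds_ratio),
        "fisher_p": float(fisher_p),
    }
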