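import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from p53ie import default_pwm
from p53ie.exprcore import CountMatrix


@pytest.fixture(scope="session")
def pwm():
    """The bundled synthetic p53 response-element PFM."""
    return default_pwm()


@pytest.fixture()
def tiny_counts():
    """3 genes x 4 samples, two genotypes, hand-checkable."""
    counts = pd.DataFrame(
        {
            "a1": [10, 20, 40],
            "a2": [12, 18, 44],
            "b1": [20, 40, 80],
            "b2": [24, 36, 88],
        },
        index=["g1", "g2", "g3"],
    )
    meta = pd.DataFrame(
        {"genotype": ["A", "A", "B", "B"], "sex": ["M", "F", "M", "F"]},
        index=pd.Index(["a1", "a2", "b1", "b2"], name="sample_id"),
    )
    return CountMatrix(counts=counts, sample_meta=meta)


#: the published 19-tumor LOH breakdown: 13 with no loss, five partial
#: losses of 15/25/33/33/50 percent, one complete loss
LOH_BREAKDOWN = (
    [("none", 0.0)] * 13
    + [("partial", 0.15), ("partial", 0.25), ("partial", 0.33), ("partial", 0.33),
       ("partial", 0.50)]
    + [("complete", 1.0)]
)


def naive_best_hit(seq: str, pwm):
    """Brute-force O(L*W) best-window oracle, independent of the scanner.

    Scores every offset on both strands with explicit python loops and the
    same tie rule (smallest offset, then + strand).
    """
    code = {c: i for i, c in enumerate("ACGT")}
    W = pwm.width
    lo = pwm.log_odds
    lo_rc = lo[::-1, ::-1]
    best = (-np.inf, -1, "?")
    for pos in range(len(seq) - W + 1):
        for strand, mat in (("+", lo), ("-", lo_rc)):
            s = 0.0
            for j in range(W):
                b = seq[pos + j]
                s += mat[code[b], j] if b in code else 0.0
            if s > best[0]:
                best = (s, pos, strand)
    return best
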