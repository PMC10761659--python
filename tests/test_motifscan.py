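"""PFM parsing, scanning vs brute force, DP p-values, hit calling, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from p53ie.motifscan import (
    MotifHitSet,
    PFMFormatError,
    PWMModel,
    call_hits,
    estimate_background,
    match_pvalue,
    parse_jaspar,
    promoter_enrichment,
    scan_promoter,
    score_distribution,
)
from tests.conftest import naive_best_hit


def random_pwm(rng, width):
    return PWMModel("rnd", rng.uniform(0, 40, size=(4, width)))


def random_seq(rng, length, n_rate=0.0):
    bases = np.array(list("ACGTN"))
    p = [(1 - n_rate) / 4] * 4 + [n_rate]
    return "".join(rng.choice(bases, size=length, p=p))


class TestParseJaspar:
    TEXT = ">MA0000.1 test\nA [ 10 ]\nC [ 0 ]\nG [ 0 ]\nT [ 0 ]\n"

    def test_single_column_frequencies_and_log_odds(self):
        pwm = parse_jaspar(self.TEXT)
        assert pwm.motif_id == "MA0000.1"
        assert pwm.frequencies[0, 0] == pytest.approx(10.25 / 11)
        assert pwm.log_odds[0, 0] == pytest.approx(np.log2((10.25 / 11) / 0.25))

    def test_columns_sum_to_one(self, pwm):
        assert np.allclose(pwm.frequencies.sum(axis=0), 1.0)

    def test_three_rows_rejected(self):
        with pytest.raises(PFMFormatError, match="4"):
            parse_jaspar(">x\nA [1]\nC [1]\nG [1]\n")

    def test_unequal_widths_rejected(self):
        with pytest.raises(PFMFormatError, match="unequal"):
            parse_jaspar(">x\nA [1 2]\nC [1]\nG [1 2]\nT [1 2]\n")

    def test_negative_counts_rejected(self):
        with pytest.raises(PFMFormatError):
            parse_jaspar(">x\nA [-1]\nC [1]\nG [1]\nT [1]\n")

    def test_unlabeled_rows_accepted(self):
        pwm = parse_jaspar("1 2\n3 4\n5 6\n7 8\n")
        assert pwm.width == 2


class TestScanPromoter:
    def test_consensus_scores_maximum_at_origin(self, pwm):
        score, pos, strand = scan_promoter(pwm.consensus, pwm)
        assert score == pytest.approx(pwm.max_score)
        assert (pos, strand) == (0, "+")

    def test_strand_symmetry(self, pwm):
        rng = np.random.default_rng(41)
        seq = random_seq(rng, 300)
        rc = str(Seq(seq).reverse_complement())
        s1, _, _ = scan_promoter(seq, pwm)
        s2, _, _ = scan_promoter(rc, pwm)
        assert s1 == pytest.approx(s2)

    def test_short_sequence_rejected(self, pwm):
        with pytest.raises(ValueError, match="shorter"):
            scan_promoter("ACGT", pwm)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            w = int(rng.integers(4, 9))
            pwm = random_pwm(rng, w)
            seq = random_seq(rng, int(rng.integers(w, 200)), n_rate=0.05)
            assert scan_promoter(seq, pwm) == naive_best_hit(seq, pwm)


class TestMatchPvalue:
    def test_minimum_score_gives_one(self, pwm):
        assert match_pvalue(pwm, pwm.min_score - 1.0) == 1.0

    def test_single_column_best_letter(self):
        pwm = parse_jaspar(TestParseJaspar.TEXT)
        assert match_pvalue(pwm, pwm.max_score) == pytest.approx(0.25)

    def test_bad_granularity(self, pwm):
        with pytest.raises(ValueError):
            match_pvalue(pwm, 1.0, granularity=0.0)

    @pytest.mark.parametrize("width", [3, 5])
    def test_dp_equals_exhaustive_enumeration(self, width):
        # full 4^W enumeration on the same discretized score model
        rng = np.random.default_rng(43)
        pwm = random_pwm(rng, width)
        g = 0.01
        ints = pwm.int_scores(g)
        offset, pmf = score_distribution(pwm, g)
        words = np.array(list(itertools.product(range(4), repeat=width)))
        word_scores = ints[words, np.arange(width)].sum(axis=1)
        word_probs = pwm.background[words].prod(axis=1)
        for t in np.unique(word_scores):
            exact = word_probs[word_scores >= t].sum()
            dp = pmf[t - offset :].sum()
            assert dp == pytest.approx(exact, abs=1e-12)


class TestCallHits:
    def test_planted_consensus_is_hit_among_141(self, pwm):
        rng = np.random.default_rng(44)
        promoters = [(f"g{i}", random_seq(rng, 1000)) for i in range(141)]
        seq = promoters[0][1]
        promoters[0] = ("g0", seq[:400] + pwm.consensus + seq[400 + pwm.width :])
        hits = call_hits(promoters, pwm)
        assert bool(hits.table.loc["g0", "is_hit"])
        assert hits.table.loc["g0", "best_position"] == 400
        assert hits.table.loc["g0", "strand"] == "+"

    def test_single_sequence_e_equals_p(self, pwm):
        rng = np.random.default_rng(45)
        hits = call_hits([("g", random_seq(rng, 500))], pwm)
        row = hits.table.iloc[0]
        assert row["e_value"] == pytest.approx(row["p_value"])

    def test_hit_count_monotone_in_threshold(self, pwm):
        rng = np.random.default_rng(46)
        promoters = [(f"g{i}", random_seq(rng, 600)) for i in range(50)]
        counts = [
            int(call_hits(promoters, pwm, e_threshold=e).table["is_hit"].sum())
            for e in (0.1, 1.0, 10.0, 50.0)
        ]
        assert counts == sorted(counts)

    def test_duplicate_ids_rejected(self, pwm):
        with pytest.raises(ValueError, match="duplicate"):
            call_hits([("g", "A" * 100), ("g", "C" * 100)], pwm)

    def test_record_order_invariance(self, pwm):
        rng = np.random.default_rng(47)
        promoters = [(f"g{i}", random_seq(rng, 400)) for i in range(20)]
        a = call_hits(promoters, pwm).table.sort_index()
        b = call_hits(promoters[::-1], pwm).table.sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_bed_output_is_half_open(self, pwm):
        promoters = [("g0", "T" * 100 + pwm.consensus + "T" * 100)]
        hits = call_hits(promoters, pwm)
        chrom, start, end, name, _score, strand = hits.to_bed().strip().split("\t")
        # the consensus is palindromic, so either strand may win the tie
        assert (chrom, int(start), int(end)) == ("g0", 100, 100 + pwm.width)
        assert strand in "+-"

    def test_background_estimation_fallback(self):
        assert np.allclose(estimate_background(["NNNN"]), 0.25)
        # add-one smoothing keeps absent bases at positive probability
        bg = estimate_background(["GGCC", "GCGC"])
        assert bg[1] + bg[2] == pytest.approx(10 / 12)
        assert bg[0] == bg[3] == pytest.approx(1 / 12)


class TestPromoterEnrichment:
    def _hits(self, flags: dict, pwm):
        table = pd.DataFrame(
            {
                "best_score": 0.0,
                "best_position": 0,
                "strand": "+",
                "p_value": 0.5,
                "e_value": 1.0,
                "is_hit": pd.Series(flags),
            }
        )
        table.index.name = "gene_id"
        return MotifHitSet(pwm=pwm, e_threshold=10.0, table=table)

    def test_symmetric_table_gives_unit_odds(self, pwm):
        flags = {f"i{k}": k < 5 for k in range(10)}
        flags.update({f"r{k}": k < 5 for k in range(10)})
        hits = self._hits(flags, pwm)
        rep = promoter_enrichment(
            {f"i{k}" for k in range(10)}, set(flags), hits, seed=1
        )
        assert rep["odds_ratio"] == pytest.approx(1.0)
        assert rep["fisher_p"] == pytest.approx(1.0)

    def test_insufficient_pool_rejected(self, pwm):
        flags = {"a": True, "b": False}
        hits = self._hits(flags, pwm)
        with pytest.raises(ValueError, match="draw"):
            promoter_enrichment({"a"}, {"a", "b"}, hits, n_random=5, seed=1)

    def test_reproducible_draws(self, pwm):
        flags = {f"g{k}": k % 3 == 0 for k in range(60)}
        hits = self._hits(flags, pwm)
        ie = {f"g{k}" for k in range(10)}
        a = promoter_enrichment(ie, set(flags), hits, seed=9)
        b = promoter_enrichment(ie, set(flags), hits, seed=9)
        assert a == b
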