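import dataclasses
import random

import pytest

from conftest import random_dna
from oracles import bf_best_pair
from ssrforge.errors import ConfigError, FlankError, ValidationError
from ssrforge.primer_design import (
    PrimerCandidate, PrimerConstraints, candidate_penalty, design_primer_pairs,
    has_sufficient_flanks, max_mononucleotide_run, reverse_complement,
    self_complementarity,
)
from ssrforge.sequence_io import SequenceRecord
from ssrforge.ssr_scanner import SSRLocus


def make_record_with_ssr(rng, flank_left=150, flank_right=150,
                         motif="AT", repeats=8, rec_id="toy"):
    """GC-balanced random flanks around a planted repeat; returns (rec, locus)."""
    left = random_dna(rng, flank_left)
    right = random_dna(rng, flank_right)
    # keep the junctions from extending the repeat
    k = len(motif)
    seq = left + motif * repeats + right
    start = flank_left + 1
    end = flank_left + repeats * k
    if seq[start - 2] == seq[start - 2 + k]:
        seq = seq[:start - 2] + ("C" if seq[start - 2 + k] != "C" else "G") \
            + seq[start - 1:]
    locus = SSRLocus(seq_id=rec_id, motif=motif, repeats=repeats,
                     length=repeats * k, start=start, end=end)
    return SequenceRecord(id=rec_id, description="", seq=seq), locus


class TestFlankFilter:
    def test_locus_at_sequence_start(self):
        locus = SSRLocus("s", "AC", 5, 10, 1, 10)
        assert has_sufficient_flanks(locus, 500) is False

    def test_interior_locus_passes(self):
        locus = SSRLocus("s", "AC", 10, 20, 100, 119)
        assert has_sufficient_flanks(locus, 500) is True

    def test_locus_too_long_for_product(self):
        locus = SSRLocus("s", "AC", 140, 280, 100, 379)
        assert has_sufficient_flanks(locus, 1000) is False

    def test_locus_outside_sequence(self):
        locus = SSRLocus("s", "AC", 5, 10, 100, 109)
        with pytest.raises(ValidationError):
            has_sufficient_flanks(locus, 50)


class TestSelfComplementarity:
    def test_homopolymer_cannot_self_pair(self):
        assert self_complementarity("AAAAAAAA") == (0, 0)

    def test_palindrome_scores_its_length(self):
        s_any, s_end = self_complementarity("ACGCGT")
        assert s_any == 6

    def test_end_bounded_by_any(self):
        rng = random.Random(4)
        for _ in range(100):
            s_any, s_end = self_complementarity(random_dna(rng, 18))
            assert 0 <= s_end <= s_any


class TestPenalty:
    def make_candidate(self, length, tm, gc):
        return PrimerCandidate(
            seq_id="s", strand="forward", start=1, end=length,
            oligo="A" * length, tm=tm, gc_pct=gc,
            self_any=0, self_end=0, penalty=0.0,
        )

    def test_zero_at_optimum(self):
        c = PrimerConstraints()
        assert candidate_penalty(self.make_candidate(20, 60.0, 50.0), c) == 0.0

    def test_weighted_deviation(self):
        c = PrimerConstraints()
        assert candidate_penalty(self.make_candidate(22, 59.0, 50.0), c) == \
            pytest.approx(3.0)

    def test_zero_weights_zero_penalty(self):
        c = PrimerConstraints(weight_size=0, weight_tm=0, weight_gc=0)
        assert candidate_penalty(self.make_candidate(27, 57.0, 20.0), c) == 0.0


class TestConstraints:
    def test_triples_must_be_ordered(self):
        with pytest.raises(ConfigError):
            PrimerConstraints(tm_min=63, tm_opt=60, tm_max=57)

    def test_product_must_fit_two_primers(self):
        with pytest.raises(ConfigError):
            PrimerConstraints(product_min=20)


class TestDesign:
    def audit_pair(self, pair, locus, c):
        for cand in (pair.left, pair.right):
            assert c.size_min <= len(cand.oligo) <= c.size_max
            assert c.tm_min <= cand.tm <= c.tm_max
            assert c.gc_min <= cand.gc_pct <= c.gc_max
            assert "N" not in cand.oligo
            assert max_mononucleotide_run(cand.oligo) <= c.max_poly_x
            assert cand.self_any <= c.max_self_any
            assert cand.self_end <= c.max_self_end
        assert c.product_min <= pair.product_size <= c.product_max
        assert abs(pair.left.tm - pair.right.tm) <= c.max_pair_tm_diff
        assert pair.left.end < locus.start <= locus.end < pair.right.start

    def test_insufficient_flanks_raise(self):
        rec = SequenceRecord(id="s", description="", seq="AC" * 30)
        locus = SSRLocus("s", "AC", 5, 10, 1, 10)
        with pytest.raises(FlankError):
            design_primer_pairs(rec, locus)

    def test_every_emitted_pair_is_sound(self):
        rng = random.Random(31)
        c = PrimerConstraints()
        found_any = False
        for _ in range(10):
            rec, locus = make_record_with_ssr(rng)
            pairs = design_primer_pairs(rec, locus, c)
            for p in pairs:
                self.audit_pair(p, locus, c)
            found_any = found_any or bool(pairs)
        assert found_any

    def test_reverse_oligo_reconstructs_product(self):
        rng = random.Random(8)
        rec, locus = make_record_with_ssr(rng)
        pairs = design_primer_pairs(rec, locus)
        assert pairs
        p = pairs[0]
        product = rec.seq[p.left.start - 1:p.right.end]
        assert product.startswith(p.left.oligo)
        assert product.endswith(reverse_complement(p.right.oligo))
        assert locus.start - p.left.start + 1 > 0  # SSR inside the product

    def test_best_pair_matches_exhaustive_enumeration(self):
        rng = random.Random(55)
        c = PrimerConstraints()
        compared = 0
        for _ in range(15):
            rec, locus = make_record_with_ssr(
                rng, flank_left=rng.randint(60, 130),
                flank_right=rng.randint(60, 130))
            pairs = design_primer_pairs(rec, locus, c)
            oracle = bf_best_pair(rec.seq, locus.start, locus.end, c)
            if oracle is None:
                assert pairs == []
                continue
            compared += 1
            best = pairs[0]
            assert (best.left.start, best.left.end,
                    best.right.start, best.right.end) == oracle[:4]
            assert best.pair_penalty == pytest.approx(oracle[4])
        assert compared >= 5

    def test_determinism(self):
        rng1, rng2 = random.Random(3), random.Random(3)
        rec1, locus1 = make_record_with_ssr(rng1)
        rec2, locus2 = make_record_with_ssr(rng2)
        a = design_primer_pairs(rec1, locus1)
        b = design_primer_pairs(rec2, locus2)
        assert a == b

    def test_tightening_constraints_never_adds_pairs(self):
        rng = random.Random(21)
        rec, locus = make_record_with_ssr(rng)
        base = PrimerConstraints()
        baseline = {(p.left.start, p.left.end, p.right.start, p.right.end)
                    for p in design_primer_pairs(
                        rec, locus, dataclasses.replace(
                            base, max_pairs_returned=10 ** 6))}
        for change in ({"tm_min": 58.0, "tm_max": 62.0},
                       {"gc_min": 40.0, "gc_max": 60.0},
                       {"max_poly_x": 3},
                       {"max_self_any": 5, "max_self_end": 2},
                       {"product_min": 120, "product_max": 250}):
            tight = dataclasses.replace(base, max_pairs_returned=10 ** 6,
                                        **change)
            got = {(p.left.start, p.left.end, p.right.start, p.right.end)
                   for p in design_primer_pairs(rec, locus, tight)}
            assert got <= baseline
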