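from __future__ import annotations

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as bio_mt
from hypothesis import given, settings, strategies as st

from estindel import (
    PrimerConstraints,
    Segment,
    design_primer_pairs,
    design_for_transcript,
    gc_fraction,
    melting_temp,
    primer_penalty,
    segment_est,
)
from estindel._seq import revcomp

from _oracles import exhaustive_pair_search, nn_tm
from conftest import random_seq


class TestSegmentation:
    def test_tiled_900bp_without_overlap(self):
        segs = segment_est("A" * 900, "q", target_len=300, overlap=0, mode="tiled")
        assert [(s.start, s.end) for s in segs] == [(0, 300), (300, 600), (600, 900)]

    def test_short_transcript_is_one_segment(self):
        segs = segment_est("A" * 250, "q", target_len=300)
        assert [(s.start, s.end) for s in segs] == [(0, 250)]

    def test_empty_sequence_gives_no_segments(self):
        assert segment_est("", "q") == []

    @given(
        n=st.integers(min_value=1, max_value=2500),
        seed=st.integers(min_value=0, max_value=10_000),
        mode=st.sampled_from(["tiled", "random"]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_coverage_and_overlap_invariants(self, n, seed, mode):
        segs = segment_est("A" * n, "q", target_len=300, overlap=60, mode=mode, seed=seed)
        assert segs[0].start == 0 and segs[-1].end == n
        for prev, cur in zip(segs, segs[1:]):
            assert prev.end - cur.start >= 60  # adjacent overlap
            assert cur.start > prev.start

    def test_random_mode_deterministic_per_seed(self):
        a = segment_est("A" * 1500, "q", seed=5)
        b = segment_est("A" * 1500, "q", seed=5)
        c = segment_est("A" * 1500, "q", seed=6)
        assert [(s.start, s.end) for s in a] == [(s.start, s.end) for s in b]
        assert [(s.start, s.end) for s in a] != [(s.start, s.end) for s in c]


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 0.5), ("AAAA", 0.0), ("GGCC", 1.0), ("GGGN", 0.75)]
    )
    def test_values(self, seq, expected):
        assert gc_fraction(seq) == expected

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            gc_fraction("")


class TestMeltingTemp:
    def test_reverse_complement_symmetry(self, rng):
        for _ in range(30):
            s = random_seq(rng, int(rng.integers(18, 21)))
            assert melting_temp(s) == pytest.approx(melting_temp(revcomp(s)), abs=1e-3)

    def test_gc_rich_melts_higher_than_at_rich(self):
        assert melting_temp("G" * 20) > melting_temp("A" * 20)

    def test_agrees_with_hand_coded_parameter_table(self, rng):
        for _ in range(50):
            s = random_seq(rng, int(rng.integers(18, 21)))
            assert melting_temp(s) == pytest.approx(nn_tm(s), abs=0.5)

    def test_agrees_with_biopython_reference(self, rng):
        for _ in range(50):
            s = random_seq(rng, int(rng.integers(8, 37)))
            ref = bio_mt.Tm_NN(
                s, nn_table=bio_mt.DNA_NN3, Na=50, dnac1=50, dnac2=0, saltcorr=5
            )
            assert melting_temp(s) == pytest.approx(ref, abs=0.5)

    def test_wallace_rule(self):
        assert melting_temp("ACGTACGTAC", method="wallace") == 30.0

    @pytest.mark.parametrize("bad", ["", "ACGTN" * 4, "ACGT"])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            melting_temp(bad)


class TestPenalty:
    def test_gc_out_of_bounds_is_infeasible(self, rng):
        # a 20-mer with 30% GC violates the 45-65% hard bound
        seq = "AT" * 7 + "GC" * 3
        assert gc_fraction(seq) == 0.3
        assert primer_penalty(seq) is None

    def test_formula_matches_attributes(self, rng):
        found = 0
        for _ in range(300):
            s = random_seq(rng, 19)
            pen = primer_penalty(s)
            if pen is None:
                continue
            found += 1
            expected = (
                1.0 * abs(19 - 20)
                + 1.0 * abs(gc_fraction(s) - 0.5) * 10.0
                + 1.0 * abs(melting_temp(s) - 58.0)
            )
            assert pen == pytest.approx(expected, abs=1e-9)
        assert found > 0

    def test_infeasible_when_tm_out_of_range(self):
        assert primer_penalty("G" * 20) is None  # Tm far above 62


class TestDesign:
    def test_all_a_segment_designs_nothing(self):
        seg = Segment("q", 0, 300, "A" * 300)
        assert design_primer_pairs(seg) == []

    def test_pairs_satisfy_all_hard_bounds(self, rng):
        c = PrimerConstraints()
        for _ in range(10):
            bases = random_seq(rng, 300)
            seg = Segment("q", 0, 300, bases)
            for p in design_primer_pairs(seg, c, n_best=3):
                for primer in (p.fwd_seq, p.rev_seq):
                    assert c.len_min <= len(primer) <= c.len_max
                    assert c.gc_min <= gc_fraction(primer) <= c.gc_max
                    assert c.tm_min <= melting_temp(primer) <= c.tm_max
                assert c.product_min <= p.expected_size <= c.product_max
                assert p.fwd_seq == bases[p.fwd_start : p.fwd_start + len(p.fwd_seq)]
                assert revcomp(p.rev_seq) == bases[p.rev_end - len(p.rev_seq) : p.rev_end]
                assert p.expected_size == p.rev_end - p.fwd_start

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        c = PrimerConstraints()
        for _ in range(8):
            bases = random_seq(rng, 300)
            seg = Segment("q", 40, 340, bases)
            got = [
                (p.penalty, p.fwd_start, p.rev_end, len(p.fwd_seq), len(p.rev_seq))
                for p in design_primer_pairs(seg, c, n_best=2)
            ]
            expected = [
                (round(e[0], 6), *e[1:])
                for e in exhaustive_pair_search(bases, 40, "q", c, 2, primer_penalty)
            ]
            assert got == expected

    def test_transcript_design_reports_gaps(self, rng):
        bases = random_seq(rng, 700)
        pairs, gaps = design_for_transcript(bases, "q", seed=3)
        covered = set()
        for p in pairs:
            covered.update(range(p.fwd_start, p.rev_end))
        for a, b in gaps:
            assert not covered & set(range(a, b))
        union = covered | {i for a, b in gaps for i in range(a, b)}
        assert union == set(range(700))

    def test_design_deterministic(self, rng):
        bases = random_seq(rng, 600)
        a, _ = design_for_transcript(bases, "q", seed=9)
        b, _ = design_for_transcript(bases, "q", seed=9)
        assert a == b
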