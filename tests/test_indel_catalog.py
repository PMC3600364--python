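from __future__ import annotations

import pytest

from estindel import (
    BandPattern,
    PrimerPair,
    bin_sizes,
    classify_band_pattern,
    collapse_redundant,
    select_markers,
    summarize_catalog,
)
from estindel.indel_catalog import InDelLocus
from estindel.insilico_pcr import InDelCall
from estindel._seq import revcomp


def _pair(pair_id, query, fwd_start, rev_end):
    return PrimerPair(
        pair_id=pair_id,
        source_id=query,
        fwd_seq="A" * 20,
        rev_seq="T" * 20,
        fwd_start=fwd_start,
        rev_end=rev_end,
        expected_size=rev_end - fwd_start,
        penalty=0.0,
    )


def _call(pair_id, query, target, delta, expected=200):
    return InDelCall(pair_id, query, target, expected, expected + delta, delta)


class TestCollapse:
    def test_nested_pairs_same_delta_merge_with_support(self):
        pairs = {"p1": _pair("p1", "q", 10, 210), "p2": _pair("p2", "q", 40, 240)}
        calls = [_call("p1", "q", "t", -7), _call("p2", "q", "t", -7)]
        loci = collapse_redundant(calls, pairs)
        assert len(loci) == 1
        assert loci[0].support == 2
        assert loci[0].delta_set == frozenset({-7})
        assert loci[0].query_interval == (10, 240)

    def test_non_overlapping_regions_stay_separate(self):
        pairs = {"p1": _pair("p1", "q", 0, 200), "p2": _pair("p2", "q", 300, 500)}
        calls = [_call("p1", "q", "t", -7), _call("p2", "q", "t", -7)]
        loci = collapse_redundant(calls, pairs)
        assert len(loci) == 2

    def test_two_targets_contribute_a_delta_set(self):
        pairs = {"p1": _pair("p1", "q", 10, 210)}
        calls = [_call("p1", "q", "t1", -7), _call("p1", "q", "t2", +3)]
        loci = collapse_redundant(calls, pairs)
        assert len(loci) == 1
        assert loci[0].delta_set == frozenset({-7, 3})

    def test_cluster_mapping_merges_across_queries(self):
        pairs = {"p1": _pair("p1", "q1", 10, 210), "p2": _pair("p2", "q2", 50, 250)}
        calls = [_call("p1", "q1", "t", 4), _call("p2", "q2", "t", 4)]
        separate = collapse_redundant(calls, pairs)
        merged = collapse_redundant(calls, pairs, {"q1": "c1", "q2": "c1"})
        assert len(separate) == 2 and len(merged) == 1

    def test_unknown_pair_id_is_an_error(self):
        with pytest.raises(KeyError):
            collapse_redundant([_call("nope", "q", "t", 1)], {})

    def test_collapse_idempotent(self):
        pairs = {
            "p1": _pair("p1", "q", 10, 210),
            "p2": _pair("p2", "q", 40, 240),
            "p3": _pair("p3", "q", 400, 600),
        }
        calls = [
            _call("p1", "q", "t1", -7),
            _call("p2", "q", "t1", -7),
            _call("p2", "q", "t2", 3),
            _call("p3", "q", "t1", 12),
        ]
        once = collapse_redundant(calls, pairs)
        # re-collapsing the loci's own calls (one per delta, tightest interval)
        recalls, repairs = [], {}
        for locus in once:
            for d, (a, b) in locus.delta_intervals:
                pid = f"{locus.locus_id}:{d}"
                repairs[pid] = _pair(pid, locus.query_id, a, b)
                recalls.append(_call(pid, locus.query_id, "t", d, expected=b - a))
        again = collapse_redundant(recalls, repairs)
        assert [(l.query_id, l.query_interval, l.delta_set) for l in again] == [
            (l.query_id, l.query_interval, l.delta_set) for l in once
        ]


def _locus(query, lo, hi, deltas, pair_id="p1", support=1):
    return InDelLocus(
        locus_id=f"{query}:{lo}-{hi}",
        query_id=query,
        query_interval=(lo, hi),
        delta_set=frozenset(deltas),
        support=support,
        representative_pair=pair_id,
        delta_intervals=tuple((d, (lo, hi)) for d in sorted(deltas)),
    )


class TestBinsAndMarkers:
    def test_bin_boundaries_as_published(self):
        loci = [
            _locus("q1", 0, 100, {-1}),
            _locus("q2", 0, 100, {3}),
            _locus("q3", 0, 100, {-7}),
            _locus("q4", 0, 100, {21}),
        ]
        s = bin_sizes(loci)
        assert (s.n_1bp, s.n_2_4bp, s.n_5_10bp, s.n_gt10bp) == (1, 1, 1, 1)
        assert s.total == 4

    def test_empty_summary(self):
        s = bin_sizes([])
        assert s.total == 0 and s.max_abs_delta == 0

    def test_bins_partition_random_loci(self, rng):
        loci = [
            _locus(f"q{i}", 0, 100, {int(d)})
            for i, d in enumerate(rng.integers(1, 170, 500))
        ]
        s = bin_sizes(loci)
        assert s.n_1bp + s.n_2_4bp + s.n_5_10bp + s.n_gt10bp == s.total == 500

    def test_marker_cutoff_is_inclusive_at_5(self):
        pairs = {"p1": _pair("p1", "q", 0, 200)}
        loci = [
            _locus("q", 0, 200, {-5}),
            _locus("q", 300, 500, {4}),
            _locus("q", 600, 800, {-2, 12}),
        ]
        markers = select_markers(loci, pairs)
        assert len(markers) == 2
        assert markers[0].max_abs_delta == 5
        assert markers[1].max_abs_delta == 12

    def test_marker_count_equals_large_bins(self, rng):
        pairs = {"p1": _pair("p1", "q", 0, 200)}
        loci = [
            _locus(f"q{i}", 0, 100, {int(d) * (1 if i % 2 else -1)})
            for i, d in enumerate(rng.integers(1, 40, 300))
        ]
        s = bin_sizes(loci)
        markers = select_markers(loci, pairs, 5)
        assert len(markers) == s.n_5_10bp + s.n_gt10bp

    def test_unknown_representative_pair_is_an_error(self):
        with pytest.raises(KeyError):
            select_markers([_locus("q", 0, 100, {9}, pair_id="missing")], {})

    def test_summary_mean_max(self):
        loci = [_locus("q1", 0, 9, {5}), _locus("q2", 0, 9, {-10}), _locus("q3", 0, 9, {15})]
        s, per_cluster = summarize_catalog(loci)
        assert s.mean_abs_delta == 10 and s.max_abs_delta == 15
        assert per_cluster == {"q1": 1, "q2": 1, "q3": 1}


class TestBandPatterns:
    def test_single_distinct_bands_are_orthologous(self):
        assert classify_band_pattern(
            [BandPattern("H", (200,))], [BandPattern("T", (190,))]
        ) == "type1_orthologous"

    def test_multi_band_differences_are_homoeologous(self):
        assert classify_band_pattern(
            [BandPattern("H", (200, 188))], [BandPattern("T", (200, 195))]
        ) == "type2_homoeologous"

    def test_identical_bands_are_monomorphic(self):
        assert classify_band_pattern(
            [BandPattern("H", (200,))], [BandPattern("T", (200,))]
        ) == "type3_monomorphic"

    def test_no_amplification_is_failure(self):
        assert classify_band_pattern(
            [BandPattern("H", ())], [BandPattern("T", ())]
        ) == "failure"

    def test_symmetric_and_order_invariant(self, rng):
        for _ in range(40):
            a = [BandPattern("a", tuple(sorted(rng.integers(100, 300, rng.integers(0, 4)))))]
            b = [BandPattern("b", tuple(sorted(rng.integers(100, 300, rng.integers(0, 4)))))]
            ab = classify_band_pattern(a, b)
            ba = classify_band_pattern(b, a)
            assert ab == ba
            shuffled = [BandPattern("a", tuple(reversed(a[0].bands)))]
            assert classify_band_pattern(shuffled, b) == ab

    def test_tolerance_merges_near_bands(self):
        res = classify_band_pattern(
            [BandPattern("H", (200,))], [BandPattern("T", (202,))], size_tolerance=3
        )
        assert res == "type3_monomorphic"
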