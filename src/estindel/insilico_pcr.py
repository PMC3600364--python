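"""Mismatch-tolerant virtual PCR on transcript collections.

Primer binding sites are located by substitution-only (Hamming) matching on
both strands — the e-PCR convention: gapped primer sites would conflate
primer-site InDels with the amplicon-size InDels the pipeline is after.  A
site qualifies with at most ``max_mismatch`` substitutions (default 2,
i.e. fewer than 3 mismatching bases) and an exactly matching 3' terminus
(``anchor3`` bases, default 1), since polymerase extension requires a paired
3' end.  ``N`` on the target always counts as a mismatch.

Amplicons are reported in 0-based half-open coordinates on the target plus
strand, ``size == end - start``; a size differing from the pair's expected
product on the query becomes an :class:`InDelCall` with signed
``delta = observed - expected`` (positive = net insertion in the target
relative to the query).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._seq import encode, revcomp
from .primer_design import PrimerPair

__all__ = [
    "PrimerHit",
    "Amplicon",
    "InDelCall",
    "TargetIndex",
    "scan_primer",
    "virtual_amplify",
    "call_size_variants",
    "run_pcr",
]


@dataclass(frozen=True)
class PrimerHit:
    """A primer binding site on a target (site length == primer length)."""

    target_id: str
    offset: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product on the target plus strand."""

    target_id: str
    start: int
    end: int
    size: int
    fwd_hit: PrimerHit
    rev_hit: PrimerHit


@dataclass(frozen=True)
class InDelCall:
    """A size difference between expected and observed product."""

    pair_id: str
    query_id: str
    target_id: str
    expected_size: int
    observed_size: int
    delta: int


@njit(cache=False)
def _scan_kernel(t, p, max_mismatch, anchor_head, anchor_tail):  # pragma: no cover
    n = t.size
    m = p.size
    n_off = n - m + 1
    offs = np.empty(n_off, np.int64)
    cnts = np.empty(n_off, np.int64)
    k = 0
    for o in range(n_off):
        bad = False
        for j in range(anchor_head):
            if t[o + j] != p[j] or t[o + j] >= 4 or p[j] >= 4:
                bad = True
                break
        if bad:
            continue
        for j in range(m - anchor_tail, m):
            if t[o + j] != p[j] or t[o + j] >= 4 or p[j] >= 4:
                bad = True
                break
        if bad:
            continue
        mism = 0
        for j in range(m):
            if t[o + j] != p[j] or t[o + j] >= 4 or p[j] >= 4:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            offs[k] = o
            cnts[k] = mism
            k += 1
    return offs[:k], cnts[:k]


def _hit_offsets(
    tcodes: np.ndarray, pcodes: np.ndarray, max_mismatch: int, anchor_head: int, anchor_tail: int
) -> tuple[np.ndarray, np.ndarray]:
    """Offsets and mismatch counts of qualifying windows of ``pcodes``.

    ``anchor_head``/``anchor_tail`` bases at the window start/end must match
    exactly (used to enforce the primer 3' anchor on either strand).  Any
    non-ACGT code on either side counts as a mismatch.
    """
    m = pcodes.size
    if tcodes.size < m:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return _scan_kernel(
        np.ascontiguousarray(tcodes),
        np.ascontiguousarray(pcodes),
        max_mismatch,
        anchor_head,
        anchor_tail,
    )


def scan_primer(
    primer: str,
    target: str,
    max_mismatch: int = 2,
    anchor3: int = 1,
    target_id: str = "",
) -> list[PrimerHit]:
    """All substitution-only binding sites of ``primer`` on both strands.

    Minus-strand sites are reported at the plus-strand start of the matched
    window (the site where the reverse complement of the primer aligns).
    Hits are sorted by (offset, strand); a primer longer than the target
    yields no hits.
    """
    if max_mismatch < 0 or anchor3 < 0:
        raise ValueError("max_mismatch and anchor3 must be >= 0")
    if not primer:
        raise ValueError("empty primer")
    tcodes = encode(target.upper())
    p = encode(primer.upper())
    hits = []
    offs, counts = _hit_offsets(tcodes, p, max_mismatch, 0, anchor3)
    hits += [
        PrimerHit(target_id, int(o), "+", int(c)) for o, c in zip(offs, counts)
    ]
    prc = encode(revcomp(primer.upper()))
    offs, counts = _hit_offsets(tcodes, prc, max_mismatch, anchor3, 0)
    hits += [
        PrimerHit(target_id, int(o), "-", int(c)) for o, c in zip(offs, counts)
    ]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _pair_amplicons(
    pair: PrimerPair,
    fwd_hits: list[PrimerHit],
    rev_hits: list[PrimerHit],
    max_product: int,
    pair_mismatch_budget: int | None,
) -> list[Amplicon]:
    lf, lr = len(pair.fwd_seq), len(pair.rev_seq)
    out = []
    fwd_plus = [h for h in fwd_hits if h.strand == "+"]
    rev_minus = [h for h in rev_hits if h.strand == "-"]
    rev_plus = [h for h in rev_hits if h.strand == "+"]
    fwd_minus = [h for h in fwd_hits if h.strand == "-"]
    # canonical orientation: fwd on plus, rev on minus, fwd upstream
    for f in fwd_plus:
        for r in rev_minus:
            start, end = f.offset, r.offset + lr
            if end - start < lf + lr or end - start > max_product:
                continue
            if _within_budget(f, r, pair_mismatch_budget):
                out.append(Amplicon(f.target_id, start, end, end - start, f, r))
    # flipped orientation: the target is the reverse complement of the
    # amplified region, so the rev primer sits on plus upstream of fwd
    for r in rev_plus:
        for f in fwd_minus:
            start, end = r.offset, f.offset + lf
            if end - start < lf + lr or end - start > max_product:
                continue
            if _within_budget(f, r, pair_mismatch_budget):
                out.append(Amplicon(f.target_id, start, end, end - start, f, r))
    out.sort(key=lambda a: (a.start, a.end, a.fwd_hit.strand))
    return out


def _within_budget(f: PrimerHit, r: PrimerHit, budget: int | None) -> bool:
    return budget is None or (f.mismatches + r.mismatches) <= budget


def virtual_amplify(
    pair: PrimerPair,
    target: str,
    target_id: str = "",
    max_mismatch: int = 2,
    anchor3: int = 1,
    max_product: int | None = None,
    pair_mismatch_budget: int | None = None,
) -> list[Amplicon]:
    """Virtual products of one primer pair on one target sequence.

    One amplicon per correctly-oriented (forward, reverse) hit combination
    with ``len(fwd)+len(rev) <= size <= max_product``; multiple amplicons per
    target are allowed (homoeologous copies).  ``max_product`` defaults to
    ``expected_size + 500``.
    """
    if max_product is None:
        max_product = pair.expected_size + 500
    fwd_hits = scan_primer(pair.fwd_seq, target, max_mismatch, anchor3, target_id)
    rev_hits = scan_primer(pair.rev_seq, target, max_mismatch, anchor3, target_id)
    return _pair_amplicons(pair, fwd_hits, rev_hits, max_product, pair_mismatch_budget)


def call_size_variants(pair: PrimerPair, amplicons: list[Amplicon]) -> list[InDelCall]:
    """One call per amplicon whose size differs from the expected product."""
    return [
        InDelCall(
            pair_id=pair.pair_id,
            query_id=pair.source_id,
            target_id=a.target_id,
            expected_size=pair.expected_size,
            observed_size=a.size,
            delta=a.size - pair.expected_size,
        )
        for a in amplicons
        if a.size != pair.expected_size
    ]


class TargetIndex:
    """Concatenated target collection for fast whole-collection scans.

    Records are joined with runs of ``N`` (always-mismatch) spacers; hits are
    mapped back to record coordinates and any window crossing a record
    boundary is discarded.
    """

    _SPACER = 40

    def __init__(self, records: dict[str, str]):
        self.ids = list(records)
        parts = []
        starts = []
        pos = 0
        spacer = np.full(self._SPACER, 4, dtype=np.uint8)
        for i, (rid, seq) in enumerate(records.items()):
            if i > 0:
                parts.append(spacer)
                pos += self._SPACER
            starts.append(pos)
            codes = encode(seq.upper())
            parts.append(codes)
            pos += codes.size
        self.codes = (
            np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        )
        self.starts = np.array(starts, dtype=int)
        self.lengths = np.array([len(s) for s in records.values()], dtype=int)

    def scan(self, primer: str, max_mismatch: int, anchor3: int) -> dict[str, list[PrimerHit]]:
        """Hits of ``primer`` per record, both strands, record coordinates."""
        out: dict[str, list[PrimerHit]] = {}
        p = encode(primer.upper())
        for strand, codes, head, tail in (
            ("+", p, 0, anchor3),
            ("-", encode(revcomp(primer.upper())), anchor3, 0),
        ):
            offs, counts = _hit_offsets(self.codes, codes, max_mismatch, head, tail)
            for o, c in zip(offs, counts):
                rec = int(np.searchsorted(self.starts, o, side="right") - 1)
                local = int(o) - int(self.starts[rec])
                if local < 0 or local + p.size > int(self.lengths[rec]):
                    continue
                rid = self.ids[rec]
                out.setdefault(rid, []).append(
                    PrimerHit(rid, local, strand, int(c))
                )
        for hits in out.values():
            hits.sort(key=lambda h: (h.offset, h.strand))
        return out


def run_pcr(
    pairs: list[PrimerPair],
    targets: dict[str, str],
    max_mismatch: int = 2,
    anchor3: int = 1,
    max_product: int | None = None,
    pair_mismatch_budget: int | None = None,
) -> tuple[list[tuple[PrimerPair, Amplicon]], list[InDelCall]]:
    """Amplify every pair against a whole target collection.

    Returns all (pair, amplicon) products and the InDel calls they imply.
    Primer scans are cached per unique primer sequence, so nested pairs
    sharing a primer cost one scan.
    """
    index = TargetIndex(targets)
    cache: dict[str, dict[str, list[PrimerHit]]] = {}

    def scan(primer: str) -> dict[str, list[PrimerHit]]:
        if primer not in cache:
            cache[primer] = index.scan(primer, max_mismatch, anchor3)
        return cache[primer]

    products: list[tuple[PrimerPair, Amplicon]] = []
    calls: list[InDelCall] = []
    for pair in pairs:
        cap = pair.expected_size + 500 if max_product is None else max_product
        fwd_by_target = scan(pair.fwd_seq)
        rev_by_target = scan(pair.rev_seq)
        for tid in (t for t in fwd_by_target if t in rev_by_target):
            amps = _pair_amplicons(
                pair, fwd_by_target[tid], rev_by_target[tid], cap, pair_mismatch_budget
            )
            products += [(pair, a) for a in amps]
            calls += call_size_variants(pair, amps)
    return products, calls
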