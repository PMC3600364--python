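"""EST cleaning cascade: quality trimming, vector masking, polyA/X removal.

Single-pass cDNA reads (ESTs) carry sequencing artifacts that must be
stripped before any comparative analysis: low-quality termini, cloning-vector
fragments, polyA tails from the mRNA, and ``X`` characters left by upstream
maskers.  The cascade here applies, in order:

1. Mott-style quality trimming at a Phred-20 cutoff (1% error probability),
2. vector masking (seeded local alignment, cross_match-style thresholds)
   followed by excision of the masked spans,
3. terminal polyA/polyT/X removal,
4. a minimum-length filter (default 100 bp).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from ._seq import revcomp

__all__ = [
    "RawEST",
    "CleanEST",
    "Rejection",
    "VectorLibrary",
    "CleaningConfig",
    "mott_quality_trim",
    "trim_terminal_homopolymer",
    "mask_vector",
    "clean_est",
]


@dataclass(frozen=True)
class RawEST:
    """A transcript read before cleaning.

    ``quals`` are per-base Phred scores; ``None`` means no chromatogram
    qualities are available (common for public EST submissions), in which
    case quality trimming is skipped.
    """

    id: str
    bases: str
    quals: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("RawEST id must be non-empty")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"{self.id}: {len(self.quals)} quality values for "
                f"{len(self.bases)} bases"
            )


@dataclass(frozen=True)
class CleanEST:
    """A cleaned transcript with trim provenance.

    ``source_interval`` is the retained 0-based half-open interval on the raw
    sequence; ``bases == raw.bases[slice(*source_interval)]`` with any masked
    spans already excised (the cascade keeps the longest unmasked fragment,
    so the retained region is always a single interval).  ``trims`` records
    each removal as ``(stage, (start, end))`` in raw coordinates.
    """

    id: str
    bases: str
    trims: tuple[tuple[str, tuple[int, int]], ...] = ()
    source_interval: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class Rejection:
    """Why a record was dropped: too_short, fully_masked or fully_low_quality."""

    id: str
    reason: str
    original_length: int
    retained_interval: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class VectorLibrary:
    """Vector/adapter sequences to mask (UniVec-style)."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for name, seq in self.entries:
            if not seq:
                raise ValueError(f"vector entry {name!r} is empty")


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds for the cleaning cascade (defaults mirror standard EST
    processing: Q20 quality cutoff, cross_match minmatch/minscore 20/20,
    100 bp minimum length)."""

    error_cutoff: float = 0.01
    min_run: int = 8
    window: int = 50
    minmatch: int = 20
    minscore: int = 20
    min_length: int = 100


def mott_quality_trim(
    quals: "list[int] | tuple[int, ...] | np.ndarray", error_cutoff: float = 0.01
) -> tuple[int, int]:
    """Maximal-scoring quality interval (Mott algorithm, as in phred/lucy).

    Each base scores ``error_cutoff - 10**(-q/10)``; the retained interval is
    the contiguous window maximizing the score sum.  ``error_cutoff`` 0.01
    corresponds to Phred Q20.  Ties break leftmost start, then longest.
    Returns the empty interval ``(0, 0)`` when no window has positive score.
    """
    if not 0.0 < error_cutoff < 1.0:
        raise ValueError("error_cutoff must be in (0, 1)")
    q = np.asarray(quals, dtype=float)
    if q.size == 0:
        return (0, 0)
    scores = error_cutoff - np.power(10.0, -q / 10.0)
    # Prefix-sum formulation: interval [s, e) scores P[e] - P[s].
    prefix = np.concatenate(([0.0], np.cumsum(scores)))
    best_val = 0.0
    best = (0, 0)
    min_p = prefix[0]
    min_i = 0
    for e in range(1, len(prefix)):
        val = prefix[e] - min_p
        if val > best_val or (
            val == best_val
            and best != (0, 0)
            and (min_i < best[0] or (min_i == best[0] and e > best[1]))
        ):
            if val > 0.0:
                best_val = val
                best = (min_i, e)
        if prefix[e] < min_p:
            min_p = prefix[e]
            min_i = e
    return best


def trim_terminal_homopolymer(
    bases: str,
    letters: frozenset[str] | set[str] = frozenset("A"),
    min_run: int = 8,
    window: int = 50,
    which: str = "both",
) -> str:
    """Remove a terminal homopolymer run (polyA tail style).

    A run of >= ``min_run`` identical letters from ``letters`` is removed
    together with everything outside it, provided the run ends within
    ``window`` bases of the terminus.  ``which`` selects the 5' end, 3' end
    or both.  Internal runs are never touched; the operation is idempotent.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    out = bases
    changed = True
    while changed:
        changed = False
        if which in ("3p", "both"):
            cut = _find_terminal_run(out, letters, min_run, window, three_prime=True)
            if cut is not None:
                out = out[:cut]
                changed = True
        if which in ("5p", "both"):
            cut = _find_terminal_run(out, letters, min_run, window, three_prime=False)
            if cut is not None:
                out = out[cut:]
                changed = True
    return out


def _find_terminal_run(
    seq: str, letters, min_run: int, window: int, three_prime: bool
) -> int | None:
    """Cut coordinate for a trimmable terminal run, or None.

    For the 3' end returns the position to truncate at (``seq[:cut]``); for
    the 5' end the position to resume from (``seq[cut:]``).  A run qualifies
    when it has >= ``min_run`` identical letters and ends within ``window``
    bases of the terminus; the leftmost (3') / rightmost (5') qualifying run
    wins so that run+junk+run tails are removed in one pass.
    """
    s = seq if three_prime else seq[::-1]
    n = len(s)
    best: int | None = None  # run start in `s` coordinates
    run_start: int | None = None
    run_letter = ""
    for pos in range(n + 1):
        c = s[pos] if pos < n else ""
        if c == run_letter and run_start is not None:
            continue
        if run_start is not None:
            if (pos - run_start) >= min_run and (n - pos) <= window:
                best = run_start if best is None else min(best, run_start)
            run_start = None
            run_letter = ""
        if c in letters:
            run_start = pos
            run_letter = c
    if best is None:
        return None
    return best if three_prime else n - best


def _aligner(minscore: int) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -3
    a.extend_gap_score = -1
    return a


def mask_vector(
    bases: str,
    lib: VectorLibrary,
    minmatch: int = 20,
    minscore: int = 20,
) -> str:
    """Mask vector/adapter hits with ``X`` (cross_match-style thresholds).

    A hit requires an exact shared word of >= ``minmatch`` bp (the seed) and
    a local alignment score >= ``minscore`` under +1 match / -2 mismatch /
    -3 gap open / -1 gap extend.  Both strands of every vector entry are
    searched; masking is idempotent (X never seeds).
    """
    if minmatch <= 0 or minscore <= 0:
        raise ValueError("minmatch and minscore must be positive")
    if len(bases) < minmatch:
        return bases
    est = bases.upper()
    aligner = _aligner(minscore)
    mask = np.zeros(len(est), dtype=bool)
    # index EST words once
    words: dict[str, list[int]] = {}
    for i in range(len(est) - minmatch + 1):
        w = est[i : i + minmatch]
        if "X" in w or "N" in w:
            continue
        words.setdefault(w, []).append(i)
    for _name, vec in lib.entries:
        for strand_seq in (vec.upper(), revcomp(vec.upper())):
            seed_spans = _seed_spans(strand_seq, words, minmatch)
            for est_lo, est_hi, vec_lo, vec_hi in seed_spans:
                ext = 60
                wa, wb = max(0, est_lo - ext), min(len(est), est_hi + ext)
                va, vb = max(0, vec_lo - ext), min(len(strand_seq), vec_hi + ext)
                target = est[wa:wb].replace("X", "N")
                alns = aligner.align(target, strand_seq[va:vb])
                if alns.score >= minscore:
                    aln = alns[0]
                    t0 = int(aln.aligned[0][0][0])
                    t1 = int(aln.aligned[0][-1][1])
                    mask[wa + t0 : wa + t1] = True
    if not mask.any():
        return bases
    chars = np.array(list(bases))
    chars[mask] = "X"
    return "".join(chars)


def _seed_spans(
    vec: str, est_words: dict[str, list[int]], k: int
) -> list[tuple[int, int, int, int]]:
    """Maximal exact seed regions shared by the EST word index and `vec`.

    Returns merged (est_lo, est_hi, vec_lo, vec_hi) spans, grouped per
    diagonal so overlapping k-mer hits collapse to one seed region.
    """
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for j in range(len(vec) - k + 1):
        w = vec[j : j + k]
        for i in est_words.get(w, ()):
            by_diag.setdefault(i - j, []).append((i, j))
    spans = []
    for hits in by_diag.values():
        hits.sort()
        lo_i, lo_j = hits[0]
        hi_i = lo_i + k
        for i, j in hits[1:]:
            if i <= hi_i:  # contiguous/overlapping on the same diagonal
                hi_i = max(hi_i, i + k)
            else:
                spans.append((lo_i, hi_i, lo_j, lo_j + (hi_i - lo_i)))
                lo_i, lo_j = i, j
                hi_i = i + k
        spans.append((lo_i, hi_i, lo_j, lo_j + (hi_i - lo_i)))
    return spans


def clean_est(
    raw: RawEST,
    config: CleaningConfig = CleaningConfig(),
    vector_lib: VectorLibrary | None = None,
) -> CleanEST | Rejection:
    """Run the full cleaning cascade on one record.

    Order: quality trim -> vector mask + excision (longest unmasked fragment
    kept) -> terminal polyA/polyT/X trim -> minimum-length filter.  Records
    without qualities skip the quality stage.  Returns a :class:`CleanEST`
    or a :class:`Rejection` with reason ``too_short``, ``fully_masked`` or
    ``fully_low_quality``.
    """
    trims: list[tuple[str, tuple[int, int]]] = []
    n = len(raw.bases)
    lo, hi = 0, n

    if raw.quals is not None:
        lo, hi = mott_quality_trim(raw.quals, config.error_cutoff)
        if hi <= lo:
            return Rejection(raw.id, "fully_low_quality", n)
        if lo > 0:
            trims.append(("quality", (0, lo)))
        if hi < n:
            trims.append(("quality", (hi, n)))
    seq = raw.bases[lo:hi]

    if vector_lib is not None and vector_lib.entries:
        seq = mask_vector(seq, vector_lib, config.minmatch, config.minscore)

    if "X" in seq or "x" in seq:
        # excise masked/pre-masked spans, keeping the longest clean fragment
        frag = _longest_unmasked(seq.upper())
        if frag is None:
            return Rejection(raw.id, "fully_masked", n, (lo, hi))
        fa, fb = frag
        if fa > 0:
            trims.append(("vector", (lo, lo + fa)))
        if fb < len(seq):
            trims.append(("vector", (lo + fb, hi)))
        lo, hi = lo + fa, lo + fb
        seq = raw.bases[lo:hi]

    polya = trim_terminal_homopolymer(seq, {"A"}, config.min_run, config.window, "3p")
    if len(polya) < len(seq):
        trims.append(("polyA", (lo + len(polya), hi)))
        hi = lo + len(polya)
        seq = polya
    polyt = trim_terminal_homopolymer(seq, {"T"}, config.min_run, config.window, "5p")
    if len(polyt) < len(seq):
        cut = len(seq) - len(polyt)
        trims.append(("polyT", (lo, lo + cut)))
        lo += cut
        seq = polyt

    if len(seq) < config.min_length:
        return Rejection(raw.id, "too_short", n, (lo, hi))
    return CleanEST(raw.id, seq, tuple(trims), (lo, hi))


def _longest_unmasked(masked: str) -> tuple[int, int] | None:
    """Longest maximal X-free interval, leftmost on ties; None if all X."""
    best = None
    start = None
    for i, c in enumerate(masked + "X"):
        if c == "X":
            if start is not None:
                if best is None or (i - start) > (best[1] - best[0]):
                    best = (start, i)
                start = None
        elif start is None:
            start = i
    return best
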