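"""Segment transcripts and design PCR primer pairs under Primer3-style bounds.

Each query transcript is cut into ~300 bp segments (randomly jittered or
strictly tiled) whose union covers the whole sequence, and primer pairs are
designed inside every segment by exhaustive enumeration: all 18-20-mer
placements are screened against hard bounds on GC content (45-65%), melting
temperature (57-62 deg C, nearest-neighbor) and product size (100-250 bp),
then ranked by a weighted distance from the optima (20 bp, 50% GC, 58 deg C).
Segments are short enough (<~360 bp) that exhaustive search is cheap and
exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode, gc_fraction, revcomp

__all__ = [
    "Segment",
    "PrimerConstraints",
    "PrimerPair",
    "segment_est",
    "gc_fraction",
    "melting_temp",
    "primer_penalty",
    "design_primer_pairs",
    "design_for_transcript",
    "coverage_gaps",
]


@dataclass(frozen=True)
class Segment:
    """A window of a query transcript (0-based half-open coordinates)."""

    source_id: str
    start: int
    end: int
    bases: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad segment interval [{self.start}, {self.end})")
        if len(self.bases) != self.end - self.start:
            raise ValueError("segment bases do not match its interval")


@dataclass(frozen=True)
class PrimerConstraints:
    """Hard bounds and optima for primer selection.

    Defaults: primers 18-20 bp (optimum 20), GC 0.45-0.65 (optimum 0.50),
    Tm 57-62 deg C (optimum 58), product 100-250 bp.
    """

    len_min: int = 18
    len_opt: int = 20
    len_max: int = 20
    gc_min: float = 0.45
    gc_opt: float = 0.50
    gc_max: float = 0.65
    tm_min: float = 57.0
    tm_opt: float = 58.0
    tm_max: float = 62.0
    product_min: int = 100
    product_max: int = 250
    # penalty weights per unit: bp of length, 10 percentage points of GC, deg C
    w_len: float = 1.0
    w_gc: float = 1.0
    w_tm: float = 1.0

    def __post_init__(self) -> None:
        for lo, opt, hi in (
            (self.len_min, self.len_opt, self.len_max),
            (self.gc_min, self.gc_opt, self.gc_max),
            (self.tm_min, self.tm_opt, self.tm_max),
        ):
            if not lo <= opt <= hi:
                raise ValueError("constraint triple must satisfy min <= opt <= max")
        if not self.product_min < self.product_max:
            raise ValueError("product_min must be < product_max")


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair with its expected amplicon on the query.

    ``rev_seq`` is the primer as synthesized (reverse-complement strand), so
    ``revcomp(rev_seq) == query[rev_end - len(rev_seq) : rev_end]``.
    ``expected_size == rev_end - fwd_start``.
    """

    pair_id: str
    source_id: str
    fwd_seq: str
    rev_seq: str
    fwd_start: int
    rev_end: int
    expected_size: int
    penalty: float
    fwd_tm: float = 0.0
    rev_tm: float = 0.0
    fwd_gc: float = 0.0
    rev_gc: float = 0.0


def segment_est(
    bases: str,
    source_id: str,
    target_len: int = 300,
    overlap: int = 60,
    mode: str = "random",
    seed: int = 0,
) -> list[Segment]:
    """Cut a transcript into overlapping segments covering [0, len).

    ``tiled`` mode advances by exactly ``target_len - overlap``; ``random``
    mode jitters each segment length within +-20% of ``target_len``
    (deterministically for a given seed).  The union of segments always
    covers the full sequence and adjacent segments overlap by >= ``overlap``.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    if not 0 <= overlap < target_len:
        raise ValueError("overlap must be in [0, target_len)")
    n = len(bases)
    if n == 0:
        return []
    if n <= target_len:
        return [Segment(source_id, 0, n, bases)]
    rng = np.random.default_rng(seed)
    jitter = int(round(0.2 * target_len))
    segments: list[Segment] = []
    start = 0
    while True:
        if mode == "random" and jitter > 0:
            seg_len = target_len + int(rng.integers(-jitter, jitter + 1))
        elif mode in ("random", "tiled"):
            seg_len = target_len
        else:
            raise ValueError(f"unknown segmentation mode {mode!r}")
        seg_len = max(seg_len, overlap + 1)
        end = min(start + seg_len, n)
        if n - end < (target_len - overlap) // 2:
            end = n  # absorb a tiny remainder into the final segment
        segments.append(Segment(source_id, start, end, bases[start:end]))
        if end >= n:
            return segments
        start = end - overlap


# Unified nearest-neighbor parameters (Allawi & SantaLucia 1997 / SantaLucia
# 1998): (delta-H kcal/mol, delta-S cal/mol/K) per propagation step, indexed
# by dinucleotide code 4*first+second with A=0, C=1, G=2, T=3.
_NN_DH = np.zeros(16)
_NN_DS = np.zeros(16)
for _din, (_dh, _ds) in {
    "AA": (-7.9, -22.2), "AC": (-8.4, -22.4), "AG": (-7.8, -21.0),
    "AT": (-7.2, -20.4), "CA": (-8.5, -22.7), "CC": (-8.0, -19.9),
    "CG": (-10.6, -27.2), "CT": (-7.8, -21.0), "GA": (-8.2, -22.2),
    "GC": (-9.8, -24.4), "GG": (-8.0, -19.9), "GT": (-8.4, -22.4),
    "TA": (-7.2, -21.3), "TC": (-8.2, -22.2), "TG": (-8.5, -22.7),
    "TT": (-7.9, -22.2),
}.items():
    _idx = 4 * "ACGT".index(_din[0]) + "ACGT".index(_din[1])
    _NN_DH[_idx] = _dh
    _NN_DS[_idx] = _ds
# terminal-basepair initiation: A/T ends vs G/C ends
_END_DH = np.array([2.3, 0.1, 0.1, 2.3])
_END_DS = np.array([4.1, -2.8, -2.8, 4.1])
_SYM_DS = -1.4  # self-complementary duplex entropy correction
_GAS_R = 1.987  # cal / (mol K)
# design conditions: 50 mM monovalent salt, 50 nM primer, no complement strand
_SALT_M = 0.05
_CONC_K = 50e-9


def _tm_windows(codes: np.ndarray, length: int) -> np.ndarray:
    """Nearest-neighbor Tm (deg C) of every window of ``length`` in ``codes``.

    Windows containing non-ACGT codes get NaN.  Values are rounded to 1e-4
    deg C so scalar and batch evaluation of the same oligo agree exactly.
    """
    n = codes.size
    if n < length:
        return np.empty(0)
    valid_cum = np.concatenate(([0], np.cumsum(codes >= 4)))
    ok = (valid_cum[length:] - valid_cum[:-length]) == 0
    c = np.where(codes >= 4, 0, codes).astype(np.intp)
    din = 4 * c[:-1] + c[1:]
    dh_cum = np.concatenate(([0.0], np.cumsum(_NN_DH[din])))
    ds_cum = np.concatenate(([0.0], np.cumsum(_NN_DS[din])))
    k = length - 1  # propagation steps per window
    dh = dh_cum[k:] - dh_cum[: n - k]
    ds = ds_cum[k:] - ds_cum[: n - k]
    first = c[: n - k]
    last = c[k:]
    dh = dh + _END_DH[first] + _END_DH[last]
    ds = ds + _END_DS[first] + _END_DS[last]
    # self-complementary windows bind themselves: entropy of symmetry
    rc = 3 - c
    win = np.lib.stride_tricks.sliding_window_view(c, length)
    win_rc_rev = np.lib.stride_tricks.sliding_window_view(rc, length)[:, ::-1]
    selfcomp = (win == win_rc_rev).all(axis=1)
    ds = ds + np.where(selfcomp, _SYM_DS, 0.0)
    ds = ds + 0.368 * k * np.log(_SALT_M)
    tm = (1000.0 * dh) / (ds + _GAS_R * np.log(_CONC_K)) - 273.15
    tm = np.round(tm, 4)
    return np.where(ok, tm, np.nan)


def melting_temp(seq: str, method: str = "nearest_neighbor") -> float:
    """Primer melting temperature in deg C.

    ``nearest_neighbor`` uses SantaLucia (1998) unified thermodynamics at
    50 mM monovalent salt and 50 nM primer (no complement strand), the
    conditions assumed for all design bounds.  ``wallace`` is the 2(A+T)+4(G+C)
    rule-of-thumb, kept for cross-checks on short oligos.
    """
    s = seq.upper()
    if not s or any(c not in "ACGT" for c in s):
        raise ValueError(f"melting_temp requires a non-empty ACGT string: {seq!r}")
    if method == "wallace":
        return float(2 * (s.count("A") + s.count("T")) + 4 * (s.count("G") + s.count("C")))
    if method != "nearest_neighbor":
        raise ValueError(f"unknown Tm method {method!r}")
    if not 8 <= len(s) <= 36:
        raise ValueError("nearest_neighbor Tm supported for 8-36 nt oligos")
    return float(_tm_windows(encode(s), len(s))[0])


def primer_penalty(
    seq: str, constraints: PrimerConstraints = PrimerConstraints()
) -> float | None:
    """Weighted distance from the design optima, or None if infeasible.

    Infeasible iff any hard bound (length, GC, Tm) is violated.  Otherwise
    ``penalty = w_len*|len-opt| + w_gc*|GC%-opt%|/10 + w_tm*|Tm-opt|`` and is
    zero exactly when every attribute sits at its optimum.
    """
    c = constraints
    if any(b not in "ACGT" for b in seq.upper()):
        return None
    n = len(seq)
    if not c.len_min <= n <= c.len_max:
        return None
    gc = gc_fraction(seq)
    if not c.gc_min <= gc <= c.gc_max:
        return None
    tm = melting_temp(seq)
    if not c.tm_min <= tm <= c.tm_max:
        return None
    return (
        c.w_len * abs(n - c.len_opt)
        + c.w_gc * abs(gc - c.gc_opt) * 10.0
        + c.w_tm * abs(tm - c.tm_opt)
    )


def _window_attrs(codes: np.ndarray, length: int, c: PrimerConstraints):
    """Per-window (penalty, tm, gc, feasible) arrays for one primer length.

    A window and its reverse complement form the same duplex, so Tm, GC and
    penalty apply to both the forward primer (the window itself) and the
    reverse primer (its reverse complement) anchored on the same site.
    """
    tm = _tm_windows(codes, length)
    if tm.size == 0:
        return tm, tm, tm, np.zeros(0, dtype=bool)
    gc_cum = np.concatenate(([0], np.cumsum((codes == 1) | (codes == 2))))
    gc = (gc_cum[length:] - gc_cum[:-length]) / float(length)
    with np.errstate(invalid="ignore"):
        pen = (
            c.w_len * abs(length - c.len_opt)
            + c.w_gc * np.abs(gc - c.gc_opt) * 10.0
            + c.w_tm * np.abs(tm - c.tm_opt)
        )
        feasible = (
            ~np.isnan(tm)
            & (tm >= c.tm_min)
            & (tm <= c.tm_max)
            & (gc >= c.gc_min)
            & (gc <= c.gc_max)
        )
    return pen, tm, gc, feasible


def design_primer_pairs(
    segment: Segment,
    constraints: PrimerConstraints = PrimerConstraints(),
    n_best: int = 2,
) -> list[PrimerPair]:
    """Best primer pairs in a segment by exhaustive enumeration.

    Every feasible (forward, reverse) placement with a product size inside
    the bounds and non-overlapping primer sites is scored by the sum of the
    two primer penalties; pairs are ranked by (penalty, fwd_start, rev_end,
    fwd_len, rev_len) and up to ``n_best`` pairs with distinct amplicon
    intervals are returned.  An infeasible segment yields an empty list.
    """
    c = constraints
    seg = segment.bases.upper()
    codes = encode(seg)
    starts, lens, pens = [], [], []
    for length in range(c.len_min, c.len_max + 1):
        pen, _tm, _gc, feasible = _window_attrs(codes, length, c)
        idx = np.flatnonzero(feasible)
        starts.append(idx)
        lens.append(np.full(idx.size, length))
        pens.append(pen[idx])
    if not starts:
        return []
    cs = np.concatenate(starts)
    cl = np.concatenate(lens)
    cp = np.concatenate(pens)
    if cs.size == 0:
        return []
    # the same feasible windows serve as forward primers and (reverse
    # complemented) reverse primers
    fs, fl, fp = cs[:, None], cl[:, None], cp[:, None]
    rs, rl, rp = cs[None, :], cl[None, :], cp[None, :]
    re_ = rs + rl
    size = re_ - fs
    ok = (
        (size >= c.product_min)
        & (size <= c.product_max)
        & (rs >= fs + fl)  # primer sites must not overlap
    )
    fi, ri = np.nonzero(ok)
    if fi.size == 0:
        return []
    pen_tot = cp[fi] + cp[ri]
    key_fs = cs[fi]
    key_re = cs[ri] + cl[ri]
    order = np.lexsort((cl[ri], cl[fi], key_re, key_fs, pen_tot))
    pairs: list[PrimerPair] = []
    seen: set[tuple[int, int]] = set()
    for j in order:
        f, r = fi[j], ri[j]
        amp = (segment.start + int(cs[f]), segment.start + int(cs[r] + cl[r]))
        if amp in seen:
            continue
        seen.add(amp)
        fseq = seg[cs[f] : cs[f] + cl[f]]
        rsite = seg[cs[r] : cs[r] + cl[r]]
        k = len(pairs)
        pairs.append(
            PrimerPair(
                pair_id=f"{segment.source_id}:{segment.start}-{segment.end}:p{k}",
                source_id=segment.source_id,
                fwd_seq=fseq,
                rev_seq=revcomp(rsite),
                fwd_start=amp[0],
                rev_end=amp[1],
                expected_size=amp[1] - amp[0],
                penalty=round(float(pen_tot[j]), 6),
                fwd_tm=melting_temp(fseq),
                rev_tm=melting_temp(revcomp(rsite)),
                fwd_gc=round(gc_fraction(fseq), 6),
                rev_gc=round(gc_fraction(rsite), 6),
            )
        )
        if len(pairs) >= n_best:
            break
    return pairs


def design_for_transcript(
    bases: str,
    source_id: str,
    constraints: PrimerConstraints = PrimerConstraints(),
    target_len: int = 300,
    overlap: int = 60,
    mode: str = "random",
    seed: int = 0,
    n_best: int = 2,
) -> tuple[list[PrimerPair], list[tuple[int, int]]]:
    """Segment a transcript and design pairs in every segment.

    Returns the designed pairs plus the list of coverage gaps: maximal
    intervals of the transcript not covered by any designed amplicon
    (reported, never silently dropped).
    """
    pairs: list[PrimerPair] = []
    for seg in segment_est(bases, source_id, target_len, overlap, mode, seed):
        pairs.extend(design_primer_pairs(seg, constraints, n_best))
    return pairs, coverage_gaps(len(bases), pairs)


def coverage_gaps(length: int, pairs: list[PrimerPair]) -> list[tuple[int, int]]:
    """Maximal intervals of [0, length) not covered by any amplicon."""
    if length <= 0:
        return []
    ivs = sorted((p.fwd_start, p.rev_end) for p in pairs)
    gaps = []
    pos = 0
    for a, b in ivs:
        if a > pos:
            gaps.append((pos, a))
        pos = max(pos, b)
    if pos < length:
        gaps.append((pos, length))
    return gaps
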