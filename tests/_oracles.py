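"""Independent reference implementations used only by the tests.

Each oracle is a deliberately naive second implementation (brute force,
exhaustive enumeration, or a hand-coded published formula) kept separate
from the package's code paths.
"""

from __future__ import annotations

import math


def brute_force_scan(
    primer: str, target: str, max_mismatch: int, anchor3: int = 0
) -> list[tuple[int, str, int]]:
    """Every-offset, both-strand Hamming scan; returns (offset, strand, mism)."""
    comp = str.maketrans("ACGT", "TGCA")
    prc = primer.translate(comp)[::-1]
    m = len(primer)
    hits = []
    for offset in range(len(target) - m + 1):
        site = target[offset : offset + m]
        for strand, probe in (("+", primer), ("-", prc)):
            mism = [
                a != b or a not in "ACGT" or b not in "ACGT"
                for a, b in zip(probe, site)
            ]
            if sum(mism) > max_mismatch:
                continue
            if anchor3:
                anchored = mism[-anchor3:] if strand == "+" else mism[:anchor3]
                if any(anchored):
                    continue
            hits.append((offset, strand, sum(mism)))
    hits.sort()
    return hits


def best_quality_interval(quals, error_cutoff: float) -> tuple[int, int]:
    """All-intervals maximizer for the Mott trimming score (O(n^2))."""
    prefix = [0.0]
    for q in quals:
        prefix.append(prefix[-1] + (error_cutoff - 10.0 ** (-q / 10.0)))
    best_val = 0.0
    best = (0, 0)
    for s in range(len(quals) + 1):
        for e in range(s + 1, len(quals) + 1):
            val = prefix[e] - prefix[s]
            if val <= 0.0:
                continue
            if val > best_val or (
                val == best_val and (s < best[0] or (s == best[0] and e > best[1]))
            ):
                best_val = val
                best = (s, e)
    return best


# SantaLucia (1998) unified nearest-neighbor parameters, transcribed by hand
# from the published table: kcal/mol and cal/(mol K) per propagation step.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def nn_tm(seq: str, na_mM: float = 50.0, primer_nM: float = 50.0) -> float:
    """Hand-coded SantaLucia-98 nearest-neighbor Tm with entropy salt term."""
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    comp = str.maketrans("ACGT", "TGCA")
    if seq.translate(comp)[::-1] == seq:
        ds += -1.4
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    k = primer_nM * 1e-9
    return 1000.0 * dh / (ds + 1.987 * math.log(k)) - 273.15


def exhaustive_pair_search(segment_bases, segment_start, source_id, constraints,
                           n_best, penalty_fn):
    """From-scratch exhaustive primer-pair search over a segment.

    ``penalty_fn(seq) -> float | None`` supplies feasibility + penalty so the
    oracle checks the search/selection logic independently of the scoring
    primitives.  Returns [(penalty, fwd_start, rev_end, fwd_len, rev_len)]
    in the package's documented ranking with distinct amplicons.
    """
    comp = str.maketrans("ACGT", "TGCA")
    c = constraints
    candidates = []
    for length in range(c.len_min, c.len_max + 1):
        for start in range(len(segment_bases) - length + 1):
            window = segment_bases[start : start + length]
            pen = penalty_fn(window)
            if pen is not None:
                candidates.append((start, length, pen))
    pairs = []
    for fs, fl, fpen in candidates:
        for rs, rl, rpen in candidates:
            size = rs + rl - fs
            if not c.product_min <= size <= c.product_max:
                continue
            if rs < fs + fl:
                continue
            pairs.append((fpen + rpen, fs, rs + rl, fl, rl))
    pairs.sort()
    chosen = []
    seen = set()
    for item in pairs:
        amp = (item[1], item[2])
        if amp in seen:
            continue
        seen.add(amp)
        chosen.append(
            (item[0], segment_start + item[1], segment_start + item[2], item[3], item[4])
        )
        if len(chosen) >= n_best:
            break
    return chosen
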