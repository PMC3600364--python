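"""Small shared sequence helpers (encoding, reverse complement)."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNXacgtnx", "TGCANXtgcanx")

# A/C/G/T -> 0..3; N -> 4; anything else -> 5.  Codes >= 4 never match.
_CODE = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N,X} alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, N=4, other=5)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_fraction(seq: str) -> float:
    """(#G + #C) / len; N and other ambiguity codes count as non-GC.

    Raises ValueError on the empty string: a GC content of nothing is
    undefined and always indicates an upstream bug.
    """
    if not seq:
        raise ValueError("gc_fraction of empty sequence is undefined")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)
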