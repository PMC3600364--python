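"""Collapse raw size-variant calls into unique InDel loci and select markers.

Nested primer pairs and multiple target copies hit the same underlying
event repeatedly, so raw calls are grouped into loci: calls on the same
query (or the same query cluster, when an assembly-derived clustering is
supplied) whose amplicon intervals overlap form one locus.  The locus keeps
the set of distinct signed deltas seen across targets — an orthologous event
shows one delta, homoeologous copies can contribute several.

Loci are binned by their largest absolute delta into the conventional size
classes (1 bp, 2-4 bp, 5-10 bp, >10 bp), and loci with max |delta| >= 5 bp
(the practical gel-resolvable cutoff) are exported as markers.  Band-pattern
classification mirrors gel genotyping of two species: orthologous
polymorphism (one distinct band per species), homoeologous polymorphism
(multiple bands, differing multisets), monomorphism, or amplification
failure.
"""

from __future__ import annotations

from dataclasses import dataclass

from .insilico_pcr import InDelCall
from .primer_design import PrimerPair

__all__ = [
    "InDelLocus",
    "SizeBinSummary",
    "MarkerRecord",
    "BandPattern",
    "collapse_redundant",
    "bin_sizes",
    "select_markers",
    "classify_band_pattern",
    "summarize_catalog",
]


@dataclass(frozen=True)
class InDelLocus:
    """A redundancy-collapsed InDel event region on a query transcript.

    ``query_interval`` is the union of the contributing amplicon intervals
    (0-based half-open on the query); ``delta_intervals`` retains, per
    distinct delta, the tightest amplicon interval that produced it.
    """

    locus_id: str
    query_id: str
    query_interval: tuple[int, int]
    delta_set: frozenset[int]
    support: int
    representative_pair: str
    delta_intervals: tuple[tuple[int, tuple[int, int]], ...] = ()

    @property
    def max_abs_delta(self) -> int:
        return max(abs(d) for d in self.delta_set)


@dataclass(frozen=True)
class SizeBinSummary:
    """Locus counts by size class plus mean/max of per-locus max |delta|."""

    n_1bp: int
    n_2_4bp: int
    n_5_10bp: int
    n_gt10bp: int
    total: int
    mean_abs_delta: float
    max_abs_delta: int


@dataclass(frozen=True)
class MarkerRecord:
    """An exportable InDel marker row (loci with max |delta| >= cutoff)."""

    marker_id: str
    query_id: str
    fwd_seq: str
    rev_seq: str
    expected_size_query: int
    observed_sizes_target: tuple[int, ...]
    max_abs_delta: int


@dataclass(frozen=True)
class BandPattern:
    """Product sizes one accession shows for one marker (possibly none)."""

    accession: str
    bands: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.bands):
            raise ValueError("band sizes must be positive")


def collapse_redundant(
    calls: list[InDelCall],
    pairs: dict[str, PrimerPair],
    query_clusters: dict[str, str] | None = None,
) -> list[InDelLocus]:
    """Merge raw calls into unique loci.

    Calls join the same locus when they belong to the same query cluster
    (same ``query_id`` if no clustering is given) and their query amplicon
    intervals overlap; the locus accumulates support and the set of deltas.
    Output is sorted by (query_id, interval) and the operation is idempotent.
    """
    keyed: dict[str, list[tuple[tuple[int, int], InDelCall]]] = {}
    for call in calls:
        pair = pairs.get(call.pair_id)
        if pair is None:
            raise KeyError(f"call references unknown pair_id {call.pair_id!r}")
        cluster = (
            query_clusters.get(call.query_id, call.query_id)
            if query_clusters
            else call.query_id
        )
        keyed.setdefault(cluster, []).append(
            ((pair.fwd_start, pair.rev_end), call)
        )
    loci: list[InDelLocus] = []
    for cluster in sorted(keyed):
        group = sorted(keyed[cluster], key=lambda t: (t[0], t[1].pair_id, t[1].target_id))
        # sweep: overlap-connected components of intervals
        comp: list[tuple[tuple[int, int], InDelCall]] = []
        hi = None
        for iv, call in group:
            if hi is not None and iv[0] >= hi:
                loci.append(_component_to_locus(comp))
                comp = []
                hi = None
            comp.append((iv, call))
            hi = iv[1] if hi is None else max(hi, iv[1])
        if comp:
            loci.append(_component_to_locus(comp))
    loci.sort(key=lambda l: (l.query_id, l.query_interval))
    return loci


def _component_to_locus(comp: list[tuple[tuple[int, int], InDelCall]]) -> InDelLocus:
    lo = min(iv[0] for iv, _ in comp)
    hi = max(iv[1] for iv, _ in comp)
    qid = min(c.query_id for _, c in comp)
    tightest: dict[int, tuple[int, int]] = {}
    for iv, c in comp:
        cur = tightest.get(c.delta)
        if cur is None or (iv[1] - iv[0], iv) < (cur[1] - cur[0], cur):
            tightest[c.delta] = iv
    rep = comp[0][1].pair_id
    return InDelLocus(
        locus_id=f"{qid}:{lo}-{hi}",
        query_id=qid,
        query_interval=(lo, hi),
        delta_set=frozenset(c.delta for _, c in comp),
        support=len(comp),
        representative_pair=rep,
        delta_intervals=tuple(sorted(tightest.items())),
    )


def bin_sizes(loci: list[InDelLocus]) -> SizeBinSummary:
    """Bin loci by max |delta| into {1, 2-4, 5-10, >10} bp classes."""
    sizes = [l.max_abs_delta for l in loci]
    return SizeBinSummary(
        n_1bp=sum(s == 1 for s in sizes),
        n_2_4bp=sum(2 <= s <= 4 for s in sizes),
        n_5_10bp=sum(5 <= s <= 10 for s in sizes),
        n_gt10bp=sum(s > 10 for s in sizes),
        total=len(sizes),
        mean_abs_delta=(sum(sizes) / len(sizes)) if sizes else 0.0,
        max_abs_delta=max(sizes, default=0),
    )


def select_markers(
    loci: list[InDelLocus],
    pairs: dict[str, PrimerPair],
    min_marker_delta: int = 5,
) -> list[MarkerRecord]:
    """Markers: exactly the loci with max |delta| >= ``min_marker_delta``.

    The cutoff is inclusive (a 5 bp event at the default is a marker).  Each
    marker joins its locus to the representative primer pair; a locus naming
    an unknown pair is a consistency error.
    """
    out = []
    for i, locus in enumerate(loci):
        if locus.max_abs_delta < min_marker_delta:
            continue
        pair = pairs.get(locus.representative_pair)
        if pair is None:
            raise KeyError(
                f"locus {locus.locus_id} references unknown pair "
                f"{locus.representative_pair!r}"
            )
        observed = tuple(
            pair.expected_size + d for d in sorted(locus.delta_set)
        )
        out.append(
            MarkerRecord(
                marker_id=f"IND{i + 1:05d}",
                query_id=locus.query_id,
                fwd_seq=pair.fwd_seq,
                rev_seq=pair.rev_seq,
                expected_size_query=pair.expected_size,
                observed_sizes_target=observed,
                max_abs_delta=locus.max_abs_delta,
            )
        )
    return out


def _pooled_bands(patterns: list[BandPattern], tol: int) -> list[int]:
    """Distinct band sizes of one species, merging bands within ``tol`` bp."""
    sizes = sorted(b for p in patterns for b in p.bands)
    merged: list[int] = []
    for s in sizes:
        if merged and s - merged[-1] <= tol:
            continue
        merged.append(s)
    return merged


def _same_bands(a: list[int], b: list[int], tol: int) -> bool:
    return len(a) == len(b) and all(abs(x - y) <= tol for x, y in zip(a, b))


def classify_band_pattern(
    species_a: list[BandPattern],
    species_b: list[BandPattern],
    size_tolerance: int = 0,
) -> str:
    """Classify a marker's two-species banding pattern.

    * ``failure`` — no bands in either species;
    * ``type3_monomorphic`` — the pooled band sets agree within tolerance;
    * ``type1_orthologous`` — a single, distinct band per species;
    * ``type2_homoeologous`` — any species shows multiple bands (duplicated
      subgenome copies) and the band sets differ.

    When only one species amplifies, the call follows its band count
    (single -> type1, multiple -> type2).  Symmetric in species order and
    invariant to band ordering; ``size_tolerance`` 0 suits in silico sizes.
    """
    if size_tolerance < 0:
        raise ValueError("size_tolerance must be >= 0")
    a = _pooled_bands(species_a, size_tolerance)
    b = _pooled_bands(species_b, size_tolerance)
    if not a and not b:
        return "failure"
    if _same_bands(a, b, size_tolerance):
        return "type3_monomorphic"
    if len(a) <= 1 and len(b) <= 1:
        return "type1_orthologous"
    return "type2_homoeologous"


def summarize_catalog(
    loci: list[InDelLocus],
    query_clusters: dict[str, str] | None = None,
) -> tuple[SizeBinSummary, dict[str, int]]:
    """Size-bin summary plus per-cluster locus counts (deterministic order)."""
    summary = bin_sizes(loci)
    counts: dict[str, int] = {}
    for locus in loci:
        cluster = (
            query_clusters.get(locus.query_id, locus.query_id)
            if query_clusters
            else locus.query_id
        )
        counts[cluster] = counts.get(cluster, 0) + 1
    return summary, dict(sorted(counts.items()))
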