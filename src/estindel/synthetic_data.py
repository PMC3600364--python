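"""Synthetic tetraploid EST pairs with fully recorded planted mutations.

Emulates the comparative setting the pipeline is built for: two
allotetraploid species sharing A/D subgenome structure.  Per gene an
ancestral transcript is drawn i.i.d. over ACGT, duplicated into two
homoeologs (the D copy diverged by substitutions), and each homoeolog gains
a species-B ortholog carrying further substitutions plus planted InDels
whose positions and sizes are recorded exactly.  The species-A copies form
the query collection, the species-B copies the target collection, so every
size difference the PCR engine should find is known ground truth.

Raw-EST variants of the query (polyA tails, a synthetic vector fragment,
simulated Phred strings with 3' decay) exercise the cleaning cascade.

The generator also provides the truth-side oracles used in testing:
which planted events are detectable by a given primer-pair set, and
recall / precision / delta-exactness of a called locus set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._seq import revcomp
from .indel_catalog import InDelLocus
from .preprocess import RawEST, VectorLibrary
from .primer_design import PrimerPair

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimResult",
    "EvalResult",
    "simulate_ancestor",
    "mutate",
    "simulate_tetraploid_pair",
    "synthetic_vector_library",
    "detectable_events",
    "evaluate_against_truth",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated tetraploid EST pair.

    Defaults: 200 genes of 400-900 bp (EST-scale transcripts), 3%
    homoeolog divergence, 1% species divergence, ~1 planted InDel per
    transcript with sizes drawn from the empirical size classes (mass
    0.49 / 0.347 / 0.085 / 0.078 on 1 bp / 2-4 bp / 5-10 bp / >10 bp,
    the >10 bp tail truncated-geometric up to 168 bp).
    """

    n_genes: int = 200
    length_min: int = 400
    length_max: int = 900
    homoeolog_divergence: float = 0.03
    species_divergence: float = 0.01
    indel_rate: float = 1.0
    indel_bin_probs: tuple[float, float, float, float] = (0.49, 0.347, 0.085, 0.078)
    indel_tail_p: float = 0.08
    indel_max_size: int = 168
    edge_margin: int = 30
    polya_prob: float = 0.5
    vector_prob: float = 0.2
    qual_mean: float = 50.0
    qual_sd: float = 4.0
    qual_tail_len: int = 60
    qual_tail_floor: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.homoeolog_divergence,
            self.species_divergence,
            self.polya_prob,
            self.vector_prob,
            *self.indel_bin_probs,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.length_min <= 0 or self.length_max < self.length_min:
            raise ValueError("bad transcript length bounds")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class TruthRecord:
    """One planted mutation event, in query (species-A copy) coordinates."""

    event_id: str
    gene_id: str
    copy_label: str
    kind: str  # insertion | deletion | substitution
    query_position: int
    size: int

    @property
    def signed_size(self) -> int:
        """Target-minus-query length change contributed by this event."""
        if self.kind == "insertion":
            return self.size
        if self.kind == "deletion":
            return -self.size
        return 0


@dataclass
class SimResult:
    query: dict[str, str]
    target: dict[str, str]
    truth: list[TruthRecord]
    raw_query: list[RawEST]
    vector_library: VectorLibrary
    config: SimConfig


def simulate_ancestor(length: int, rng: np.random.Generator) -> str:
    """An i.i.d. uniform ACGT transcript of the given length."""
    if length <= 0:
        raise ValueError("length must be positive")
    return "".join(_BASES[rng.integers(0, 4, length)])


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, np.ndarray]:
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), hit


def _draw_indel_size(config: SimConfig, rng: np.random.Generator) -> int:
    bin_idx = rng.choice(4, p=np.asarray(config.indel_bin_probs) / sum(config.indel_bin_probs))
    if bin_idx == 0:
        return 1
    if bin_idx == 1:
        return int(rng.integers(2, 5))
    if bin_idx == 2:
        return int(rng.integers(5, 11))
    size = 11 + int(rng.geometric(config.indel_tail_p)) - 1
    return min(size, config.indel_max_size)


def mutate(
    seq: str,
    sub_rate: float,
    config: SimConfig,
    rng: np.random.Generator,
    gene_id: str = "",
    copy_label: str = "",
    record_substitutions: bool = False,
) -> tuple[str, list[TruthRecord]]:
    """Apply substitutions and planted InDels, recording every InDel.

    Substitutions are i.i.d. per site.  The number of InDels is Poisson
    with mean ``config.indel_rate``; positions avoid the first/last
    ``edge_margin`` bases and never overlap each other, so each recorded
    ``query_position``/``size`` is exact in input coordinates.  The output
    length equals the input length plus the signed sum of planted sizes.
    """
    truth: list[TruthRecord] = []
    mutated, subs = _substitute(seq, sub_rate, rng)
    if record_substitutions:
        truth += [
            TruthRecord(f"{gene_id}:{copy_label}:s{i}", gene_id, copy_label,
                        "substitution", int(p), 1)
            for i, p in enumerate(subs)
        ]
    n = len(seq)
    n_indels = int(rng.poisson(config.indel_rate))
    events: list[tuple[int, str, int]] = []  # (pos, kind, size)
    used: list[tuple[int, int]] = []
    for _ in range(n_indels):
        size = _draw_indel_size(config, rng)
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        span = size if kind == "deletion" else 1
        lo, hi = config.edge_margin, n - config.edge_margin - span
        if hi <= lo:
            continue
        for _attempt in range(20):
            pos = int(rng.integers(lo, hi))
            if all(pos + span <= a or pos >= b for a, b in used):
                used.append((pos, pos + span))
                events.append((pos, kind, size))
                break
    # apply right-to-left so recorded positions stay in input coordinates
    out = mutated
    for pos, kind, size in sorted(events, reverse=True):
        if kind == "deletion":
            out = out[:pos] + out[pos + size :]
        else:
            ins = "".join(_BASES[rng.integers(0, 4, size)])
            out = out[:pos] + ins + out[pos:]
    for i, (pos, kind, size) in enumerate(sorted(events)):
        truth.append(
            TruthRecord(
                f"{gene_id}:{copy_label}:i{i}", gene_id, copy_label, kind, pos, size
            )
        )
    return out, truth


def synthetic_vector_library(seed: int = 7_031) -> VectorLibrary:
    """A small synthetic cloning-vector stand-in (not a real vector sequence)."""
    rng = np.random.default_rng(seed)
    return VectorLibrary(
        entries=(("synthetic_vector_1", simulate_ancestor(600, rng)),)
    )


def simulate_tetraploid_pair(config: SimConfig = SimConfig()) -> SimResult:
    """Generate matched query/target collections plus ground truth.

    Query records are named ``g<idx>_A`` / ``g<idx>_D`` (species-A
    homoeologs); target records append ``_sp2`` (species-B orthologs).
    Raw query variants optionally carry a polyA tail, a 5' vector fragment
    and simulated quality strings.
    """
    rng = np.random.default_rng(config.seed)
    vec_lib = synthetic_vector_library()
    vec_seq = vec_lib.entries[0][1]
    query: dict[str, str] = {}
    target: dict[str, str] = {}
    truth: list[TruthRecord] = []
    raw_query: list[RawEST] = []
    for g in range(config.n_genes):
        gene = f"g{g:04d}"
        length = int(rng.integers(config.length_min, config.length_max + 1))
        ancestor = simulate_ancestor(length, rng)
        copies = {"A": ancestor}
        copies["D"], _ = _substitute(ancestor, config.homoeolog_divergence, rng)
        for sub, qseq in copies.items():
            qid = f"{gene}_{sub}"
            query[qid] = qseq
            tseq, events = mutate(
                qseq,
                config.species_divergence,
                config,
                rng,
                gene_id=gene,
                copy_label=f"{sub}_sp2",
            )
            target[f"{qid}_sp2"] = tseq
            truth += events
            raw_query.append(_raw_variant(qid, qseq, vec_seq, config, rng))
    return SimResult(query, target, truth, raw_query, vec_lib, config)


def _raw_variant(
    qid: str, seq: str, vec: str, config: SimConfig, rng: np.random.Generator
) -> RawEST:
    bases = seq
    if rng.random() < config.vector_prob:
        frag_len = int(rng.integers(30, 80))
        start = int(rng.integers(0, len(vec) - frag_len))
        bases = vec[start : start + frag_len] + bases
    if rng.random() < config.polya_prob:
        bases = bases + "A" * int(rng.integers(10, 31))
    n = len(bases)
    quals = rng.normal(config.qual_mean, config.qual_sd, n)
    tail = min(config.qual_tail_len, n)
    decay = np.linspace(0.0, 1.0, tail)
    quals[n - tail :] -= decay * (config.qual_mean - config.qual_tail_floor)
    quals = np.clip(np.rint(quals), 0, 60).astype(int)
    return RawEST(qid, bases, tuple(int(q) for q in quals))


# ---------------------------------------------------------------------------
# truth-side oracles


@dataclass(frozen=True)
class EvalResult:
    recall: float
    precision: float
    exactness: float
    n_truth: int
    n_recovered: int
    n_loci: int
    n_correct_loci: int


def _gene_of(query_id: str) -> str:
    return query_id.rsplit("_", 1)[0]


def _events_by_copy(
    truth: list[TruthRecord],
) -> dict[str, dict[str, list[TruthRecord]]]:
    out: dict[str, dict[str, list[TruthRecord]]] = {}
    for ev in truth:
        if ev.kind == "substitution":
            continue
        out.setdefault(ev.gene_id, {}).setdefault(ev.copy_label, []).append(ev)
    for copies in out.values():
        for evs in copies.values():
            evs.sort(key=lambda e: e.query_position)
    return out


def detectable_events(
    truth: list[TruthRecord],
    pairs: list[PrimerPair],
    query: dict[str, str],
    target: dict[str, str],
    max_mismatch: int = 2,
    anchor3: int = 1,
) -> set[str]:
    """Planted InDels a perfect size-difference caller could report.

    An event is detectable iff some designed pair on its query copy (a)
    contains the event strictly between its primer sites, (b) has both
    primer sites free of InDels on the target copy, with at most
    ``max_mismatch`` substitutions each and an intact 3' anchor, and (c)
    sees a non-zero net size change inside the amplicon.  Computed purely
    from coordinates and direct string comparison — the PCR engine is never
    invoked.
    """
    by_copy = _events_by_copy(truth)
    pairs_by_query: dict[str, list[PrimerPair]] = {}
    for p in pairs:
        pairs_by_query.setdefault(p.source_id, []).append(p)
    detectable: set[str] = set()
    for gene, copies in by_copy.items():
        for copy_label, events in copies.items():
            sub = copy_label.split("_", 1)[0]
            qid = f"{gene}_{sub}"
            tid = f"{qid}_sp2"
            if qid not in query or tid not in target:
                continue
            tseq = target[tid]
            for ev in events:
                for pair in pairs_by_query.get(qid, ()):
                    if _pair_detects(pair, ev, events, tseq, max_mismatch, anchor3):
                        detectable.add(ev.event_id)
                        break
    return detectable


def _pair_detects(
    pair: PrimerPair,
    ev: TruthRecord,
    events: list[TruthRecord],
    tseq: str,
    max_mismatch: int,
    anchor3: int,
) -> bool:
    lf, lr = len(pair.fwd_seq), len(pair.rev_seq)
    inner_lo = pair.fwd_start + lf
    inner_hi = pair.rev_end - lr
    span = ev.size if ev.kind == "deletion" else 0
    if not (inner_lo <= ev.query_position and ev.query_position + span <= inner_hi):
        return False
    fwd_site = (pair.fwd_start, pair.fwd_start + lf)
    rev_site = (pair.rev_end - lr, pair.rev_end)
    for other in events:
        ospan = other.size if other.kind == "deletion" else 0
        for lo, hi in (fwd_site, rev_site):
            if other.kind == "deletion":
                if other.query_position < hi and other.query_position + ospan > lo:
                    return False
            elif lo < other.query_position < hi:
                return False
    net = sum(
        e.signed_size
        for e in events
        if inner_lo <= e.query_position < inner_hi
    )
    if net == 0:
        return False
    # map primer sites onto the target via upstream net shifts
    for (lo, hi), primer, is_rev in (
        (fwd_site, pair.fwd_seq, False),
        (rev_site, revcomp(pair.rev_seq), True),
    ):
        shift = sum(e.signed_size for e in events if e.query_position <= lo)
        site = tseq[lo + shift : hi + shift]
        if len(site) != hi - lo:
            return False
        mism = [a != b for a, b in zip(primer, site)]
        if sum(mism) > max_mismatch:
            return False
        if anchor3 > 0:
            anchored = mism[:anchor3] if is_rev else mism[-anchor3:]
            if any(anchored):
                return False
    return True


def evaluate_against_truth(
    loci: list[InDelLocus],
    truth: list[TruthRecord],
    window: int = 10,
    restrict_to: set[str] | None = None,
) -> EvalResult:
    """Score called loci against planted InDels.

    A delta carried by a locus is *explained* when, for some target copy of
    the locus's gene, it equals the net signed size of that copy's planted
    InDels inside the amplicon interval that produced the delta (each delta
    keeps its tightest contributing interval; ``window`` bp of slack on the
    interval bounds is tried when the exact interval does not explain it).

    * precision — fraction of loci whose every delta is explained;
    * recall — fraction of planted InDels contained in the interval of at
      least one explained delta of their gene;
    * exactness — fraction of deltas explained among loci that overlap at
      least one planted event (1.0 means every matched call has exactly the
      planted net size).

    ``restrict_to`` limits the recall denominator (and numerator) to the
    given event ids, e.g. the output of :func:`detectable_events`.
    """
    by_copy = _events_by_copy(truth)
    eligible = {
        e.event_id
        for g in by_copy.values()
        for v in g.values()
        for e in v
        if restrict_to is None or e.event_id in restrict_to
    }
    n_truth = len(eligible)
    recovered: set[str] = set()
    n_correct = 0
    linked_deltas = 0
    linked_explained = 0
    for locus in loci:
        gene = _gene_of(locus.query_id)
        copies = by_copy.get(gene, {})
        all_ok = True
        locus_linked = False
        results = []
        for delta, (ilo, ihi) in locus.delta_intervals or (
            (d, locus.query_interval) for d in sorted(locus.delta_set)
        ):
            explained_by: list[TruthRecord] = []
            ok = False
            for events in copies.values():
                inside = [
                    e
                    for e in events
                    if ilo - window <= e.query_position < ihi + window
                ]
                # an amplicon reports the net size of the events between its
                # effective primer sites: any contiguous run of in-window
                # events with the right net sum is a valid explanation
                for i in range(len(inside)):
                    for j in range(i + 1, len(inside) + 1):
                        run = inside[i:j]
                        if sum(e.signed_size for e in run) == delta:
                            ok = True
                            explained_by += run
            results.append((ok, explained_by))
            if not ok:
                all_ok = False
        for events in copies.values():
            for e in events:
                if locus.query_interval[0] - window <= e.query_position < locus.query_interval[1] + window:
                    locus_linked = True
        if all_ok and locus.delta_set:
            n_correct += 1
        if locus_linked:
            linked_deltas += len(results)
            linked_explained += sum(ok for ok, _ in results)
        for ok, explained_by in results:
            if ok:
                recovered.update(
                    e.event_id for e in explained_by if e.event_id in eligible
                )
    n_loci = len(loci)
    return EvalResult(
        recall=(len(recovered) / n_truth) if n_truth else 1.0,
        precision=(n_correct / n_loci) if n_loci else 1.0,
        exactness=(linked_explained / linked_deltas) if linked_deltas else 1.0,
        n_truth=n_truth,
        n_recovered=len(recovered),
        n_loci=n_loci,
        n_correct_loci=n_correct,
    )
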