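"""File contracts: FASTA/FASTQ in, TSV/JSON out.

All tables have fixed, documented column orders so pipeline outputs are
diffable; coordinates in every file are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .indel_catalog import InDelLocus, MarkerRecord
from .insilico_pcr import Amplicon, InDelCall
from .preprocess import RawEST, Rejection
from .primer_design import PrimerPair
from .synthetic_data import TruthRecord

PRIMER_COLUMNS = [
    "pair_id", "source_id", "fwd_seq", "rev_seq", "fwd_start", "rev_end",
    "expected_size", "fwd_tm", "rev_tm", "fwd_gc", "rev_gc", "penalty",
]
AMPLICON_COLUMNS = [
    "pair_id", "target_id", "start", "end", "size",
    "fwd_strand", "fwd_offset", "fwd_mismatches", "rev_offset", "rev_mismatches",
]
CALL_COLUMNS = [
    "pair_id", "query_id", "target_id", "expected_size", "observed_size", "delta",
]
LOCUS_COLUMNS = [
    "locus_id", "query_id", "start", "end", "deltas", "support",
    "representative_pair", "max_abs_delta", "delta_intervals",
]
MARKER_COLUMNS = [
    "marker_id", "query_id", "fwd_seq", "rev_seq", "expected_size_query",
    "observed_sizes_target", "max_abs_delta",
]
TRUTH_COLUMNS = ["event_id", "gene_id", "copy_label", "kind", "query_position", "size"]
REJECT_COLUMNS = ["id", "reason", "original_length", "retained_start", "retained_end"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-FASTA into an ordered id -> sequence mapping.

    Duplicate ids are a hard error (downstream joins key on the id).
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()),
        str(path),
        "fasta",
    )


def read_raw_ests(
    fasta: str | Path | None = None,
    fastq: str | Path | None = None,
    qual: str | Path | None = None,
) -> list[RawEST]:
    """Raw records from FASTQ, or FASTA with an optional paired QUAL file."""
    if fastq is not None:
        return [
            RawEST(r.id, str(r.seq).upper(),
                   tuple(r.letter_annotations["phred_quality"]))
            for r in SeqIO.parse(str(fastq), "fastq")
        ]
    if fasta is None:
        raise ValueError("either fasta or fastq input is required")
    quals: dict[str, tuple[int, ...]] = {}
    if qual is not None:
        quals = {
            r.id: tuple(r.letter_annotations["phred_quality"])
            for r in SeqIO.parse(str(qual), "qual")
        }
    return [
        RawEST(rid, seq, quals.get(rid))
        for rid, seq in read_fasta(fasta).items()
    ]


def write_fastq(records: list[RawEST], path: str | Path) -> None:
    recs = []
    for r in records:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(
            r.quals if r.quals is not None else [40] * len(r.bases)
        )
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def _write_tsv(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    df.reindex(columns=columns).to_csv(path, sep="\t", index=False)


def write_primer_table(pairs: list[PrimerPair], path: str | Path) -> None:
    _write_tsv(pd.DataFrame([dataclasses.asdict(p) for p in pairs]),
               PRIMER_COLUMNS, path)


def read_primer_table(path: str | Path) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "source_id": str})
    return [PrimerPair(**row) for row in df.to_dict("records")]


def write_amplicon_table(
    products: list[tuple[PrimerPair, Amplicon]], path: str | Path
) -> None:
    rows = [
        {
            "pair_id": pair.pair_id,
            "target_id": a.target_id,
            "start": a.start,
            "end": a.end,
            "size": a.size,
            "fwd_strand": a.fwd_hit.strand,
            "fwd_offset": a.fwd_hit.offset,
            "fwd_mismatches": a.fwd_hit.mismatches,
            "rev_offset": a.rev_hit.offset,
            "rev_mismatches": a.rev_hit.mismatches,
        }
        for pair, a in products
    ]
    _write_tsv(pd.DataFrame(rows), AMPLICON_COLUMNS, path)


def write_call_table(calls: list[InDelCall], path: str | Path) -> None:
    _write_tsv(pd.DataFrame([dataclasses.asdict(c) for c in calls]),
               CALL_COLUMNS, path)


def read_call_table(path: str | Path) -> list[InDelCall]:
    df = pd.read_csv(
        path, sep="\t", dtype={"pair_id": str, "query_id": str, "target_id": str}
    )
    return [InDelCall(**row) for row in df.to_dict("records")]


def write_locus_table(loci: list[InDelLocus], path: str | Path) -> None:
    rows = [
        {
            "locus_id": l.locus_id,
            "query_id": l.query_id,
            "start": l.query_interval[0],
            "end": l.query_interval[1],
            "deltas": ",".join(str(d) for d in sorted(l.delta_set)),
            "support": l.support,
            "representative_pair": l.representative_pair,
            "max_abs_delta": l.max_abs_delta,
            "delta_intervals": ";".join(
                f"{d}:{a}-{b}" for d, (a, b) in l.delta_intervals
            ),
        }
        for l in loci
    ]
    _write_tsv(pd.DataFrame(rows), LOCUS_COLUMNS, path)


def read_locus_table(path: str | Path) -> list[InDelLocus]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.to_dict("records"):
        intervals = []
        if isinstance(row["delta_intervals"], str) and row["delta_intervals"]:
            for item in row["delta_intervals"].split(";"):
                d, iv = item.split(":")
                a, b = iv.split("-")
                intervals.append((int(d), (int(a), int(b))))
        out.append(
            InDelLocus(
                locus_id=row["locus_id"],
                query_id=row["query_id"],
                query_interval=(int(row["start"]), int(row["end"])),
                delta_set=frozenset(int(d) for d in row["deltas"].split(",")),
                support=int(row["support"]),
                representative_pair=row["representative_pair"],
                delta_intervals=tuple(intervals),
            )
        )
    return out


def write_marker_table(markers: list[MarkerRecord], path: str | Path) -> None:
    rows = [
        {
            **dataclasses.asdict(m),
            "observed_sizes_target": ",".join(
                str(s) for s in m.observed_sizes_target
            ),
        }
        for m in markers
    ]
    _write_tsv(pd.DataFrame(rows), MARKER_COLUMNS, path)


def write_truth_table(truth: list[TruthRecord], path: str | Path) -> None:
    _write_tsv(pd.DataFrame([dataclasses.asdict(t) for t in truth]),
               TRUTH_COLUMNS, path)


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"event_id": str, "gene_id": str, "copy_label": str, "kind": str},
    )
    return [TruthRecord(**row) for row in df.to_dict("records")]


def write_reject_table(rejects: list[Rejection], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "reason": r.reason,
            "original_length": r.original_length,
            "retained_start": r.retained_interval[0],
            "retained_end": r.retained_interval[1],
        }
        for r in rejects
    ]
    _write_tsv(pd.DataFrame(rows), REJECT_COLUMNS, path)
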