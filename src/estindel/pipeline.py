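"""End-to-end discovery: clean -> design -> amplify -> call -> collapse -> markers.

The orchestration is deterministic under a fixed seed: the same inputs and
config always produce byte-identical tables.  Every stage count is recorded
in a summary so the outputs are mutually checkable (calls >= loci >= markers).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io
from .indel_catalog import (
    InDelLocus,
    MarkerRecord,
    SizeBinSummary,
    bin_sizes,
    collapse_redundant,
    select_markers,
)
from .insilico_pcr import InDelCall, run_pcr
from .preprocess import CleanEST, CleaningConfig, RawEST, Rejection, VectorLibrary, clean_est
from .primer_design import PrimerConstraints, PrimerPair, design_for_transcript

log = logging.getLogger("estindel")

__all__ = ["PipelineConfig", "DiscoveryResult", "discover", "run_discovery"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage threshold in one round-trippable record."""

    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    constraints: PrimerConstraints = field(default_factory=PrimerConstraints)
    target_len: int = 300
    overlap: int = 60
    segment_mode: str = "random"
    n_best: int = 2
    max_mismatch: int = 2
    anchor3: int = 1
    max_product: int | None = None  # None -> expected_size + 500 per pair
    pair_mismatch_budget: int | None = None
    min_marker_delta: int = 5
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        if "cleaning" in data and isinstance(data["cleaning"], dict):
            data["cleaning"] = CleaningConfig(**data["cleaning"])
        if "constraints" in data and isinstance(data["constraints"], dict):
            data["constraints"] = PrimerConstraints(**data["constraints"])
        return cls(**data)


@dataclass
class DiscoveryResult:
    cleaned_query: dict[str, str]
    cleaned_target: dict[str, str]
    rejects: list[Rejection]
    pairs: list[PrimerPair]
    gaps: dict[str, list[tuple[int, int]]]
    products: list
    calls: list[InDelCall]
    loci: list[InDelLocus]
    markers: list[MarkerRecord]
    summary: dict

    @property
    def pair_index(self) -> dict[str, PrimerPair]:
        return {p.pair_id: p for p in self.pairs}


def _clean_collection(
    records: dict[str, str] | list[RawEST],
    config: CleaningConfig,
    vector_lib: VectorLibrary | None,
) -> tuple[dict[str, str], list[Rejection]]:
    raws = (
        records
        if isinstance(records, list)
        else [RawEST(rid, seq) for rid, seq in records.items()]
    )
    cleaned: dict[str, str] = {}
    rejects: list[Rejection] = []
    for raw in raws:
        result = clean_est(raw, config, vector_lib)
        if isinstance(result, CleanEST):
            cleaned[result.id] = result.bases
        else:
            rejects.append(result)
    return cleaned, rejects


def discover(
    query: dict[str, str] | list[RawEST],
    target: dict[str, str] | list[RawEST],
    config: PipelineConfig = PipelineConfig(),
    vector_lib: VectorLibrary | None = None,
    query_clusters: dict[str, str] | None = None,
) -> DiscoveryResult:
    """Run the full InDel discovery pipeline in memory."""
    n_query_in = len(query)
    n_target_in = len(target)
    cleaned_q, rejects_q = _clean_collection(query, config.cleaning, vector_lib)
    cleaned_t, rejects_t = _clean_collection(target, config.cleaning, vector_lib)
    log.info("cleaned %d/%d query, %d/%d target records",
             len(cleaned_q), n_query_in, len(cleaned_t), n_target_in)

    pairs: list[PrimerPair] = []
    gaps: dict[str, list[tuple[int, int]]] = {}
    for qid, seq in cleaned_q.items():
        # per-record seed keeps designs independent of collection order
        rec_seed = (config.seed * 1_000_003 + _stable_hash(qid)) % (2**31)
        p, g = design_for_transcript(
            seq,
            qid,
            config.constraints,
            target_len=config.target_len,
            overlap=config.overlap,
            mode=config.segment_mode,
            seed=rec_seed,
            n_best=config.n_best,
        )
        pairs += p
        if g:
            gaps[qid] = g
    log.info("designed %d primer pairs on %d transcripts", len(pairs), len(cleaned_q))

    products, calls = run_pcr(
        pairs,
        cleaned_t,
        max_mismatch=config.max_mismatch,
        anchor3=config.anchor3,
        max_product=config.max_product,
        pair_mismatch_budget=config.pair_mismatch_budget,
    )
    log.info("%d virtual products, %d size-variant calls", len(products), len(calls))

    pair_index = {p.pair_id: p for p in pairs}
    loci = collapse_redundant(calls, pair_index, query_clusters)
    markers = select_markers(loci, pair_index, config.min_marker_delta)
    summary_bins = bin_sizes(loci)
    summary = {
        "counts": {
            "query_in": n_query_in,
            "target_in": n_target_in,
            "query_cleaned": len(cleaned_q),
            "target_cleaned": len(cleaned_t),
            "query_rejected": len(rejects_q),
            "target_rejected": len(rejects_t),
            "primer_pairs": len(pairs),
            "uncovered_gap_bp": sum(b - a for g in gaps.values() for a, b in g),
            "amplicons": len(products),
            "calls": len(calls),
            "loci": len(loci),
            "markers": len(markers),
        },
        "size_bins": dataclasses.asdict(summary_bins),
        "config": dataclasses.asdict(config),
    }
    return DiscoveryResult(
        cleaned_query=cleaned_q,
        cleaned_target=cleaned_t,
        rejects=rejects_q + rejects_t,
        pairs=pairs,
        gaps=gaps,
        products=products,
        calls=calls,
        loci=loci,
        markers=markers,
        summary=summary,
    )


def _stable_hash(text: str) -> int:
    """Deterministic across processes (unlike built-in str hashing)."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def run_discovery(
    query_path: str | Path,
    target_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    vector_path: str | Path | None = None,
) -> DiscoveryResult:
    """File-level pipeline: FASTA in, TSV/JSON tables in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    query = io.read_fasta(query_path)
    target = io.read_fasta(target_path)
    vector_lib = None
    if vector_path is not None:
        vector_lib = VectorLibrary(tuple(io.read_fasta(vector_path).items()))
    result = discover(query, target, config, vector_lib)
    io.write_fasta(result.cleaned_query, out / "query.clean.fasta")
    io.write_fasta(result.cleaned_target, out / "target.clean.fasta")
    io.write_reject_table(result.rejects, out / "rejects.tsv")
    io.write_primer_table(result.pairs, out / "primers.tsv")
    io.write_amplicon_table(result.products, out / "amplicons.tsv")
    io.write_call_table(result.calls, out / "calls.tsv")
    io.write_locus_table(result.loci, out / "loci.tsv")
    io.write_marker_table(result.markers, out / "markers.tsv")
    tmp = out / "summary.json.tmp"
    tmp.write_text(json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    tmp.replace(out / "summary.json")
    return result
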