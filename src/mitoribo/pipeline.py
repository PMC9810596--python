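"""End-to-end sample processing: FASTQ -> codon count table.

Chains adapter trimming, length filtering, circular-genome mapping and A-site
assignment with the standard profiling parameters (offset 14, lengths 25-35)
and reports per-stage diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import MitoGenome, OrfAnnotation
from .occupancy import AssignmentStats, CodonCountTable, assign_alignments, build_count_table
from .reads import (
    MULTI,
    UNIQUE,
    AlignmentRecord,
    FilterStats,
    GenomeIndex,
    length_filter,
    map_read,
    trim_adapter,
)
from .simulate import DEFAULT_ADAPTER

__all__ = ["PipelineStats", "process_reads", "process_sample"]


@dataclass
class PipelineStats:
    n_input: int = 0
    filter_stats: FilterStats = field(default_factory=FilterStats)
    n_unique: int = 0
    n_multi: int = 0
    n_unmapped: int = 0
    assignment_stats: AssignmentStats = field(default_factory=AssignmentStats)


def process_reads(
    genome: MitoGenome,
    records: list[tuple[str, str, str]],
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = 25,
    max_len: int = 35,
    max_mismatches: int = 1,
    drop_untrimmed: bool = True,
    index: GenomeIndex | None = None,
) -> tuple[list[AlignmentRecord], PipelineStats]:
    """Trim, length-filter and map raw FASTQ records; returns all alignment
    records (UNIQUE, MULTI and UNMAPPED) for the retained reads."""
    stats = PipelineStats(n_input=len(records))
    trimmed = [trim_adapter(rid, seq, adapter) for rid, seq, _ in records]
    kept, stats.filter_stats = length_filter(trimmed, min_len, max_len, drop_untrimmed)
    idx = index or GenomeIndex(genome)
    alignments = [map_read(idx, r, max_mismatches) for r in kept]
    for a in alignments:
        if a.status == UNIQUE:
            stats.n_unique += 1
        elif a.status == MULTI:
            stats.n_multi += 1
        else:
            stats.n_unmapped += 1
    return alignments, stats


def process_sample(
    genome: MitoGenome,
    orfs: list[OrfAnnotation],
    records: list[tuple[str, str, str]],
    sample_id: str,
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = 25,
    max_len: int = 35,
    max_mismatches: int = 1,
    offset: int = 14,
    index: GenomeIndex | None = None,
) -> tuple[CodonCountTable, PipelineStats]:
    """Full sample pipeline: raw records to the per-sample codon count table."""
    alignments, stats = process_reads(
        genome, records, adapter, min_len, max_len, max_mismatches, index=index
    )
    assignments, stats.assignment_stats = assign_alignments(genome, orfs, alignments, offset)
    return build_count_table(assignments, sample_id), stats
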