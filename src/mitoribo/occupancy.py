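"""A-site assignment and per-sample codon count tables.

Each uniquely mapped footprint is assigned the codon its ribosomal A-site
occupies: the A-site codon's first base sits at a fixed offset (14 nt by
default) from the footprint's 5' end, applied uniformly to all retained
lengths (25-35 nt). An A-site position is attributed to every same-strand ORF
containing it, so reads landing in a bicistronic overlap (ATP8/ATP6,
ND4L/ND4) count toward both frames; the double count is reported, not hidden.
A-sites outside all ORFs are tallied in an off-ORF diagnostic counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome import MitoGenome, OrfAnnotation, codons_of, genomic_to_codon_index
from .reads import UNIQUE, AlignmentRecord

__all__ = [
    "AsiteAssignment",
    "CodonCountTable",
    "AssignmentStats",
    "asite_genomic_position",
    "assign_alignment",
    "assign_alignments",
    "build_count_table",
]


@dataclass(frozen=True)
class AsiteAssignment:
    read_id: str
    gene: str
    codon_index: int
    codon: str
    genomic_a_pos: int


def asite_genomic_position(alignment: AlignmentRecord, offset: int, genome_length: int) -> int:
    """Genomic coordinate of the A-site codon's first base: 5' position plus
    ``offset`` along the read's sense ('+' adds, '-' subtracts), modulo the
    circular genome length."""
    if alignment.status != UNIQUE:
        raise ValueError(f"{alignment.read_id}: A-site requires a UNIQUE alignment")
    if alignment.read_length < offset + 1:
        raise ValueError(f"{alignment.read_id}: footprint shorter than offset + 1")
    if alignment.strand == "+":
        return (alignment.five_prime_pos + offset) % genome_length
    return (alignment.five_prime_pos - offset) % genome_length


class _OrfCodons:
    """Cache of per-ORF codon lists keyed by gene."""

    def __init__(self, genome: MitoGenome, orfs: list[OrfAnnotation]):
        self.genome = genome
        self.orfs = orfs
        self._codons = {o.gene: codons_of(genome, o) for o in orfs}

    def codon(self, gene: str, index: int) -> str:
        return self._codons[gene][index]


def assign_alignment(
    genome: MitoGenome,
    orfs: list[OrfAnnotation],
    alignment: AlignmentRecord,
    offset: int = 14,
    _cache: _OrfCodons | None = None,
) -> list[AsiteAssignment]:
    """A-site assignments of one unique alignment: one entry per same-strand
    ORF containing the A-site position (more than one only in bicistronic
    overlaps); empty if the A-site lies outside all same-strand ORFs."""
    cache = _cache or _OrfCodons(genome, orfs)
    apos = asite_genomic_position(alignment, offset, len(genome))
    out = []
    for orf in orfs:
        if orf.strand != alignment.strand:
            continue
        ci = genomic_to_codon_index(orf, apos, len(genome))
        if ci is not None:
            out.append(
                AsiteAssignment(alignment.read_id, orf.gene, ci, cache.codon(orf.gene, ci), apos)
            )
    return out


@dataclass
class AssignmentStats:
    n_unique: int = 0
    n_assigned_reads: int = 0
    n_off_orf: int = 0
    n_overlap_double_counted: int = 0


def assign_alignments(
    genome: MitoGenome,
    orfs: list[OrfAnnotation],
    alignments: list[AlignmentRecord],
    offset: int = 14,
) -> tuple[list[AsiteAssignment], AssignmentStats]:
    """Assign every UNIQUE alignment; non-unique records are ignored here
    (they are accounted for by the mapping stage)."""
    cache = _OrfCodons(genome, orfs)
    stats = AssignmentStats()
    out: list[AsiteAssignment] = []
    for rec in alignments:
        if rec.status != UNIQUE:
            continue
        stats.n_unique += 1
        hits = assign_alignment(genome, orfs, rec, offset, _cache=cache)
        if not hits:
            stats.n_off_orf += 1
            continue
        stats.n_assigned_reads += 1
        stats.n_overlap_double_counted += len(hits) - 1
        out.extend(hits)
    return out, stats


@dataclass
class CodonCountTable:
    """Per-sample A-site counts indexed by (gene, codon index) — the central
    object every occupancy statistic consumes."""

    sample_id: str
    counts: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def gene_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for (g, _), c in self.counts.items():
            totals[g] = totals.get(g, 0) + c
        return totals

    @property
    def grand_total(self) -> int:
        return sum(self.counts.values())

    def gene_vector(self, orf: OrfAnnotation) -> pd.Series:
        """Dense per-codon counts for one gene (zeros included)."""
        idx = range(orf.n_codons)
        return pd.Series([self.counts.get((orf.gene, i), 0) for i in idx], index=idx, name=orf.gene)

    def to_frame(self, genome: MitoGenome | None = None, orfs: list[OrfAnnotation] | None = None) -> pd.DataFrame:
        """Tidy table (sample, gene, codon_index, codon, count); the codon
        identity column requires genome + annotation."""
        codons = None
        if genome is not None and orfs is not None:
            codons = {o.gene: codons_of(genome, o) for o in orfs}
        rows = [
            (self.sample_id, g, i, codons[g][i] if codons else "", c)
            for (g, i), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["sample", "gene", "codon_index", "codon", "count"])

    def to_tsv(self, path, genome=None, orfs=None) -> None:
        self.to_frame(genome, orfs).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str | None = None) -> "CodonCountTable":
        sid = sample_id or (str(df["sample"].iloc[0]) if len(df) else "sample")
        counts = {
            (str(r.gene), int(r.codon_index)): int(r.count)
            for r in df.itertuples()
            if int(r.count) != 0
        }
        return cls(sample_id=sid, counts=counts)

    @classmethod
    def from_tsv(cls, path, sample_id: str | None = None) -> "CodonCountTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False), sample_id)


def build_count_table(assignments: list[AsiteAssignment], sample_id: str) -> CodonCountTable:
    """Histogram assignments into a (gene, codon index) count table; the grand
    total equals the number of assignments (overlap reads contribute one count
    per overlapping ORF)."""
    counts: dict[tuple[str, int], int] = {}
    for a in assignments:
        key = (a.gene, a.codon_index)
        counts[key] = counts.get(key, 0) + 1
    return CodonCountTable(sample_id=sample_id, counts=counts)
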