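"""Circular mitochondrial genome, ORF annotations, and the mitochondrial genetic code.

The mammalian mitochondrial genome is a single circular replicon (~16.5 kb in
human) encoding 13 proteins on both strands. Translation follows the vertebrate
mitochondrial code: UGA is read as tryptophan, AUA/AUU serve as start codons,
and AGA/AGG — arginine in the universal code — have no cognate tRNAs and act as
non-canonical stop codons at the ends of COX1 and ND6. Several mRNAs end in
partial stop codons (U or UA) that are completed to UAA by polyadenylation.

Coordinates are 0-based, half-open, on the forward genome axis; strand only
affects reading direction. Annotations may wrap the origin, in which case
``end`` exceeds the genome length and indexing is modular.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "MitoGenome",
    "OrfAnnotation",
    "GeneticCode",
    "CodonClass",
    "VERTEBRATE_MITO_CODE",
    "AnnotationError",
    "CodonError",
    "orf_mrna_sequence",
    "codons_of",
    "classify_codon",
    "codon_frequency",
    "genomic_to_codon_index",
    "reverse_complement",
    "read_genome_fasta",
    "read_annotation_table",
    "write_annotation_table",
    "read_annotation_gff3",
    "ALL_CODONS",
]

_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

ALL_CODONS = tuple(a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG")


class AnnotationError(ValueError):
    """An ORF annotation is inconsistent with the genome or with itself."""


class CodonError(ValueError):
    """A codon string is not 3 nt over {A,C,G,T}."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MitoGenome:
    """A circular nucleotide sequence.

    Positions are taken modulo the genome length, so slices may run past the
    origin (``fetch(16560, 16580)`` on a 16569-nt genome wraps around).
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("genome sequence is empty")
        bad = set(self.sequence) - _BASES
        if bad:
            raise ValueError(f"genome contains non-ACGT characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Return the forward-strand sequence of [start, end), wrapping the origin."""
        n = len(self.sequence)
        length = end - start
        if length < 0:
            raise ValueError(f"end {end} < start {start}")
        if length > n:
            raise ValueError(f"slice of length {length} exceeds genome length {n}")
        start %= n
        stop = start + length
        if stop <= n:
            return self.sequence[start:stop]
        if not self.circular:
            raise ValueError("slice runs past the end of a linear genome")
        return self.sequence[start:] + self.sequence[: stop - n]

    def base(self, pos: int) -> str:
        return self.sequence[pos % len(self.sequence)]


@dataclass(frozen=True)
class OrfAnnotation:
    """One protein-coding ORF on the circular genome.

    ``start``/``end`` are 0-based half-open forward-axis coordinates of the
    genomically encoded part of the coding region; for origin-wrapping ORFs
    ``end`` may exceed the genome length. ``polya_completion`` counts the A
    residues appended post-transcriptionally to complete the terminal stop
    codon (0-2), so ``(end - start + polya_completion)`` is a multiple of 3.
    """

    gene: str
    start: int
    end: int
    strand: str
    polya_completion: int = 0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene}: strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.polya_completion <= 2:
            raise AnnotationError(f"{self.gene}: polya_completion must be 0-2")
        if self.start < 0 or self.end <= self.start:
            raise AnnotationError(f"{self.gene}: need 0 <= start < end (after unwrapping)")
        if (self.end - self.start + self.polya_completion) % 3:
            raise AnnotationError(f"{self.gene}: length + polyA completion not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return (self.end - self.start + self.polya_completion) // 3

    def contains(self, pos: int, genome_length: int | None = None) -> int | None:
        """Unwrapped coordinate of ``pos`` if inside the ORF, else None."""
        if self.start <= pos < self.end:
            return pos
        if genome_length is not None and self.start <= pos + genome_length < self.end:
            return pos + genome_length
        return None


class CodonClass:
    AMINO_ACID = "AMINO_ACID"
    CANONICAL_STOP = "CANONICAL_STOP"
    NONCANONICAL_STOP = "NONCANONICAL_STOP"


@dataclass(frozen=True)
class CodonClassification:
    category: str
    amino_acid: str | None = None

    def __str__(self) -> str:
        if self.category == CodonClass.AMINO_ACID:
            return f"AMINO_ACID({self.amino_acid})"
        return self.category


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table with stop codons split into canonical
    (recognized by mtRF1a: UAA/UAG) and non-canonical (AGA/AGG, no cognate
    tRNA, recognized by mtRF1) categories."""

    table: dict = field(repr=False)
    start_codons: frozenset
    canonical_stops: frozenset
    noncanonical_stops: frozenset

    def __post_init__(self):
        if len(self.table) != 64:
            raise ValueError(f"genetic code must map exactly 64 codons, got {len(self.table)}")

    @classmethod
    def from_ncbi_table(
        cls,
        table_id: int = 2,
        noncanonical_stops: tuple[str, ...] = ("AGA", "AGG"),
    ) -> "GeneticCode":
        """Build from an NCBI translation table (2 = vertebrate mitochondrial),
        designating the given stop codons as non-canonical."""
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        nc = frozenset(noncanonical_stops)
        table = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            table[stop] = None
        canonical = frozenset(ncbi.stop_codons) - nc
        missing = nc - frozenset(ncbi.stop_codons)
        if missing:
            raise ValueError(f"{sorted(missing)} are not stop codons in NCBI table {table_id}")
        return cls(
            table=table,
            start_codons=frozenset(ncbi.start_codons),
            canonical_stops=canonical,
            noncanonical_stops=nc,
        )


VERTEBRATE_MITO_CODE = GeneticCode.from_ncbi_table(2)


def classify_codon(code: GeneticCode, codon: str) -> CodonClassification:
    """Classify a codon as an amino acid, a canonical stop (UAA/UAG, read by
    mtRF1a) or a non-canonical stop (AGA/AGG, read by mtRF1)."""
    if len(codon) != 3 or set(codon) - _BASES:
        raise CodonError(f"invalid codon {codon!r}: must be 3 nt over ACGT")
    if codon in code.canonical_stops:
        return CodonClassification(CodonClass.CANONICAL_STOP)
    if codon in code.noncanonical_stops:
        return CodonClassification(CodonClass.NONCANONICAL_STOP)
    return CodonClassification(CodonClass.AMINO_ACID, code.table[codon])


def orf_mrna_sequence(genome: MitoGenome, orf: OrfAnnotation) -> str:
    """Coding sequence of the ORF in translation order (mRNA sense), with the
    post-transcriptional polyA completion appended. Forward slice for '+',
    reverse complement for '-'; length is a multiple of 3."""
    n = len(genome)
    if orf.start >= n or orf.end - orf.start > n:
        raise AnnotationError(
            f"{orf.gene}: coordinates [{orf.start}, {orf.end}) outside unwrapped range of a {n}-nt genome"
        )
    seg = genome.fetch(orf.start, orf.end)
    if orf.strand == "-":
        seg = reverse_complement(seg)
    return seg + "A" * orf.polya_completion


def codons_of(genome: MitoGenome, orf: OrfAnnotation) -> list[str]:
    """The ORF's codons, in translation order."""
    mrna = orf_mrna_sequence(genome, orf)
    return [mrna[i : i + 3] for i in range(0, len(mrna), 3)]


def codon_frequency(genome: MitoGenome, orfs: list[OrfAnnotation]) -> dict[str, int]:
    """Occurrence count of every codon identity across the in-frame codons of
    all ORFs. All 64 codons are present in the result (possibly 0)."""
    if not orfs:
        raise AnnotationError("empty annotation set")
    counts = Counter()
    for orf in orfs:
        counts.update(codons_of(genome, orf))
    return {c: counts.get(c, 0) for c in ALL_CODONS}


def genomic_to_codon_index(
    orf: OrfAnnotation, genomic_pos: int, genome_length: int | None = None
) -> int | None:
    """Codon index (0-based, in translation order) of a genomic position, or
    None if the position lies outside the ORF.

    Positions within the genomically encoded bases of a polyA-completed
    terminal codon map to the final codon index; the appended A's themselves
    have no genomic coordinate.
    """
    u = orf.contains(genomic_pos, genome_length)
    if u is None:
        return None
    if orf.strand == "+":
        return (u - orf.start) // 3
    return (orf.end - 1 - u) // 3


# ---------------------------------------------------------------------------
# I/O


def read_genome_fasta(path) -> MitoGenome:
    """Load a single-record FASTA as a circular genome."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single FASTA record, found {len(records)}")
    rec = records[0]
    return MitoGenome(name=rec.id, sequence=str(rec.seq).upper())


def write_genome_fasta(genome: MitoGenome, path) -> None:
    rec = SeqIO.SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


_ANNOTATION_COLUMNS = ["gene", "start", "end", "strand", "polya_completion"]


def read_annotation_table(path) -> list[OrfAnnotation]:
    """Read a tab-separated ORF table with columns
    gene/start/end/strand/polya_completion (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    orfs = [
        OrfAnnotation(
            gene=str(r.gene),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            polya_completion=int(r.polya_completion),
        )
        for r in df.itertuples()
    ]
    genes = [o.gene for o in orfs]
    if len(set(genes)) != len(genes):
        raise AnnotationError("duplicate gene symbols in annotation set")
    return orfs


def write_annotation_table(orfs: list[OrfAnnotation], path) -> None:
    df = pd.DataFrame(
        [(o.gene, o.start, o.end, o.strand, o.polya_completion) for o in orfs],
        columns=_ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation_gff3(path, feature_type: str = "CDS") -> list[OrfAnnotation]:
    """Read a minimal GFF3, converting 1-based inclusive coordinates to 0-based
    half-open. The gene symbol is taken from the ``gene``, ``Name`` or ``ID``
    attribute; an optional ``polya_completion`` attribute defaults to 0."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True)
    orfs = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        for key in ("gene", "Name", "ID"):
            if key in feat.attributes:
                gene = feat.attributes[key][0]
                break
        else:
            raise AnnotationError(f"GFF3 feature at {feat.start} has no gene/Name/ID attribute")
        polya = int(feat.attributes.get("polya_completion", ["0"])[0])
        orfs.append(
            OrfAnnotation(
                gene=gene,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                polya_completion=polya,
            )
        )
    return orfs


def check_stop_codons(genome: MitoGenome, orfs: list[OrfAnnotation], code: GeneticCode = VERTEBRATE_MITO_CODE):
    """Diagnostic: per-gene terminal codon and its classification (after polyA
    completion). Genes not ending in any stop are reported with a warning."""
    rows = []
    for orf in orfs:
        last = codons_of(genome, orf)[-1]
        cls = classify_codon(code, last)
        if cls.category == CodonClass.AMINO_ACID:
            warnings.warn(f"{orf.gene} does not end in a stop codon (ends {last})")
        rows.append((orf.gene, last, cls.category))
    return pd.DataFrame(rows, columns=["gene", "terminal_codon", "classification"])
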