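"""Raw-read processing: 3' adapter trimming, length filtering, and exact
short-read mapping on the circular mitochondrial genome.

The mapper is exhaustive in effect: every circular offset on both strands is
considered, candidate loci are ranked by mismatch count, and a read is UNIQUE
only when a single locus attains the minimum (ties are never broken silently —
they yield MULTI). For speed the search is driven by a k-mer index with a
pigeonhole guarantee: a read with at most ``max_mismatches`` mismatches must
contain an exact seed in one of ``max_mismatches + 1`` chunks, so no qualifying
locus can be missed. Reads too short to seed fall back to a full positional
scan. The reference is ~16.5 kb, so indexing the doubled genome is cheap and
removes any external aligner dependency while keeping results bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import MitoGenome, reverse_complement

__all__ = [
    "TrimmedRead",
    "AlignmentRecord",
    "FilterStats",
    "UNIQUE",
    "MULTI",
    "UNMAPPED",
    "trim_adapter",
    "length_filter",
    "GenomeIndex",
    "map_read",
    "write_alignments_tsv",
    "read_alignments_tsv",
    "write_alignments_sam",
]

UNIQUE = "UNIQUE"
MULTI = "MULTI"
UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    sequence: str
    adapter_found: bool

    @property
    def trimmed_length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """A read placed on the circular genome. ``five_prime_pos`` is the genomic
    coordinate of the read's 5' base: the lowest-coordinate aligned base on
    '+', the highest on '-'."""

    read_id: str
    five_prime_pos: int | None
    strand: str | None
    n_mismatches: int | None
    status: str
    read_length: int
    sequence: str = ""


def _hamming(a: str, b: str, limit: int | None = None) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d


def trim_adapter(
    read_id: str,
    sequence: str,
    adapter: str,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> TrimmedRead:
    """Trim a 3' sequencing adapter.

    Finds the 5'-most position at which a prefix of the adapter (at least
    ``min_overlap`` nt of it) matches the read suffix with a mismatch fraction
    of at most ``max_error_rate``, and truncates the read there. If no such
    position exists the read is returned unchanged with ``adapter_found``
    False.
    """
    if not sequence:
        raise ValueError(f"{read_id}: empty read")
    if min_overlap < 3 or len(adapter) < min_overlap:
        raise ValueError("need adapter length >= min_overlap >= 3")
    n = len(sequence)
    # exact occurrence of the (possibly clipped) full adapter prefix bounds the
    # mismatch-tolerant scan: only more-5' positions can beat it
    probe = adapter[: min(len(adapter), n)]
    exact = sequence.find(probe)
    limit = exact if exact != -1 else n - min_overlap + 1
    for pos in range(0, limit):
        ov = min(len(adapter), n - pos)
        allowed = int(max_error_rate * ov + 1e-9)
        if _hamming(sequence[pos : pos + ov], adapter[:ov], limit=allowed) <= allowed:
            return TrimmedRead(read_id, sequence[:pos], True)
    if exact != -1:
        return TrimmedRead(read_id, sequence[:exact], True)
    return TrimmedRead(read_id, sequence, False)


@dataclass
class FilterStats:
    kept: int = 0
    too_short: int = 0
    too_long: int = 0
    untrimmed: int = 0


def length_filter(
    reads: list[TrimmedRead],
    min_len: int = 25,
    max_len: int = 35,
    drop_untrimmed: bool = True,
) -> tuple[list[TrimmedRead], FilterStats]:
    """Retain reads with min_len <= trimmed length <= max_len.

    Untrimmed reads (adapter never found) are discarded by default: with 50-nt
    raw reads and <= 40-nt inserts the adapter must be present; set
    ``drop_untrimmed=False`` for library designs where inserts can fill the
    read.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    kept, stats = [], FilterStats()
    for r in reads:
        if drop_untrimmed and not r.adapter_found:
            stats.untrimmed += 1
        elif r.trimmed_length < min_len:
            stats.too_short += 1
        elif r.trimmed_length > max_len:
            stats.too_long += 1
        else:
            kept.append(r)
            stats.kept += 1
    return kept, stats


class GenomeIndex:
    """k-mer index of the doubled circular genome (both strands searched via
    the read and its reverse complement against the forward text)."""

    def __init__(self, genome: MitoGenome, seed_length: int = 12):
        self.genome = genome
        self.k = seed_length
        n = len(genome)
        # doubled text makes every circular window contiguous; seed positions
        # are indexed only for offsets < n so each circular locus appears once
        self._text = genome.sequence * 2
        self._index: dict[str, list[int]] = {}
        for i in range(n):
            kmer = self._text[i : i + seed_length]
            self._index.setdefault(kmer, []).append(i)

    def _candidates(self, query: str, max_mismatches: int) -> set[int]:
        n = len(self.genome)
        L = len(query)
        hits: set[int] = set()
        n_chunks = max_mismatches + 1
        chunk = L // n_chunks
        if chunk < self.k:
            return set(range(n))  # too short to seed: full scan
        for c in range(n_chunks):
            off = c * chunk
            for p in self._index.get(query[off : off + self.k], ()):
                hits.add((p - off) % n)
        return hits

    def alignments(self, query: str, max_mismatches: int) -> list[tuple[int, int]]:
        """All (start, n_mismatches) with n_mismatches <= max_mismatches for
        the query on the forward text, starts in [0, genome length)."""
        out = []
        for p in self._candidates(query, max_mismatches):
            d = _hamming(query, self._text[p : p + len(query)], limit=max_mismatches)
            if d <= max_mismatches:
                out.append((p, d))
        return out


def map_read(
    index: GenomeIndex,
    read: TrimmedRead,
    max_mismatches: int = 1,
) -> AlignmentRecord:
    """Map a read to the circular genome, both strands, ranking loci by
    mismatch count. UNIQUE iff exactly one locus attains the minimum and the
    minimum is within ``max_mismatches``; equal-mismatch ties give MULTI."""
    L = len(read.sequence)
    if L > len(index.genome):
        raise ValueError(f"{read.read_id}: read longer than genome")
    if L == 0:
        return AlignmentRecord(read.read_id, None, None, None, UNMAPPED, 0, "")
    loci = [(p, "+", d) for p, d in index.alignments(read.sequence, max_mismatches)]
    rc = reverse_complement(read.sequence)
    n = len(index.genome)
    loci += [
        ((p + L - 1) % n, "-", d) for p, d in index.alignments(rc, max_mismatches)
    ]
    if not loci:
        return AlignmentRecord(read.read_id, None, None, None, UNMAPPED, L, read.sequence)
    best = min(d for _, _, d in loci)
    top = [(p, s) for p, s, d in loci if d == best]
    if len(top) > 1:
        return AlignmentRecord(read.read_id, None, None, best, MULTI, L, read.sequence)
    pos, strand = top[0]
    return AlignmentRecord(read.read_id, pos, strand, best, UNIQUE, L, read.sequence)


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = ["read_id", "five_prime_pos", "strand", "n_mismatches", "status", "read_length", "sequence"]


def write_alignments_tsv(records: list[AlignmentRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (r.read_id, r.five_prime_pos, r.strand, r.n_mismatches, r.status, r.read_length, r.sequence)
            for r in records
        ],
        columns=_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path) -> list[AlignmentRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)

    def _opt_int(v: str):
        return None if v == "" else int(float(v))

    return [
        AlignmentRecord(
            read_id=r.read_id,
            five_prime_pos=_opt_int(r.five_prime_pos),
            strand=r.strand if r.strand in ("+", "-") else None,
            n_mismatches=_opt_int(r.n_mismatches),
            status=r.status,
            read_length=int(r.read_length),
            sequence=r.sequence,
        )
        for r in df.itertuples()
    ]


def write_alignments_sam(records: list[AlignmentRecord], genome: MitoGenome, path) -> None:
    """Write UNIQUE alignments as minimal SAM (CIGAR <len>M; reads spanning the
    origin keep a full-length match starting near the reference end)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": genome.name, "LN": len(genome)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            if r.status != UNIQUE:
                continue
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = 0 if r.strand == "+" else 16
            a.reference_id = 0
            left = r.five_prime_pos if r.strand == "+" else (r.five_prime_pos - r.read_length + 1) % len(genome)
            a.reference_start = left
            a.mapping_quality = 255
            a.cigartuples = [(0, r.read_length)]
            a.query_sequence = r.sequence if r.strand == "+" else reverse_complement(r.sequence)
            out.write(a)
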