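"""Synthetic mitoribosome-profiling read generator.

Emits single-end FASTQ reads with the statistical structure of a mitoribosome
profiling library — 25-40 nt footprints carrying a 3' sequencing adapter,
per-codon occupancy with optional stall peaks at chosen codons and
queued-ribosome peaks one footprint length (~12 codons) upstream — together
with a per-read ground-truth table, so the downstream pipeline (trimming,
mapping, A-site assignment, stall statistics) is verifiable end to end without
any deposited data.

Footprint geometry mirrors the analysis pipeline's single fixed A-site offset:
the first base of the A-site codon sits exactly ``offset`` nt from the
footprint's 5' end for every footprint length. Footprints are genomic
sequence; reads from the first codons of an ORF simply extend into upstream
genomic sequence (mitochondrial transcripts are essentially UTR-less).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genome import MitoGenome, OrfAnnotation, reverse_complement

__all__ = [
    "TERMINAL",
    "StallSpec",
    "SimulationConfig",
    "SimulationError",
    "DEFAULT_ADAPTER",
    "DEFAULT_LENGTH_DISTRIBUTION",
    "build_density_profile",
    "simulate_reads",
    "write_fastq",
    "read_fastq",
    "truth_to_tsv",
]

#: Sentinel codon index meaning "the ORF's stop codon".
TERMINAL = "terminal"

#: Illumina TruSeq small-RNA 3' adapter used in the profiling libraries.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# Footprint lengths peak at 33-35 nt (monosome footprints are ~35 nt; gel
# excision spans ~30-40 nt); lengths above 35 exist to exercise the
# max-length filter downstream.
DEFAULT_LENGTH_DISTRIBUTION = {
    25: 0.02, 26: 0.02, 27: 0.03, 28: 0.04, 29: 0.05, 30: 0.07, 31: 0.09,
    32: 0.11, 33: 0.13, 34: 0.13, 35: 0.13, 36: 0.06, 37: 0.05, 38: 0.04,
    39: 0.02, 40: 0.01,
}


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class StallSpec:
    """A programmed stall: occupancy at ``codon_index`` (or the stop codon,
    with the TERMINAL sentinel) is multiplied by ``multiplier``; a trailing
    queued-ribosome peak ``queue_offset`` codons upstream is multiplied by
    ``queue_multiplier`` (default 12 codons, one ~35-nt footprint)."""

    gene: str
    codon_index: int | str = TERMINAL
    multiplier: float = 1.0
    queue_multiplier: float = 1.0
    queue_offset: int = 12

    def __post_init__(self):
        if self.multiplier < 1:
            raise SimulationError("stall multiplier must be >= 1")
        if self.queue_multiplier > 1 and self.queue_offset < 1:
            raise SimulationError("queue_offset must be >= 1 when a queue peak is set")


@dataclass
class SimulationConfig:
    n_reads: int = 50_000
    transcript_weights: dict[str, float] | None = None
    stalls: list[StallSpec] = field(default_factory=list)
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    offset: int = 14
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reads <= 0:
            raise SimulationError("n_reads must be positive")
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"length distribution sums to {total}, not 1")
        if self.offset + 3 > min(self.length_distribution):
            raise SimulationError("offset + 3 must fit inside the shortest footprint")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["stalls"] = [asdict(s) for s in self.stalls]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        d["stalls"] = [StallSpec(**s) for s in d.get("stalls", [])]
        return cls(**d)


def build_density_profile(
    orf: OrfAnnotation, stalls: list[StallSpec], base_density: float = 1.0
) -> np.ndarray:
    """Per-codon sampling weights for one ORF: ``base_density`` everywhere,
    multiplied by each applicable stall (and queued-ribosome) multiplier."""
    if base_density <= 0:
        raise SimulationError("base_density must be positive")
    w = np.full(orf.n_codons, float(base_density))
    for s in stalls:
        if s.gene != orf.gene:
            continue
        idx = orf.n_codons - 1 if s.codon_index == TERMINAL else int(s.codon_index)
        if not 0 <= idx < orf.n_codons:
            raise SimulationError(
                f"stall index {idx} out of range for {orf.gene} ({orf.n_codons} codons)"
            )
        w[idx] *= s.multiplier
        if s.queue_multiplier != 1.0:
            q = idx - s.queue_offset
            if q < 0:
                raise SimulationError(
                    f"queue peak at {q} out of range for {orf.gene} stall at {idx}"
                )
            w[q] *= s.queue_multiplier
    return w


def _footprint(genome: MitoGenome, orf: OrfAnnotation, codon_index: int, length: int, offset: int) -> str:
    """Genomic footprint whose 5' end (in mRNA sense) is ``offset`` nt upstream
    of the A-site codon's first base and extends ``length`` nt 3'-ward."""
    if orf.strand == "+":
        a = orf.start + 3 * codon_index
        return genome.fetch(a - offset, a - offset + length)
    a = orf.end - 1 - 3 * codon_index
    return reverse_complement(genome.fetch(a + offset - length + 1, a + offset + 1))


def simulate_reads(
    genome: MitoGenome, orfs: list[OrfAnnotation], config: SimulationConfig
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate a profiling library.

    Returns ``(records, truth)``: FASTQ records as (read_id, sequence,
    quality) tuples, and the ground-truth table with one row per read
    (read_id, gene, a_site_codon_index, strand, footprint_length). Identical
    seeds give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    by_gene = {o.gene: o for o in orfs}
    weights = config.transcript_weights or {g: 1.0 for g in by_gene}
    unknown = set(weights) - set(by_gene)
    if unknown:
        raise SimulationError(f"transcript weights for unknown genes: {sorted(unknown)}")

    genes = sorted(weights)
    densities = {g: build_density_profile(by_gene[g], config.stalls) for g in genes}
    gene_mass = np.array([weights[g] * densities[g].sum() for g in genes])
    if not gene_mass.sum() > 0:
        raise SimulationError("all sampling weights are zero")
    gene_p = gene_mass / gene_mass.sum()

    gene_draw = rng.choice(len(genes), size=config.n_reads, p=gene_p)
    lengths_avail = sorted(config.length_distribution)
    len_p = np.array([config.length_distribution[l] for l in lengths_avail])
    length_draw = rng.choice(lengths_avail, size=config.n_reads, p=len_p / len_p.sum())

    codon_draw = np.empty(config.n_reads, dtype=int)
    for gi, g in enumerate(genes):
        mask = gene_draw == gi
        d = densities[g]
        codon_draw[mask] = rng.choice(len(d), size=int(mask.sum()), p=d / d.sum())

    records, rows = [], []
    for i in range(config.n_reads):
        g = genes[gene_draw[i]]
        orf = by_gene[g]
        ci = int(codon_draw[i])
        L = int(length_draw[i])
        fp = _footprint(genome, orf, ci, L, config.offset)
        if config.substitution_rate > 0:
            fp = _mutate(rng, fp, config.substitution_rate)
        read = (fp + config.adapter)[: config.read_length]
        rid = f"read_{i:06d}"
        records.append((rid, read, "I" * len(read)))
        rows.append((rid, g, ci, orf.strand, L))

    truth = pd.DataFrame(
        rows, columns=["read_id", "gene", "a_site_codon_index", "strand", "footprint_length"]
    )
    return records, truth


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for j in np.flatnonzero(rng.random(len(seq)) < rate):
        out[j] = "ACGT"[(("ACGT".index(out[j])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def write_fastq(records: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = open
    if str(path).endswith(".gz"):
        import gzip

        opener = lambda p: io.TextIOWrapper(gzip.open(p))  # noqa: E731
    with opener(path) as fh:
        return [(title.split()[0], seq, qual) for title, seq, qual in FastqGeneralIterator(fh)]


def truth_to_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
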