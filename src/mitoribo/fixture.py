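"""Synthetic human-layout mitochondrial genome fixture.

Builds a deterministic circular genome whose 13 protein-coding ORFs mirror the
qualitative layout of human mtDNA: realistic gene sizes, one heavy-strand set
plus one light-strand gene (ND6), COX1 terminating at the non-canonical stop
AGA and ND6 at AGG, exactly one CGG codon in all mitochondrial ORFs (the
penultimate codon of ND6), two bicistronic overlaps (ATP8/ATP6 and ND4L/ND4),
and several genes whose terminal UAA stop is completed by polyadenylation.

The sequence is synthetic — coordinates and codon content are NOT those of the
reference human genome (NC_012920); load a real genome + annotation through
:mod:`mitoribo.genome` readers for accession-based analyses. The fixture's
purpose is to make every pipeline stage verifiable without any download while
preserving the codon-level facts the analysis depends on.
"""

from __future__ import annotations

import numpy as np

from .genome import (
    ALL_CODONS,
    MitoGenome,
    OrfAnnotation,
    codon_frequency,
    codons_of,
    reverse_complement,
)

__all__ = ["fixture_genome", "FIXTURE_SEED"]

FIXTURE_SEED = 28164  # fixed: the fixture is a constant, not a knob

# Codons never emitted by the random body sampler: the three vertebrate-mito
# stops that must only appear terminally, plus CGG, which occurs exactly once
# in human mitochondrial transcripts (at the end of ND6) and is planted there.
_FORBIDDEN = frozenset({"TAA", "TAG", "AGA", "AGG", "CGG"})
_BODY_CODONS = tuple(c for c in ALL_CODONS if c not in _FORBIDDEN)

# (gene, codon count, strand, start codon, stop codon, polyA completion)
# Sizes approximate the human genes; stops/strands/polyA follow the human
# pattern qualitatively: COX1 ends AGA, ND6 (light strand) ends AGG, and a few
# heavy-strand genes carry incomplete stops finished by polyadenylation.
_GENE_PLAN = [
    ("ND1", 318, "+", "ATG", "TAA", 0),
    ("ND2", 347, "+", "ATA", "TAG", 0),
    ("COX1", 513, "+", "ATG", "AGA", 0),
    ("COX2", 227, "+", "ATG", "TAG", 0),
    ("ATP8", 68, "+", "ATG", "TAA", 0),
    ("ATP6", 226, "+", "ATG", "TAA", 2),
    ("COX3", 261, "+", "ATG", "TAA", 1),
    ("ND3", 115, "+", "ATT", "TAA", 2),
    ("ND4L", 98, "+", "ATG", "TAA", 0),
    ("ND4", 459, "+", "ATG", "TAA", 1),
    ("ND5", 603, "+", "ATA", "TAA", 0),
    ("ND6", 174, "-", "ATG", "AGG", 0),
    ("CYTB", 380, "+", "ATG", "TAG", 0),
]

_OVERLAPS = {"ATP6": ("ATP8", 46), "ND4": ("ND4L", 7)}  # downstream: (upstream, nt)


def _rand_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(_BODY_CODONS), size=n)
    return [_BODY_CODONS[i] for i in idx]


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _gene_mrna(rng, n_codons, start_codon, stop_codon, penultimate=None) -> str:
    body = _rand_codons(rng, n_codons - 2 - (1 if penultimate else 0))
    tail = ([penultimate] if penultimate else []) + [stop_codon]
    return "".join([start_codon] + body + tail)


def _overlap_tail(rng, up_seg: str, overlap: int, n_codons: int, stop_codon: str, polya: int) -> str:
    """Genomic tail of a downstream ORF that starts ``overlap`` nt before the
    upstream ORF's end. The downstream reading frame over the shared bases must
    start with ATG and contain no stop/CGG codon; sampled by rejection."""
    assert up_seg[-overlap : -overlap + 3] == "ATG"
    shared = up_seg[-overlap:]
    n_shared_full = overlap // 3
    carry = overlap - 3 * n_shared_full  # bases of a codon split across the junction
    mrna_len = 3 * n_codons
    tail_len = mrna_len - polya - overlap
    pieces = []
    if carry:
        first = shared[3 * n_shared_full :]
        choices = [c for c in _BODY_CODONS if c.startswith(first)]
        pieces.append(choices[rng.integers(0, len(choices))][carry:])
    n_body = (tail_len - (3 - carry if carry else 0) - (3 - polya)) // 3
    pieces.extend(_rand_codons(rng, n_body))
    pieces.append(stop_codon[: 3 - polya] if polya else stop_codon)
    tail = "".join(pieces)
    assert len(tail) == tail_len
    return tail


def _clean_frame(seq: str) -> bool:
    return all(seq[i : i + 3] not in _FORBIDDEN for i in range(0, len(seq) - len(seq) % 3, 3))


def fixture_genome(spacer_min: int = 55, spacer_max: int = 75) -> tuple[MitoGenome, list[OrfAnnotation]]:
    """Build the synthetic human-layout genome and its 13-ORF annotation.

    Deterministic: the construction uses a fixed internal seed, so repeated
    calls return identical objects. Spacer lengths emulate the tRNA genes that
    punctuate mitochondrial transcripts.
    """
    rng = np.random.default_rng(FIXTURE_SEED)
    segments: list[str] = []
    orfs: list[OrfAnnotation] = []
    pos = 0

    def _spacer(length=None):
        nonlocal pos
        s = _rand_bases(rng, int(length or rng.integers(spacer_min, spacer_max + 1)))
        segments.append(s)
        pos += len(s)

    _spacer(620)  # control-region-like stretch at the origin

    plan = {g[0]: g for g in _GENE_PLAN}
    for gene, n_codons, strand, start_codon, stop_codon, polya in _GENE_PLAN:
        if gene in _OVERLAPS:
            continue  # emitted together with its upstream partner
        if gene == "ND6":
            mrna = _gene_mrna(rng, n_codons, start_codon, stop_codon, penultimate="CGG")
            seg = reverse_complement(mrna)
            segments.append(seg)
            orfs.append(OrfAnnotation(gene, pos, pos + len(seg), "-", 0))
            pos += len(seg)
        elif any(up == gene for up, _ in _OVERLAPS.values()):
            down = next(d for d, (u, _) in _OVERLAPS.items() if u == gene)
            _, dn_codons, dn_strand, _, dn_stop, dn_polya = plan[down]
            overlap = _OVERLAPS[down][1]
            # Rejection-sample the upstream gene until the downstream frame over
            # the shared bases is a clean ORF start (ATG, no stop/CGG codons).
            for _ in range(200_000):
                mrna = _gene_mrna(rng, n_codons, start_codon, stop_codon)
                seg = mrna[: len(mrna) - polya]
                shared = seg[-overlap:]
                if shared[:3] != "ATG":
                    continue
                if _clean_frame(shared[3:]):
                    break
            else:  # pragma: no cover - construction failure
                raise RuntimeError(f"could not construct {gene}/{down} overlap")
            tail = _overlap_tail(rng, seg, overlap, dn_codons, dn_stop, dn_polya)
            segments.append(seg + tail)
            orfs.append(OrfAnnotation(gene, pos, pos + len(seg), strand, polya))
            dn_start = pos + len(seg) - overlap
            orfs.append(OrfAnnotation(down, dn_start, dn_start + overlap + len(tail), dn_strand, dn_polya))
            pos += len(seg) + len(tail)
        else:
            mrna = _gene_mrna(rng, n_codons, start_codon, stop_codon)
            seg = mrna[: len(mrna) - polya]
            segments.append(seg)
            orfs.append(OrfAnnotation(gene, pos, pos + len(seg), strand, polya))
            pos += len(seg)
        _spacer()

    genome = MitoGenome(name="mito_fixture", sequence="".join(segments))
    _validate(genome, orfs)
    return genome, orfs


def _validate(genome: MitoGenome, orfs: list[OrfAnnotation]) -> None:
    freq = codon_frequency(genome, orfs)
    assert freq["CGG"] == 1, "fixture must contain exactly one in-frame CGG"
    terminal = {o.gene: codons_of(genome, o)[-1] for o in orfs}
    assert terminal["COX1"] == "AGA" and terminal["ND6"] == "AGG"
    n_canonical = sum(1 for c in terminal.values() if c in ("TAA", "TAG"))
    assert n_canonical == 11
    for o in orfs:
        codons = codons_of(genome, o)
        assert all(c not in ("TAA", "TAG", "AGA", "AGG") for c in codons[:-1]), o.gene
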