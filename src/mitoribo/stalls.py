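"""Occupancy statistics for stall detection.

Implements the descriptive statistics of codon-resolution mitoribosome
profiling:

* per-transcript relative occupancy — each gene's share of all A-site counts;
* size factors — mean gene total divided by each gene's total, so that scaled
  gene totals are equal across genes;
* terminal-window occupancy — the fraction of a gene's (size-factor-scaled)
  counts falling in its last 15 codons, the signature of ribosomes stalled at
  an unresolvable stop codon, with fold changes against a reference sample;
* codon-identity occupancy profiles and fold changes — counts aggregated by
  A-site codon identity, where AGA/AGG enrichment appears when the
  non-canonical-stop release factor is lost;
* an upstream queue scan locating the secondary peak left by a trailing
  ribosome stacked one footprint length (~12 codons) behind a stalled one.

All statistics keep exact integer counts until the final division. No
significance machinery is attached: these are descriptive per-gene and
per-codon quantities over 13 genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import MitoGenome, OrfAnnotation, codon_frequency, codons_of
from .occupancy import CodonCountTable

__all__ = [
    "relative_transcript_occupancy",
    "size_factors",
    "terminal_window_occupancy",
    "stall_fold_change",
    "StallReport",
    "stall_report",
    "CodonIdentityProfile",
    "codon_identity_profile",
    "codon_identity_fold_change",
    "QueueScanResult",
    "upstream_queue_scan",
]


def relative_transcript_occupancy(table: CodonCountTable, orfs: list[OrfAnnotation] | None = None) -> pd.Series:
    """Each gene's fraction of the sample's total A-site counts. Genes listed
    in the annotation but absent from the table appear with fraction 0."""
    totals = table.gene_totals
    if orfs is not None:
        totals = {o.gene: totals.get(o.gene, 0) for o in orfs}
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("empty count table")
    s = pd.Series(totals, dtype=float) / grand
    s.name = table.sample_id
    return s.sort_index()


def size_factors(table: CodonCountTable) -> pd.Series:
    """Per-gene size factor: the mean of the gene totals divided by each
    gene's total, so multiplying a gene's counts by its factor equalizes all
    gene totals at the pre-scaling mean. Zero-count genes are excluded with a
    warning (their factor is undefined)."""
    totals = {g: t for g, t in table.gene_totals.items() if t > 0}
    dropped = set(table.gene_totals) - set(totals)
    if dropped:
        warnings.warn(f"size factors undefined for zero-count genes: {sorted(dropped)}")
    if not totals:
        raise ValueError("all gene totals are zero")
    mean_total = np.mean(list(totals.values()))
    s = pd.Series({g: mean_total / t for g, t in totals.items()})
    s.name = table.sample_id
    return s.sort_index()


def _window_indices(orf: OrfAnnotation, window_codons: int, include_stop: bool) -> range:
    n = orf.n_codons
    if include_stop:
        return range(n - window_codons, n)
    return range(n - 1 - window_codons, n - 1)


def terminal_window_occupancy(
    table: CodonCountTable,
    orfs: list[OrfAnnotation],
    sf: pd.Series | None = None,
    window_codons: int = 15,
    include_stop: bool = True,
) -> pd.DataFrame:
    """Per-gene occupancy of the terminal window: the sum of size-factor-scaled
    counts over the gene's final ``window_codons`` codon positions (the stop
    plus 14 upstream by default; the 15 sense codons before the stop with
    ``include_stop=False``) divided by the scaled gene total.

    The size factor cancels within a gene; it is applied anyway so the
    window and total columns are comparable across samples, as in cross-sample
    fold-change displays. Genes shorter than the window are skipped with a
    warning. Columns: window_count, gene_total, window_occupancy (raw counts)
    plus their sf-scaled versions when ``sf`` is given.
    """
    rows = {}
    for orf in orfs:
        span = window_codons + (0 if include_stop else 1)
        if span >= orf.n_codons:
            warnings.warn(f"{orf.gene}: window of {window_codons} codons >= gene length; skipped")
            continue
        vec = table.gene_vector(orf)
        window = int(vec.iloc[list(_window_indices(orf, window_codons, include_stop))].sum())
        total = int(vec.sum())
        scale = float(sf.get(orf.gene, 1.0)) if sf is not None else 1.0
        rows[orf.gene] = {
            "window_count": window,
            "gene_total": total,
            "scaled_window_count": window * scale,
            "scaled_gene_total": total * scale,
            "window_occupancy": window / total if total else np.nan,
        }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.attrs["window_codons"] = window_codons
    df.attrs["include_stop"] = include_stop
    df.attrs["sample_id"] = table.sample_id
    return df


def stall_fold_change(
    sample_occ: pd.DataFrame,
    reference_occ: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene fold change of terminal-window occupancy versus a reference
    sample. When either side's window count is zero, a Haldane-style
    pseudocount is added to both window counts (and totals) before dividing.
    Genes absent from the reference are skipped with a warning."""
    for key in ("window_codons", "include_stop"):
        if sample_occ.attrs.get(key) != reference_occ.attrs.get(key):
            raise ValueError("sample and reference use different window definitions")
    fc = {}
    for gene, row in sample_occ.iterrows():
        if gene not in reference_occ.index:
            warnings.warn(f"{gene}: absent from reference; skipped")
            continue
        ref = reference_occ.loc[gene]
        ws, ts = row["window_count"], row["gene_total"]
        wr, tr = ref["window_count"], ref["gene_total"]
        if ts == 0 or tr == 0:
            warnings.warn(f"{gene}: zero gene total; skipped")
            continue
        if ws == 0 or wr == 0:
            ws, wr = ws + pseudocount, wr + pseudocount
            ts, tr = ts + pseudocount, tr + pseudocount
        fc[gene] = (ws / ts) / (wr / tr)
    s = pd.Series(fc).sort_index()
    s.name = "fold_change"
    return s


@dataclass
class StallReport:
    """Terminal-window stall quantification of one sample against a reference."""

    window_codons: int
    include_stop: bool
    pseudocount: float
    per_gene: pd.DataFrame  # window_occupancy (sample/reference), fold_change

    def to_tsv(self, path) -> None:
        header = (
            f"# terminal window: {self.window_codons} codons, "
            f"include_stop={self.include_stop}, pseudocount={self.pseudocount}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.per_gene.to_csv(fh, sep="\t", index_label="gene")


def stall_report(
    sample: CodonCountTable,
    reference: CodonCountTable,
    orfs: list[OrfAnnotation],
    window_codons: int = 15,
    include_stop: bool = True,
    pseudocount: float = 0.5,
) -> StallReport:
    """End-of-transcript stall quantification: per-gene terminal-window
    occupancy in both samples (size-factor scaled) and the fold change."""
    occ_s = terminal_window_occupancy(sample, orfs, size_factors(sample), window_codons, include_stop)
    occ_r = terminal_window_occupancy(reference, orfs, size_factors(reference), window_codons, include_stop)
    fc = stall_fold_change(occ_s, occ_r, pseudocount)
    per_gene = pd.DataFrame(
        {
            "window_occupancy": occ_s["window_occupancy"],
            "reference_window_occupancy": occ_r["window_occupancy"],
            "fold_change": fc,
        }
    )
    return StallReport(window_codons, include_stop, pseudocount, per_gene)


@dataclass
class CodonIdentityProfile:
    """Counts aggregated by A-site codon identity across all genes."""

    sample_id: str
    normalization: str  # 'total' or 'per_occurrence'
    raw_counts: pd.Series  # summed counts per codon identity
    values: pd.Series  # normalized values
    frequency_order: list[str]  # codon identities by mtDNA codon frequency
    coverage_order: list[str]  # codon identities by sequencing coverage

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": self.raw_counts, "value": self.values}
        ).rename_axis("codon")


def codon_identity_profile(
    table: CodonCountTable,
    genome: MitoGenome,
    orfs: list[OrfAnnotation],
    normalization: str = "total",
) -> CodonIdentityProfile:
    """Aggregate A-site counts by codon identity.

    ``normalization='total'`` divides the per-identity sums by the sample
    grand total (values sum to 1). ``'per_occurrence'`` additionally divides
    each identity by its occurrence count in the mitochondrial ORFs, giving
    occupancy per codon position; identities absent from the ORFs are excluded
    there. Both presentation orderings — by mtDNA codon frequency and by
    sequencing coverage — are carried along.
    """
    if normalization not in ("total", "per_occurrence"):
        raise ValueError(f"unknown normalization {normalization!r}")
    codons = {o.gene: codons_of(genome, o) for o in orfs}
    sums: dict[str, int] = {}
    for (g, i), c in table.counts.items():
        ident = codons[g][i]
        sums[ident] = sums.get(ident, 0) + c
    freq = codon_frequency(genome, orfs)
    raw = pd.Series({c: sums.get(c, 0) for c in freq}).sort_index()
    grand = raw.sum()
    if grand == 0:
        raise ValueError("empty count table")
    values = raw / grand
    if normalization == "per_occurrence":
        present = [c for c, n in freq.items() if n > 0]
        values = values[present] / pd.Series({c: freq[c] for c in present})
    freq_order = sorted(freq, key=lambda c: (-freq[c], c))
    cov_order = list(raw.sort_values(ascending=False, kind="stable").index)
    return CodonIdentityProfile(
        sample_id=table.sample_id,
        normalization=normalization,
        raw_counts=raw,
        values=values.sort_index(),
        frequency_order=freq_order,
        coverage_order=cov_order,
    )


def codon_identity_fold_change(
    sample: CodonIdentityProfile,
    reference: CodonIdentityProfile,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-codon-identity fold change of normalized occupancy versus the
    reference profile. Identities with a zero raw count on either side get a
    pseudocount on both raw counts (renormalized by the grand totals) and are
    flagged in the ``stabilized`` column."""
    if sample.normalization != reference.normalization:
        raise ValueError("profiles use different normalization modes")
    idx = sample.values.index.intersection(reference.values.index)
    fc, flagged = {}, {}
    gs, gr = sample.raw_counts.sum(), reference.raw_counts.sum()
    for c in idx:
        ns, nr = sample.raw_counts[c], reference.raw_counts[c]
        if ns == 0 or nr == 0:
            # per-occurrence divisor is identical on both sides and cancels
            vs = (ns + pseudocount) / (gs + pseudocount)
            vr = (nr + pseudocount) / (gr + pseudocount)
            fc[c] = vs / vr
            flagged[c] = True
        else:
            fc[c] = sample.values[c] / reference.values[c]
            flagged[c] = False
    return pd.DataFrame({"fold_change": pd.Series(fc), "stabilized": pd.Series(flagged)}).rename_axis("codon")


@dataclass(frozen=True)
class QueueScanResult:
    """Location of the strongest secondary peak upstream of a stall site."""

    offset_codons: int
    fold_over_median: float
    significant: bool


def upstream_queue_scan(
    table: CodonCountTable,
    orf: OrfAnnotation,
    stop_index: int | None = None,
    search_window: range = range(10, 17),
    significance_fold: float = 2.0,
) -> QueueScanResult:
    """Scan ``stop_index - k`` for k in ``search_window`` for the strongest
    secondary peak — the footprint of a ribosome queued behind one stalled at
    the stop (a ~35-nt footprint is ~12 codons, so queued peaks sit 12-13
    codons upstream). The peak height is expressed as fold over the gene's
    median per-codon count; folds below ``significance_fold`` are reported as
    non-significant."""
    stop = orf.n_codons - 1 if stop_index is None else stop_index
    if stop <= max(search_window):
        raise ValueError(f"{orf.gene}: search window extends past the start of the gene")
    vec = table.gene_vector(orf).astype(float)
    counts = {k: vec.iloc[stop - k] for k in search_window}
    best = max(counts, key=lambda k: (counts[k], -k))
    baseline = float(vec.median())
    if baseline == 0:
        baseline = float(vec.mean())
    if baseline == 0:
        raise ValueError(f"{orf.gene}: no counts on gene")
    fold = counts[best] / baseline
    return QueueScanResult(offset_codons=best, fold_over_median=fold, significant=fold >= significance_fold)
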