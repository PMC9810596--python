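"""Plotting helpers for occupancy statistics (matplotlib, Agg-safe)."""

from __future__ import annotations

import pandas as pd

from .genome import OrfAnnotation
from .occupancy import CodonCountTable


def plot_transcript_occupancy(occupancy: pd.Series, ax=None):
    """Bar chart of per-transcript relative mitoribosome occupancy."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    occupancy.plot.bar(ax=ax, color="#4878d0")
    ax.set_ylabel("fraction of total mtRPFs")
    ax.set_xlabel("")
    return ax


def plot_gene_profile(table: CodonCountTable, orf: OrfAnnotation, ax=None, last_n: int | None = None):
    """Per-codon A-site count histogram along one gene (optionally only the
    last ``last_n`` codons, the stall-diagnostic region)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    vec = table.gene_vector(orf)
    if last_n:
        vec = vec.iloc[-last_n:]
    ax.bar(vec.index, vec.values, width=1.0, color="#d65f5f")
    ax.set_xlabel(f"{orf.gene} codon index")
    ax.set_ylabel("A-site counts")
    return ax


def plot_stall_fold_changes(per_gene: pd.DataFrame, ax=None):
    """Per-gene terminal-window fold change versus the reference sample."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    per_gene["fold_change"].plot.bar(ax=ax, color="#6acc64")
    ax.axhline(1.0, color="k", lw=0.8)
    ax.set_ylabel("terminal-window occupancy fold change")
    return ax
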