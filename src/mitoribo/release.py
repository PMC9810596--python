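"""Arithmetic of the in vitro termination and translation assays.

A co-sedimentation release assay pellets ribosomes through a sucrose cushion:
radiolabeled peptide released by a release factor stays in the supernatant,
peptide still bound as peptidyl-tRNA pellets with the ribosome. The release
fraction is supernatant counts over total counts. Spontaneous release in the
absence of any factor (typically 10-15% of total peptide) is measured
separately and used as background; the default correction is simple
subtraction, clamped at zero, with the rescaled form
(sample - bg) / (1 - bg) available behind a flag.

The in vitro translation assay's active-ribosome fraction is the molar amount
of synthesized peptide per molar amount of ribosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReleaseMeasurement",
    "ActivityResult",
    "release_fraction",
    "background_corrected_activity",
    "active_ribosome_fraction",
    "summarize_release",
    "compare_conditions",
    "significance_stars",
]


@dataclass(frozen=True)
class ReleaseMeasurement:
    condition: str
    supernatant_counts: float
    pellet_counts: float
    replicate: int | None = None

    def __post_init__(self):
        if self.supernatant_counts < 0 or self.pellet_counts < 0:
            raise ValueError("scintillation counts must be non-negative")
        if self.supernatant_counts + self.pellet_counts <= 0:
            raise ValueError("total counts must be positive")


@dataclass(frozen=True)
class ActivityResult:
    raw_fraction: float
    background_fraction: float
    corrected_activity: float
    rescaled: bool


def release_fraction(m: ReleaseMeasurement) -> float:
    """Released-peptide fraction: supernatant counts over total counts."""
    return m.supernatant_counts / (m.supernatant_counts + m.pellet_counts)


def background_corrected_activity(
    sample_fraction: float, background_fraction: float, rescale: bool = False
) -> float:
    """Release activity after subtracting the no-factor (spontaneous release)
    background, clamped below at 0. With ``rescale=True`` the corrected value
    is expressed as a fraction of the releasable (non-spontaneous) peptide:
    (sample - bg) / (1 - bg)."""
    for name, f in (("sample", sample_fraction), ("background", background_fraction)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} fraction must be in [0, 1]")
    if sample_fraction < background_fraction:
        warnings.warn("sample fraction below background; clamping activity to 0")
    corrected = max(0.0, sample_fraction - background_fraction)
    if rescale and background_fraction < 1:
        corrected = corrected / (1 - background_fraction)
    return corrected


def active_ribosome_fraction(peptide_amount: float, ribosome_amount: float) -> float:
    """Fraction of ribosomes active in translation: moles of synthesized
    peptide per mole of ribosomes (same molar units). A value above 1 is
    reported with a warning — it signals a unit error."""
    if ribosome_amount <= 0:
        raise ValueError("ribosome amount must be positive")
    if peptide_amount < 0:
        raise ValueError("peptide amount must be non-negative")
    frac = peptide_amount / ribosome_amount
    if frac > 1:
        warnings.warn(f"active fraction {frac:.2f} > 1: check molar units")
    return frac


def significance_stars(p: float) -> str:
    """Conventional star annotation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_release(
    measurements: pd.DataFrame,
    background_condition: str,
    rescale: bool = False,
) -> pd.DataFrame:
    """Summarize replicate release measurements.

    ``measurements`` needs columns condition/replicate/supernatant/pellet.
    Per-replicate release fractions are background-corrected against the mean
    fraction of ``background_condition``; the result reports, per condition,
    mean and SD (ddof=1, n >= 2 required for SD) of raw and corrected
    fractions plus n.
    """
    required = {"condition", "supernatant", "pellet"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    df = measurements.copy()
    df["fraction"] = df["supernatant"] / (df["supernatant"] + df["pellet"])
    if background_condition not in set(df["condition"]):
        raise ValueError(f"background condition {background_condition!r} not in table")
    bg = float(df.loc[df["condition"] == background_condition, "fraction"].mean())
    df["corrected"] = [
        background_corrected_activity(f, bg, rescale=rescale) for f in df["fraction"]
    ]
    out = (
        df.groupby("condition")
        .agg(
            n=("fraction", "size"),
            mean_fraction=("fraction", "mean"),
            sd_fraction=("fraction", lambda x: np.std(x, ddof=1) if len(x) > 1 else np.nan),
            mean_activity=("corrected", "mean"),
            sd_activity=("corrected", lambda x: np.std(x, ddof=1) if len(x) > 1 else np.nan),
        )
        .sort_index()
    )
    out.attrs["background_condition"] = background_condition
    out.attrs["background_fraction"] = bg
    out.attrs["correction"] = "rescaled" if rescale else "subtraction"
    return out


def compare_conditions(
    measurements: pd.DataFrame, condition_a: str, condition_b: str
) -> tuple[float, float, str]:
    """Unpaired two-tailed t-test between the release fractions of two
    conditions; returns (t, p, stars)."""
    df = measurements.copy()
    df["fraction"] = df["supernatant"] / (df["supernatant"] + df["pellet"])
    a = df.loc[df["condition"] == condition_a, "fraction"]
    b = df.loc[df["condition"] == condition_b, "fraction"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per condition")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p), significance_stars(float(p))
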