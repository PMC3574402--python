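"""Abundance structure: relative abundance, rank-abundance curves, the
common/rare threshold split, and species-abundance-distribution histograms.

Abundance is measured in one of two currencies — numbers of individuals or
grams of wet biomass — and the same code paths serve both.  The histogram
uses half-open decade classes [10^k, 10^(k+1)) with k any integer, so
sub-gram biomass totals fall in negative classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurveyTable, ValidationError, species_summaries

__all__ = [
    "CURRENCIES",
    "abundance_vector",
    "relative_abundance",
    "CommonRarePartition",
    "partition_common_rare",
    "AbundanceClassHistogram",
    "log10_class_histogram",
    "rank_abundance_curve",
]

CURRENCIES = ("individuals", "biomass_g")


def abundance_vector(table: SurveyTable, currency: str = "individuals") -> pd.Series:
    """Per-species total abundance in the chosen currency."""
    if currency not in CURRENCIES:
        raise ValueError(f"currency must be one of {CURRENCIES}, got {currency!r}")
    summ = species_summaries(table)
    col = "n_individuals" if currency == "individuals" else "biomass_g"
    vec = summ[col].astype(float)
    vec.name = currency
    return vec


def relative_abundance(values: pd.Series | dict) -> pd.Series:
    """Normalise an abundance vector to proportions summing to 1."""
    vec = pd.Series(values, dtype=float)
    if len(vec) == 0:
        raise ValidationError("empty abundance vector")
    if (vec <= 0).any():
        bad = list(vec.index[vec <= 0][:10])
        raise ValidationError(f"abundances must be > 0 for detected species; offending {bad}")
    return vec / vec.sum()


@dataclass(frozen=True)
class CommonRarePartition:
    """Split of the species pool at a relative-abundance threshold.

    Species at or above the threshold are common; strictly below it, rare
    (the operational rule is strict "less than", so a species at exactly the
    threshold is common).
    """

    threshold: float
    common: frozenset
    rare: frozenset
    currency: str = "individuals"

    @property
    def species(self) -> frozenset:
        return self.common | self.rare


def partition_common_rare(
    proportions: pd.Series | dict,
    threshold: float = 0.01,
    currency: str = "individuals",
) -> CommonRarePartition:
    """Partition species into common (proportion >= threshold) and rare."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    p = pd.Series(proportions, dtype=float)
    if len(p) == 0:
        raise ValidationError("empty proportions")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError(f"proportions must sum to 1, got {p.sum():.6g}")
    rare = frozenset(p.index[p < threshold])
    common = frozenset(p.index[p >= threshold])
    return CommonRarePartition(threshold=threshold, common=common, rare=rare, currency=currency)


@dataclass(frozen=True)
class AbundanceClassHistogram:
    """Species counts per log10 abundance class, retaining the per-species
    class assignment so the histogram can later be deconstructed by
    occurrence group."""

    currency: str
    classes: pd.Series  # species -> integer decade class floor(log10 v)

    @property
    def counts(self) -> pd.Series:
        """Species count per class over the full contiguous class range."""
        lo, hi = int(self.classes.min()), int(self.classes.max())
        idx = pd.RangeIndex(lo, hi + 1, name="abundance_class")
        return self.classes.value_counts().reindex(idx, fill_value=0).astype(int)

    @property
    def total_species(self) -> int:
        return int(len(self.classes))

    def to_frame(self) -> pd.DataFrame:
        c = self.counts
        return pd.DataFrame({"abundance_class": c.index, "n_species": c.values})


def log10_class_histogram(values: pd.Series | dict, currency: str = "individuals") -> AbundanceClassHistogram:
    """Bin species into half-open decade classes [10^k, 10^(k+1))."""
    vec = pd.Series(values, dtype=float)
    if len(vec) == 0:
        raise ValidationError("empty abundance vector")
    if (vec <= 0).any():
        bad = list(vec.index[vec <= 0][:10])
        raise ValidationError(f"abundances must be > 0; offending {bad}")
    classes = pd.Series(
        [int(math.floor(math.log10(v))) for v in vec], index=vec.index, name="abundance_class"
    )
    return AbundanceClassHistogram(currency=currency, classes=classes.sort_index())


def rank_abundance_curve(proportions: pd.Series | dict) -> pd.DataFrame:
    """Rank-abundance (dominance) curve: descending relative abundance.

    Ties are broken by species identifier, lexicographically, so the curve
    is deterministic.
    """
    p = pd.Series(proportions, dtype=float)
    if len(p) == 0:
        raise ValidationError("empty proportions")
    frame = p.rename("relative_abundance").rename_axis("species").reset_index()
    frame = frame.sort_values(
        ["relative_abundance", "species"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame
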