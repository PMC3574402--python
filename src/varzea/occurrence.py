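"""Spatial and temporal occurrence: per-species persistence profiles, the
joint occurrence distribution whose bimodality separates core from satellite
species, and the deconstruction of abundance histograms by occurrence group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import AbundanceClassHistogram
from .data import SurveyTable, ValidationError

__all__ = [
    "occurrence_profiles",
    "JointOccurrenceDistribution",
    "joint_occurrence_distribution",
    "deconstruct_sad",
]


def occurrence_profiles(table: SurveyTable) -> pd.DataFrame:
    """Number of lakes and of seasons each species was detected in.

    Occupancy is detection-based (at least one individual, ever) and seasons
    pool across calendar years, so a species seen in the low-water season of
    two different years still counts one season.  Requires
    :func:`varzea.data.assign_seasons` to have run.
    """
    if not table.has_seasons:
        raise ValidationError("occurrence_profiles requires season labels; run assign_seasons first")
    g = table.records.groupby("species")
    out = pd.DataFrame(
        {
            "n_lakes": g["lake"].nunique().astype(int),
            "n_seasons": g["season"].nunique().astype(int),
        }
    )
    return out.sort_index()


@dataclass(frozen=True)
class JointOccurrenceDistribution:
    """Species counts over the (number of lakes, number of seasons) grid."""

    matrix: pd.DataFrame  # index n_lakes 1..L, columns n_seasons 1..T

    @property
    def lake_marginal(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def season_marginal(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    @property
    def total_species(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def modal_cells(self, k: int = 2) -> list[tuple[int, int]]:
        """The k cells holding the most species (ties broken by cell index)."""
        stacked = self.matrix.stack()
        stacked = stacked.sort_index()
        top = stacked.sort_values(ascending=False, kind="mergesort").head(k)
        return [(int(i), int(j)) for i, j in top.index]


def joint_occurrence_distribution(
    profiles: pd.DataFrame,
    n_lakes: int | None = None,
    n_seasons: int | None = None,
) -> JointOccurrenceDistribution:
    """Tally species over the (n_lakes, n_seasons) grid, 1..L by 1..T."""
    if len(profiles) == 0:
        raise ValidationError("empty occurrence profiles")
    L = int(n_lakes if n_lakes is not None else profiles["n_lakes"].max())
    T = int(n_seasons if n_seasons is not None else profiles["n_seasons"].max())
    if (profiles["n_lakes"] > L).any() or (profiles["n_seasons"] > T).any():
        raise ValidationError("profile exceeds declared grid size")
    mat = (
        pd.crosstab(profiles["n_lakes"], profiles["n_seasons"])
        .reindex(index=range(1, L + 1), columns=range(1, T + 1), fill_value=0)
        .astype(int)
    )
    mat.index.name = "n_lakes"
    mat.columns.name = "n_seasons"
    return JointOccurrenceDistribution(matrix=mat)


def deconstruct_sad(
    histogram: AbundanceClassHistogram,
    profiles: pd.DataFrame,
    group_by: str = "lakes",
) -> pd.DataFrame:
    """Split an abundance-class histogram by occurrence group.

    Returns tidy (abundance_class, group, n_species) rows where ``group`` is
    the raw integer occurrence level (number of lakes or of seasons).
    Summing over groups within a class recovers the plain histogram exactly.
    """
    if group_by not in ("lakes", "seasons"):
        raise ValueError("group_by must be 'lakes' or 'seasons'")
    col = "n_lakes" if group_by == "lakes" else "n_seasons"
    hist_species = set(histogram.classes.index)
    prof_species = set(profiles.index)
    if hist_species != prof_species:
        only_h = sorted(hist_species - prof_species)[:5]
        only_p = sorted(prof_species - hist_species)[:5]
        raise ValidationError(
            f"histogram and profiles cover different species (e.g. {only_h} vs {only_p})"
        )
    frame = pd.DataFrame(
        {
            "abundance_class": histogram.classes,
            "group": profiles.loc[histogram.classes.index, col].astype(int),
        }
    )
    tidy = (
        frame.groupby(["abundance_class", "group"], sort=True)
        .size()
        .rename("n_species")
        .reset_index()
    )
    return tidy


def mean_occurrence_by_class(
    histogram: AbundanceClassHistogram, profiles: pd.DataFrame, group_by: str = "lakes"
) -> pd.Series:
    """Mean occurrence level per abundance class (occupancy-abundance coupling)."""
    col = "n_lakes" if group_by == "lakes" else "n_seasons"
    levels = profiles.loc[histogram.classes.index, col].astype(float)
    return levels.groupby(histogram.classes).mean().rename(f"mean_{col}")
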