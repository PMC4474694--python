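"""Comparison of group attributes between species and seasons.

Group size is recorded in ordered categories, social composition and
activity as nominal categories; distributions are compared with a
two-sample Kolmogorov-Smirnov test on the binned CDFs (group size) and
chi-square contingency tests (composition, activity).  Mixed-species
groups are excluded from the single-species distributions and counted
separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from scipy.stats import chi2_contingency

from .occurrences import OccurrenceSet

__all__ = ["CategoricalDistribution", "TestResult", "ks_two_sample_binned",
           "chi_square_contingency", "summarize_groups"]


@dataclass
class CategoricalDistribution:
    """Counts over an ordered set of category labels."""

    categories: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.categories):
            raise ValueError("counts and categories differ in length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.counts) / self.total

    @classmethod
    def from_labels(cls, labels, categories: list[str]
                    ) -> "CategoricalDistribution":
        """Tabulate labels; empty labels are missing data, not a category."""
        s = pd.Series([l for l in labels if l != ""])
        counts = s.value_counts().reindex(categories).fillna(0).to_numpy()
        return cls(list(categories), counts)


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    df: int | None
    p_value: float


def ks_two_sample_binned(d1: CategoricalDistribution,
                         d2: CategoricalDistribution) -> TestResult:
    """Two-sample KS test on binned ordinal data.

    D is the maximum absolute difference of the two bin-level empirical
    CDFs; the p-value is the asymptotic Kolmogorov tail at
    D * sqrt(n1 n2 / (n1 + n2)).  No continuity correction is applied: the
    data are genuinely categorical.
    """
    if d1.categories != d2.categories:
        raise ValueError("category sets differ")
    if d1.total < 1 or d2.total < 1:
        raise ValueError("both distributions need at least one observation")
    d_stat = float(np.max(np.abs(d1.cdf() - d2.cdf())))
    en = np.sqrt(d1.total * d2.total / (d1.total + d2.total))
    p = float(kolmogorov(d_stat * en))
    return TestResult("KS D", d_stat, None, min(p, 1.0))


def chi_square_contingency(table) -> TestResult:
    """Pearson chi-square test for an r x c contingency table (no Yates
    correction); df = (rows - 1)(cols - 1)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a 2-D table with at least 2 rows and columns")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal row/column: expected counts undefined")
    stat, p, df, _ = chi2_contingency(table, correction=False)
    return TestResult("X2", float(stat), int(df), float(p))


def summarize_groups(occurrences: OccurrenceSet,
                     group_size_cats: list[str] | None = None,
                     composition_cats: list[str] | None = None,
                     activity_cats: list[str] | None = None) -> dict:
    """Bookkeeping tables: sighting counts by species, season and source;
    mixed-group counts by season; and per-species x season attribute
    distributions.

    Composition and activity distributions are restricted to the records
    where they were collected (systematic surveys); empty attribute fields
    are treated as missing, not as a category.  Mixed-species-group records
    are excluded from single-species distributions and counted separately.
    """
    from .occurrences import (ACTIVITY_CATS, COMPOSITION_CATS,
                              GROUP_SIZE_CATS)
    group_size_cats = group_size_cats or GROUP_SIZE_CATS
    composition_cats = composition_cats or COMPOSITION_CATS
    activity_cats = activity_cats or ACTIVITY_CATS

    t = occurrences.table
    single = t[t["mixed_group_id"] == ""]
    mixed = t[t["mixed_group_id"] != ""]

    counts = (single.groupby(["species", "season", "source"])
              .size().rename("n_sightings").reset_index())
    species_totals = single.groupby("species").size().to_dict()
    mixed_by_season = (mixed.groupby(["mixed_group_id", "season"])
                       .size().reset_index()
                       .groupby("season")["mixed_group_id"].count().to_dict())

    distributions: dict[tuple[str, str, str], CategoricalDistribution] = {}
    for (sp, season), sub in single.groupby(["species", "season"]):
        distributions[(sp, season, "group_size")] = (
            CategoricalDistribution.from_labels(sub["group_size_cat"],
                                                group_size_cats))
        syst = sub[sub["source"] == "systematic"]
        distributions[(sp, season, "composition")] = (
            CategoricalDistribution.from_labels(syst["composition"],
                                                composition_cats))
        distributions[(sp, season, "activity")] = (
            CategoricalDistribution.from_labels(syst["activity"],
                                                activity_cats))

    return {
        "counts": counts,
        "species_totals": species_totals,
        "mixed_groups_by_season": mixed_by_season,
        "n_mixed_groups": int(mixed["mixed_group_id"].nunique()),
        "distributions": distributions,
    }
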