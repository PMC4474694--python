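"""Sighting records: the point-observation side of the analysis.

An :class:`OccurrenceSet` wraps a tidy table of sightings (species, date,
season, planar position, survey source, and optional group attributes) and
knows how to round-trip itself through CSV.  Oceanographic seasons are
assigned from the record month: October–March is the warm season (thermal
front present), April–September the cold season.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: month -> season mapping used throughout: warm = Oct-Mar, cold = Apr-Sep
DEFAULT_SEASONS: dict[str, frozenset[int]] = {
    "warm": frozenset({10, 11, 12, 1, 2, 3}),
    "cold": frozenset({4, 5, 6, 7, 8, 9}),
}

#: ordered group-size categories
GROUP_SIZE_CATS = ["<10", "11-20", "21-50", "51-70", "71-100", ">100"]
#: social composition categories: adults+juveniles, mothers-with-calves, mixed
COMPOSITION_CATS = ["A+J", "MwC", "A+J+MwC"]
ACTIVITY_CATS = ["feeding", "traveling", "socializing", "resting", "milling",
                 "approach"]

COLUMNS = ["species", "date", "season", "x", "y", "source",
           "group_size_cat", "composition", "activity", "mixed_group_id"]


def season_of_month(month: int, seasons: dict[str, frozenset[int]] = DEFAULT_SEASONS) -> str:
    for name, months in seasons.items():
        if month in months:
            return name
    raise ValueError(f"month {month} not covered by season definition")


def season_of_date(date: _dt.date | str,
                   seasons: dict[str, frozenset[int]] = DEFAULT_SEASONS) -> str:
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return season_of_month(date.month, seasons)


@dataclass
class OccurrenceSet:
    """A table of sighting records with one row per group sighting."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns: {missing}")
        self.table = self.table[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def subset(self, species: str | None = None, season: str | None = None,
               source: str | None = None, exclude_mixed: bool = False) -> "OccurrenceSet":
        t = self.table
        if species is not None:
            t = t[t["species"] == species]
        if season is not None:
            t = t[t["season"] == season]
        if source is not None:
            t = t[t["source"] == source]
        if exclude_mixed:
            t = t[t["mixed_group_id"] == ""]
        return OccurrenceSet(t.copy())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        t = pd.read_csv(
            path,
            dtype={c: str for c in ("species", "date", "season", "source",
                                    "group_size_cat", "composition",
                                    "activity", "mixed_group_id")},
            keep_default_na=False,
        )
        t["x"] = t["x"].astype(float)
        t["y"] = t["y"].astype(float)
        return cls(t)

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        return self.table["x"].to_numpy(float), self.table["y"].to_numpy(float)
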