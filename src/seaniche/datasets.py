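"""Published reference values from the San Matías Gulf dolphin study.

These are the printed tables of the study this package's workflow follows:
per-source sighting counts and presence localities per species and season,
the mixed-species group counts, and the reported directional niche-overlap
indices.  They serve as reference inputs for bookkeeping checks and for
internal-consistency checks of the overlap statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .occurrences import GROUP_SIZE_CATS, OccurrenceSet

#: (species, season) -> (opportunistic, systematic, localities used in models)
SMG_SIGHTING_COUNTS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("common_dolphin", "cold"): (80, 46, 110),
    ("common_dolphin", "warm"): (38, 138, 148),
    ("dusky_dolphin", "cold"): (12, 85, 72),
    ("dusky_dolphin", "warm"): (9, 108, 93),
}

#: mixed-species group counts per season
SMG_MIXED_GROUPS = {"warm": 17, "cold": 8}

#: directional overlap report: (i, k, season) -> (SO_ik, U)
SMG_OVERLAP_TABLE: dict[tuple[str, str, str], tuple[float, float]] = {
    ("common_dolphin", "dusky_dolphin", "cold"): (0.242, 7360.0),
    ("common_dolphin", "dusky_dolphin", "warm"): (0.457, 5317.0),
    ("dusky_dolphin", "common_dolphin", "cold"): (0.029, 27671.0),
    ("dusky_dolphin", "common_dolphin", "warm"): (0.070, 37973.0),
}

#: cells carrying suitability scores in the published study (df = r - 1)
SMG_OVERLAP_CELLS = 25673


def reference_occurrences() -> OccurrenceSet:
    """A sighting table carrying exactly the published per-source counts per
    species and season, plus the published mixed-species group pairs.

    Positions and attributes are synthetic placeholders; only the counts
    are meaningful.
    """
    rows = []
    rng = np.random.default_rng(0)
    for (sp, season), (n_opp, n_sys, _) in SMG_SIGHTING_COUNTS.items():
        month = 11 if season == "warm" else 6
        for source, n in (("opportunistic", n_opp), ("systematic", n_sys)):
            for i in range(n):
                rows.append({
                    "species": sp, "date": f"2005-{month:02d}-15",
                    "season": season, "x": float(rng.uniform(0, 1000)),
                    "y": float(rng.uniform(0, 1000)), "source": source,
                    "group_size_cat": GROUP_SIZE_CATS[i % 3],
                    "composition": "A+J" if source == "systematic" else "",
                    "activity": "traveling" if source == "systematic" else "",
                    "mixed_group_id": "",
                })
    gid = 0
    for season, n_mixed in SMG_MIXED_GROUPS.items():
        month = 12 if season == "warm" else 5
        for _ in range(n_mixed):
            gid += 1
            for sp in ("common_dolphin", "dusky_dolphin"):
                rows.append({
                    "species": sp, "date": f"2005-{month:02d}-10",
                    "season": season, "x": 1.0, "y": 1.0,
                    "source": "systematic", "group_size_cat": "<10",
                    "composition": "A+J", "activity": "traveling",
                    "mixed_group_id": f"MX{gid:03d}",
                })
    return OccurrenceSet(pd.DataFrame(rows))
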