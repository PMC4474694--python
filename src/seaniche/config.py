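"""Pipeline configuration: one YAML-serialisable document, one master seed.

The master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master).spawn``; the spawn order is fixed
(seascape, occurrences, background, cross-validation, importance), so a run
is fully reproducible from the config alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

_STAGE_ORDER = ("seascape", "occurrences", "background", "cv", "importance")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs.

    In synthetic mode the pipeline generates its own seascape and sightings;
    in ingest mode it reads ``occurrences_csv``, ``bathy_csv`` and the dated
    SST rasters under ``sst_dir``.
    """

    outdir: str = "run_output"
    mode: str = "synthetic"            # "synthetic" | "ingest"
    seed: int = 0

    # ingest-mode inputs
    occurrences_csv: str | None = None
    bathy_csv: str | None = None
    sst_dir: str | None = None

    # synthetic-mode seascape block (SeascapeParams fields)
    seascape: dict = field(default_factory=dict)
    n_sightings_per_season: int = 400

    # layer construction
    depth_method: str = "kriging"      # "kriging" | "idw"
    correlation_threshold: float = 0.7
    correlation_method: str = "pearson"

    # model fitting
    n_background: int = 1000
    cv_folds: int = 25
    reg_multiplier: float = 1.0
    max_iter: int = 1000
    n_permutations: int = 2
    n_response_points: int = 51

    # overlap
    n_i_mode: str = "suitability_sum"

    def __post_init__(self):
        if self.mode not in ("synthetic", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest":
            for name in ("occurrences_csv", "bathy_csv", "sst_dir"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"ingest mode requires {name}")

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        """Per-stage child of the master seed (documented fan-out)."""
        if stage not in _STAGE_ORDER:
            raise ValueError(f"unknown stage seed {stage!r}")
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGE_ORDER))
        return children[_STAGE_ORDER.index(stage)]

    def stage_seed_int(self, stage: str) -> int:
        """A plain integer seed (< 2**31) derived for the stage."""
        return int(self.stage_seed(stage).generate_state(1)[0] % (2 ** 31))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def digest(self) -> str:
        """Stable hash of the canonical YAML form."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
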