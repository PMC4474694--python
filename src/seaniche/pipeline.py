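"""End-to-end orchestration: synthesise or ingest data, derive layers,
fit the per-species seasonal habitat models, and compute overlap and
group-attribute statistics, with a reproducible manifest.

Stages (independently re-runnable): ``synth`` writes the seascape and the
sighting table; ``layers`` builds the five predictors (depth kriged from
the sounding sample) and screens their correlations; ``fit`` runs the
cross-validated habitat model per species and season; ``overlap`` turns the
mean suitability surfaces into the directional overlap table; ``groups``
produces the sighting-bookkeeping and attribute-comparison tables.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import groups as groups_mod
from . import layers as layers_mod
from . import maxent as maxent_mod
from . import overlap as overlap_mod
from . import synth as synth_mod
from .config import PipelineConfig
from .grids import EnvStack, Raster, read_ascii_grid, write_ascii_grid
from .occurrences import (ACTIVITY_CATS, COMPOSITION_CATS, GROUP_SIZE_CATS,
                          OccurrenceSet, season_of_date)

logger = logging.getLogger(__name__)

STAGES = ("synth", "layers", "fit", "overlap", "groups")
__version__ = "0.1.0"


@dataclass
class RunManifest:
    """Reproducibility record of a pipeline run."""

    config_hash: str
    version: str = __version__
    started: str = ""
    finished: str = ""
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add_output(self, path: Path, root: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.checksums[str(path.relative_to(root))] = digest

    def to_json(self, path: Path) -> None:
        import json
        path.write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest, root: Path,
           float_format="%.10g"):
    df.to_csv(path, index=False, float_format=float_format)
    manifest.add_output(path, root)


def _write_raster(raster: Raster, path: Path, manifest: RunManifest,
                  root: Path, fmt="%.17g"):
    write_ascii_grid(raster, path, fmt=fmt)
    manifest.add_output(path, root)


def _stage_synth(cfg: PipelineConfig, out: Path, manifest: RunManifest,
                 ctx: dict):
    params = synth_mod.SeascapeParams(
        **{**cfg.seascape, "seed": cfg.stage_seed_int("seascape")})
    scape = synth_mod.make_seascape(params)
    truths = synth_mod.default_truths(cfg.n_sightings_per_season)
    stacks = scape.env_stacks()
    effort = synth_mod.default_effort(scape.grid)
    occ = synth_mod.simulate_occurrences(
        stacks, truths, effort, seed=cfg.stage_seed_int("occurrences"))

    d = out / "synth"
    d.mkdir(parents=True, exist_ok=True)
    occ.to_csv(d / "occurrences.csv")
    manifest.add_output(d / "occurrences.csv", out)
    pd.DataFrame(scape.bathy_points, columns=["x", "y", "depth"]).to_csv(
        d / "bathy_points.csv", index=False, float_format="%.17g")
    manifest.add_output(d / "bathy_points.csv", out)
    sst_dir = d / "sst"
    sst_dir.mkdir(exist_ok=True)
    for i, (date, raster) in enumerate(scape.sst_series):
        _write_raster(raster, sst_dir / f"sst_{i:03d}_{date.isoformat()}.asc",
                      manifest, out)
    _write_raster(scape.depth, d / "depth_true.asc", manifest, out)
    _write_raster(effort, d / "effort.asc", manifest, out)
    for (sp, season), raster in synth_mod.export_truth(stacks, truths).items():
        _write_raster(raster, d / f"truth_{sp}_{season}.asc", manifest, out)
    return {"occurrences": occ, "bathy_points": scape.bathy_points,
            "sst_series": scape.sst_series, "truths": truths}


def _load_sst_dir(sst_dir: Path):
    series = []
    for path in sorted(sst_dir.glob("*.asc")):
        date = _dt.date.fromisoformat(path.stem.split("_")[-1])
        series.append((date, read_ascii_grid(path, name="sst", units="degC")))
    if not series:
        raise ValueError(f"no .asc SST rasters found in {sst_dir}")
    return series


def _stage_layers(cfg: PipelineConfig, out: Path, manifest: RunManifest,
                  ctx: dict):
    if "sst_series" in ctx:
        sst_series = ctx["sst_series"]
        points = ctx["bathy_points"]
    else:
        sst_series = _load_sst_dir(Path(cfg.sst_dir))
        points = pd.read_csv(cfg.bathy_csv, float_precision="round_trip")[
            ["x", "y", "depth"]].to_numpy()
    grid = sst_series[0][1].grid

    depth = layers_mod.interpolate_depth(points, grid, method=cfg.depth_method)
    slope = layers_mod.slope_from_depth(depth)
    dist = layers_mod.distance_to_shore(grid)
    stats = layers_mod.seasonal_sst_stats(sst_series)

    d = out / "layers"
    d.mkdir(parents=True, exist_ok=True)
    stacks = {}
    for season, (mean_r, sd_r) in stats.items():
        stacks[season] = EnvStack([depth, slope, dist, mean_r, sd_r],
                                  season=season)
        matrix, flagged = layers_mod.correlation_screen(
            stacks[season], threshold=cfg.correlation_threshold,
            method=cfg.correlation_method)
        matrix.to_csv(d / f"correlation_{season}.csv",
                      float_format="%.4f", index_label="layer")
        manifest.add_output(d / f"correlation_{season}.csv", out)
        if flagged:
            msg = (f"correlation screen ({season}): flagged pairs {flagged}; "
                   "screening is advisory, proceeding with all layers")
            logger.warning(msg)
            manifest.warnings.append(msg)
    _write_raster(depth, d / "depth.asc", manifest, out)
    _write_raster(slope, d / "slope.asc", manifest, out)
    _write_raster(dist, d / "dist_shore.asc", manifest, out)
    for season, (mean_r, sd_r) in stats.items():
        _write_raster(mean_r, d / f"sst_{season}.asc", manifest, out)
        _write_raster(sd_r, d / f"sst_sd_{season}.asc", manifest, out)
    ctx["stacks"] = stacks
    return ctx


def _stage_fit(cfg: PipelineConfig, out: Path, manifest: RunManifest,
               ctx: dict):
    occ = ctx.get("occurrences")
    if occ is None:
        path = (Path(cfg.occurrences_csv) if cfg.mode == "ingest"
                else out / "synth" / "occurrences.csv")
        occ = OccurrenceSet.from_csv(path)
        ctx["occurrences"] = occ
    stacks = ctx["stacks"]
    d = out / "fit"
    d.mkdir(parents=True, exist_ok=True)

    rows = []
    surfaces = {}
    localities = {}
    for season, stack in sorted(stacks.items()):
        bg = maxent_mod.sample_background(
            stack.grid, cfg.n_background, cfg.stage_seed_int("background"))
        for species in occ.species:
            pres = maxent_mod.dedupe_presences(occ, stack.grid, species,
                                               season)
            localities[(species, season)] = pres.n_localities
            fs = maxent_mod.build_features(stack, pres.n_localities)
            cv = maxent_mod.cross_validate(
                pres, bg, fs, k=cfg.cv_folds,
                seed=cfg.stage_seed_int("cv"),
                reg_multiplier=cfg.reg_multiplier, max_iter=cfg.max_iter,
                n_permutations=cfg.n_permutations)
            logger.info("fit %s/%s: %d localities, AUC %.3f +/- %.3f",
                        species, season, pres.n_localities, cv.auc_mean,
                        cv.auc_sd)
            row = {"species": species, "season": season,
                   "n_localities": pres.n_localities,
                   "auc_mean": cv.auc_mean, "auc_sd": cv.auc_sd}
            row.update({f"imp_{name}": cv.importance[name]
                        for name in stack.names})
            rows.append(row)
            _write_raster(cv.mean_surface, d / f"suit_mean_{species}_{season}.asc",
                          manifest, out)
            _write_raster(cv.sd_surface, d / f"suit_sd_{species}_{season}.asc",
                          manifest, out)
            surfaces[(species, season)] = overlap_mod.SuitabilitySurface(
                cv.mean_surface)
            # response curves for the two top-importance variables
            for var in cv.importance.sort_values(ascending=False).index[:2]:
                curve = maxent_mod.response_curve(
                    stack, var, pres, bg, n_points=cfg.n_response_points,
                    reg_multiplier=cfg.reg_multiplier, max_iter=cfg.max_iter)
                _write(curve, d / f"response_{species}_{season}_{var}.csv",
                       manifest, out)
    _write(pd.DataFrame(rows), d / "cv_summary.csv", manifest, out)
    ctx["surfaces"] = surfaces
    ctx["localities"] = localities
    return ctx


def _stage_overlap(cfg: PipelineConfig, out: Path, manifest: RunManifest,
                   ctx: dict):
    surfaces = ctx.get("surfaces")
    if surfaces is None:
        surfaces = {}
        for path in sorted((out / "fit").glob("suit_mean_*.asc")):
            sp, season = path.stem[len("suit_mean_"):].rsplit("_", 1)
            surfaces[(sp, season)] = overlap_mod.SuitabilitySurface(
                read_ascii_grid(path, name="suitability"))
        ctx["surfaces"] = surfaces
    d = out / "overlap"
    d.mkdir(parents=True, exist_ok=True)
    report = overlap_mod.overlap_report(
        surfaces, n_i_mode=cfg.n_i_mode,
        locality_counts=ctx.get("localities"))
    _write(report, d / "overlap.csv", manifest, out)
    ctx["overlap"] = report
    return ctx


def _stage_groups(cfg: PipelineConfig, out: Path, manifest: RunManifest,
                  ctx: dict):
    occ = ctx.get("occurrences")
    if occ is None:
        path = (Path(cfg.occurrences_csv) if cfg.mode == "ingest"
                else out / "synth" / "occurrences.csv")
        occ = OccurrenceSet.from_csv(path)
    summary = groups_mod.summarize_groups(occ)
    d = out / "groups"
    d.mkdir(parents=True, exist_ok=True)
    _write(summary["counts"], d / "sighting_counts.csv", manifest, out)

    dist_rows = []
    for (sp, season, attr), dist in sorted(summary["distributions"].items()):
        for cat, n in zip(dist.categories, dist.counts):
            dist_rows.append({"species": sp, "season": season,
                              "attribute": attr, "category": cat,
                              "count": int(n)})
    _write(pd.DataFrame(dist_rows), d / "attribute_distributions.csv",
           manifest, out)

    # pairwise tests, mirroring the published comparisons
    tests = []
    dists = summary["distributions"]
    species = sorted({sp for (sp, _, _) in dists})
    seasons = sorted({se for (_, se, _) in dists})
    for season in seasons:
        for a, b in itertools.combinations(species, 2):
            ks = groups_mod.ks_two_sample_binned(
                dists[(a, season, "group_size")],
                dists[(b, season, "group_size")])
            tests.append({"comparison": f"{a} vs {b}", "season": season,
                          "attribute": "group_size", "test": ks.statistic_name,
                          "statistic": ks.statistic, "df": "",
                          "p_value": ks.p_value})
            for attr in ("composition", "activity"):
                table = np.vstack([dists[(a, season, attr)].counts,
                                   dists[(b, season, attr)].counts])
                table = table[:, table.sum(axis=0) > 0]
                if min(table.shape) < 2:
                    continue
                chi = groups_mod.chi_square_contingency(table)
                tests.append({"comparison": f"{a} vs {b}", "season": season,
                              "attribute": attr, "test": chi.statistic_name,
                              "statistic": chi.statistic, "df": chi.df,
                              "p_value": chi.p_value})
    for sp in species:
        if len(seasons) >= 2:
            a, b = seasons[:2]
            ks = groups_mod.ks_two_sample_binned(
                dists[(sp, a, "group_size")], dists[(sp, b, "group_size")])
            tests.append({"comparison": f"{a} vs {b}", "season": "",
                          "attribute": "group_size", "test": ks.statistic_name,
                          "statistic": ks.statistic, "df": "",
                          "p_value": ks.p_value})
    _write(pd.DataFrame(tests), d / "attribute_tests.csv", manifest, out)
    ctx["groups_summary"] = summary
    return ctx


def run_pipeline(cfg: PipelineConfig, stages=STAGES) -> RunManifest:
    """Run the requested stages in order and return the manifest.

    A stage failure aborts the run with the stage name in the error.  The
    manifest (written to ``<outdir>/manifest.json``) records a checksum of
    every output file; deterministic stages reproduce identical checksums
    under an identical config.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.digest(),
                           started=_dt.datetime.now().isoformat())
    ctx: dict = {}
    runners = {"synth": _stage_synth, "layers": _stage_layers,
               "fit": _stage_fit, "overlap": _stage_overlap,
               "groups": _stage_groups}
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if stage == "synth" and cfg.mode == "ingest":
            continue
        try:
            result = runners[stage](cfg, out, manifest, ctx)
            if isinstance(result, dict):
                ctx.update(result)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s complete", stage)
    manifest.finished = _dt.datetime.now().isoformat()
    manifest.to_json(out / "manifest.json")
    return manifest


def validate_inputs(cfg: PipelineConfig) -> list[dict]:
    """Machine-readable consistency report on the configured inputs.

    Checks grid agreement across SST rasters, occurrence coordinate ranges,
    season-label consistency with record dates, and the category
    vocabularies.  Returns a (possibly empty) list of problem records; it
    never raises for data problems.
    """
    problems: list[dict] = []
    out = Path(cfg.outdir)
    occ_path = (Path(cfg.occurrences_csv) if cfg.mode == "ingest"
                else out / "synth" / "occurrences.csv")
    sst_dir = (Path(cfg.sst_dir) if cfg.mode == "ingest"
               else out / "synth" / "sst")

    grid = None
    if sst_dir.is_dir():
        rasters = [read_ascii_grid(p) for p in sorted(sst_dir.glob("*.asc"))]
        if rasters:
            grid = rasters[0].grid
            for p, r in zip(sorted(sst_dir.glob("*.asc")), rasters):
                g = r.grid
                if not g.same_geometry(grid):
                    problems.append({"kind": "grid_mismatch",
                                     "message": f"{p.name}: cell_size/extent "
                                     "differs from first raster"})
    else:
        problems.append({"kind": "missing_input",
                         "message": f"SST directory {sst_dir} not found"})

    if occ_path.is_file():
        occ = OccurrenceSet.from_csv(occ_path)
        t = occ.table
        for idx, row in t.iterrows():
            expected = season_of_date(row["date"])
            if row["season"] != expected:
                problems.append({
                    "kind": "season_mismatch",
                    "message": f"record {idx}: dated {row['date']} but "
                               f"labelled {row['season']!r} (expected "
                               f"{expected!r})"})
        vocab = {"group_size_cat": GROUP_SIZE_CATS,
                 "composition": COMPOSITION_CATS,
                 "activity": ACTIVITY_CATS}
        for col, cats in vocab.items():
            bad = set(t[col]) - set(cats) - {""}
            if bad:
                problems.append({"kind": "vocabulary",
                                 "message": f"column {col}: unknown "
                                            f"categories {sorted(bad)}"})
        if grid is not None:
            row_i, col_i = grid.cell_of(t["x"].to_numpy(), t["y"].to_numpy())
            n_out = int((row_i < 0).sum())
            if n_out:
                problems.append({"kind": "out_of_grid",
                                 "message": f"{n_out} occurrence(s) outside "
                                            "the raster extent"})
    else:
        problems.append({"kind": "missing_input",
                         "message": f"occurrence table {occ_path} not found"})
    return problems
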