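"""Synthetic gulf seascape and occurrence generator with known ground truth.

The generator emulates a semi-enclosed gulf: a half-elliptical basin opening
eastward, coast on the west, north and south, a smooth bowl-shaped
bathymetry reaching ``max_depth`` (default 200 m) at the basin centre, a
warm-season thermal front separating a warm north-western water mass from a
cooler south-eastern one, a near-uniform cold-season temperature field, and
coastal upwelling patches that show up as elevated temporal SST variability
in both seasons.

Two default species truths with contrasting niches are provided: a narrow
"offshore thermal" species whose suitability tracks SST (warm season) and
SST variability (cold season), and a broad "coastal slope" species tied to
steep seabed close to shore.  Sightings are drawn with probability
proportional to true suitability times survey effort, carry the group
attributes a survey programme would record, deliberately include duplicate
records in the same cell, and occasionally pair the two species into
mixed-species groups (both species within 100 m).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import EnvStack, GridSpec, Raster
from .layers import distance_to_shore, seasonal_sst_stats, slope_from_depth
from .occurrences import (ACTIVITY_CATS, COMPOSITION_CATS, DEFAULT_SEASONS,
                          GROUP_SIZE_CATS, OccurrenceSet, season_of_month)

LAYER_NAMES = ["depth", "slope", "dist_shore", "sst", "sst_sd"]


@dataclass(frozen=True)
class SeascapeParams:
    """Knobs of the synthetic gulf.

    front_contrast is the warm-season NW-minus-SE SST difference in degC
    (default 1.6, the contrast between a 20.2 degC north-western and an
    18.6 degC south-eastern water mass); upwelling_sd is the temporal SST
    standard deviation at the centre of an upwelling patch.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1000.0
    max_depth: float = 200.0
    front_contrast: float = 1.6
    upwelling_sd: float = 1.0
    n_sst_dates_per_season: int = 12
    seed: int = 0
    sst_warm_base: float = 18.6
    sst_cold_base: float = 13.0
    noise_sd: float = 0.05
    date_offset_sd: float = 0.2
    depth_noise_sd: float = 12.0
    n_bathy_points: int = 400

    def __post_init__(self):
        if self.n_rows < 16 or self.n_cols < 16:
            raise ValueError(
                "grid too small to contain a gulf with interior cells "
                "(need n_rows, n_cols >= 16)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.max_depth <= 0:
            raise ValueError("max_depth must be positive")
        if self.n_sst_dates_per_season < 2:
            raise ValueError("need at least 2 SST dates per season")


@dataclass(frozen=True)
class SpeciesTruth:
    """A species' true habitat-suitability law.

    suitability_fn maps a dict of covariate arrays (keys from LAYER_NAMES)
    to suitability in [0, 1]; it must be deterministic.  dominant gives,
    per season, the covariate(s) that dominate the law — used by
    parameter-recovery assertions downstream.
    """

    name: str
    suitability_fn: Callable[[Mapping[str, np.ndarray]], np.ndarray]
    n_sightings_per_season: int = 400
    dominant: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def evaluate(self, cov: Mapping[str, np.ndarray]) -> np.ndarray:
        s = np.asarray(self.suitability_fn(cov), dtype=float)
        if np.nanmin(s) < -1e-9 or np.nanmax(s) > 1 + 1e-9:
            raise ValueError(f"truth {self.name!r} left [0, 1]")
        return np.clip(s, 0.0, 1.0)


@dataclass
class Seascape:
    """Everything make_seascape produces."""

    params: SeascapeParams
    grid: GridSpec                      # mask True on marine cells
    depth: Raster
    bathy_points: np.ndarray            # (n, 3) scattered x, y, depth sample
    sst_series: list                    # list of (datetime.date, Raster)

    def env_stacks(self) -> dict[str, EnvStack]:
        """Per-season predictor stacks built from the true (noise-free) fields."""
        slope = slope_from_depth(self.depth)
        dist = distance_to_shore(self.grid)
        stats = seasonal_sst_stats(self.sst_series)
        stacks = {}
        for season, (mean_r, sd_r) in stats.items():
            stacks[season] = EnvStack(
                [self.depth, slope, dist, mean_r, sd_r], season=season)
        return stacks


def _offshore_thermal_fn(cov):
    # narrow niche: a temperate SST band along the warm-season front, plus
    # elevated temporal SST variability (upwelling) in either season
    sst = cov["sst"]
    sstsd = cov["sst_sd"]
    s = (0.95 * np.exp(-0.5 * ((sst - 19.4) / 0.25) ** 2)
         + 0.55 * np.clip((sstsd - 0.35) / 0.45, 0, 1) + 0.005)
    return np.clip(s, 0, 1)


def _coastal_slope_fn(cov):
    # broad niche: steep seabed close to shore, with a non-zero floor
    # everywhere (the species ranges over the whole gulf at low density)
    s = (0.08 + 0.85 * np.clip(cov["slope"] / 1.0, 0, 1)
         * np.exp(-cov["dist_shore"] / 10000.0))
    return np.clip(s, 0, 1)


def default_truths(n_sightings_per_season: int = 400) -> list[SpeciesTruth]:
    """The two stock species: a narrow offshore-thermal niche and a broad
    coastal-slope niche."""
    return [
        SpeciesTruth(
            name="offshore_thermal",
            suitability_fn=_offshore_thermal_fn,
            n_sightings_per_season=n_sightings_per_season,
            dominant={"warm": ("sst",), "cold": ("sst_sd",)},
        ),
        SpeciesTruth(
            name="coastal_slope",
            suitability_fn=_coastal_slope_fn,
            n_sightings_per_season=n_sightings_per_season,
            dominant={"warm": ("slope", "dist_shore"),
                      "cold": ("slope", "dist_shore")},
        ),
    ]


def _gulf_mask(p: SeascapeParams):
    rows = np.arange(p.n_rows)[:, None]
    cols = np.arange(p.n_cols)[None, :]
    r0, c0 = 0.48 * p.n_rows, 0.62 * p.n_cols
    b, a = 0.40 * p.n_rows, 0.55 * p.n_cols
    rho2 = ((cols - c0) / a) ** 2 + ((rows - r0) / b) ** 2
    marine = rho2 <= 1.0
    return marine, np.sqrt(np.clip(rho2, 0, None))


def _season_dates(p: SeascapeParams, season: str, rng) -> list[_dt.date]:
    months = sorted(DEFAULT_SEASONS[season])
    dates = []
    for i in range(p.n_sst_dates_per_season):
        month = months[i % len(months)]
        year = int(rng.integers(2000, 2009))
        day = int(rng.integers(1, 29))
        dates.append(_dt.date(year, month, day))
    return sorted(dates)


def make_seascape(params: SeascapeParams | None = None) -> Seascape:
    """Generate the gulf: mask, depth field, bathymetric sample, dated SSTs.

    Deterministic: the same params (including seed) give bit-identical
    outputs.
    """
    p = params or SeascapeParams()
    ss = np.random.SeedSequence(p.seed)
    rng_depth, rng_sst, rng_bathy, rng_dates = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    marine, rho = _gulf_mask(p)
    if not marine.any() or marine.all():
        raise ValueError("gulf geometry degenerate for this grid size")
    grid = GridSpec(p.n_rows, p.n_cols, p.cell_size, origin_x=0.0,
                    origin_y=p.n_rows * p.cell_size, mask=marine)

    # bowl-shaped basin grading into a shallow shelf at the eastern mouth,
    # plus a smooth random field that vanishes at the coast
    bowl = p.max_depth * np.clip(1.0 - rho ** 2, 0, 1) ** 0.8
    cols_f = np.arange(p.n_cols)[None, :] * np.ones((p.n_rows, 1))
    w_shelf = 1.0 / (1.0 + np.exp(-(cols_f - 0.78 * p.n_cols) / 3.0))
    shelf = 60.0 * np.clip(1.0 - rho ** 2, 0, 1) ** 0.3
    base = (1.0 - w_shelf) * bowl + w_shelf * shelf
    noise = ndimage.gaussian_filter(rng_depth.standard_normal(grid.shape), 4.0)
    noise *= p.depth_noise_sd / max(noise.std(), 1e-12)
    depth_vals = np.clip(base + noise * np.clip(1.0 - rho, 0, 1), 0.2, None)
    depth = Raster(grid, np.where(marine, depth_vals, np.nan),
                   name="depth", units="m")

    # scattered sounding sample of the depth field (for kriging exercises)
    ridx = np.flatnonzero(marine.ravel())
    n_pts = min(p.n_bathy_points, len(ridx))
    pick = rng_bathy.choice(ridx, size=n_pts, replace=False)
    pr, pc = np.unravel_index(pick, grid.shape)
    xg, yg = grid.cell_centers()
    bathy_points = np.column_stack([xg[pr, pc], yg[pr, pc], depth_vals[pr, pc]])

    # NW-warm / SE-cold front pattern (0 in SE, 1 in NW), smooth step
    rows = np.arange(p.n_rows)[:, None] / max(p.n_rows - 1, 1)
    cols = np.arange(p.n_cols)[None, :] / max(p.n_cols - 1, 1)
    nw = 1.0 - (rows + cols) / 2.0
    front = 1.0 / (1.0 + np.exp(-(nw - 0.5) * 8.0))

    # coastal upwelling patches: fixed centres near the W and N coasts
    dist = ndimage.distance_transform_edt(marine, sampling=p.cell_size)
    coastal = marine & (dist < 8 * p.cell_size)
    patch_field = np.zeros(grid.shape)
    coastal_cells = np.argwhere(coastal)
    west_north = coastal_cells[
        ((coastal_cells[:, 1] < 0.5 * p.n_cols)
         | (coastal_cells[:, 0] < 0.35 * p.n_rows))
        & (coastal_cells[:, 0] / p.n_rows
           + coastal_cells[:, 1] / p.n_cols > 0.55)]
    if len(west_north):
        # four upwelling centres spread along the coast: upwelling geography
        # is anchored to topography, so the centres are placed at angular
        # quantiles around the basin rather than drawn at random
        ang = np.arctan2(west_north[:, 0] - 0.48 * p.n_rows,
                         west_north[:, 1] - 0.62 * p.n_cols)
        order = np.argsort(ang)
        k = min(4, len(order))
        sel = ((np.arange(k) + 0.5) * len(order) / k).astype(int)
        centers = west_north[order[sel]]
        rr = np.arange(p.n_rows)[:, None]
        cc = np.arange(p.n_cols)[None, :]
        for (pr_, pc_) in centers:
            d2 = (rr - pr_) ** 2 + (cc - pc_) ** 2
            patch_field = np.maximum(patch_field, np.exp(-d2 / (2 * 9.0 ** 2)))

    sst_series = []
    for season in ("warm", "cold"):
        dates = _season_dates(p, season, rng_dates)
        base_t = p.sst_warm_base if season == "warm" else p.sst_cold_base
        spatial = p.front_contrast * front if season == "warm" else 0.0
        # antithetic upwelling anomalies: exactly zero temporal mean per
        # cell, so patches raise the SST-SD map without shifting the mean
        n_dates = len(dates)
        half = rng_sst.normal(0.0, 1.0, size=(n_dates + 1) // 2)
        anoms = np.concatenate([half, -half])[:n_dates]
        if n_dates % 2 == 1:
            anoms[-1] = 0.0
        # normalise to unit sample SD so that upwelling_sd is exactly the
        # temporal SST-SD at a patch centre
        sd = anoms.std(ddof=1)
        if sd > 0:
            anoms = anoms / sd
        for date, z in zip(dates, anoms):
            date_offset = rng_sst.normal(0.0, p.date_offset_sd)
            upw = p.upwelling_sd * z
            field_t = (base_t + spatial + date_offset + upw * patch_field
                       + (p.noise_sd * rng_sst.standard_normal(grid.shape)
                          if p.noise_sd > 0 else 0.0))
            vals = np.where(marine, field_t, np.nan)
            sst_series.append((date, Raster(grid, vals, name="sst",
                                            units="degC")))
    sst_series.sort(key=lambda dr: dr[0])
    return Seascape(p, grid, depth, bathy_points, sst_series)


def default_effort(grid: GridSpec) -> Raster:
    """Heterogeneous survey effort: coastal boost over a uniform floor,
    emulating coastal transects plus offshore survey legs."""
    dist = distance_to_shore(grid)
    vals = 0.4 + 0.6 * np.exp(-dist.values / 20000.0)
    return Raster(grid, vals, name="effort", units="relative")


def _draw_attributes(rng, species_idx: int, n: int, systematic: np.ndarray):
    # group-size category distribution: both species dominated by small groups
    gs_probs = ([0.60, 0.18, 0.12, 0.05, 0.03, 0.02] if species_idx == 0
                else [0.72, 0.14, 0.08, 0.03, 0.02, 0.01])
    gs = rng.choice(GROUP_SIZE_CATS, size=n, p=gs_probs)
    comp = rng.choice(COMPOSITION_CATS, size=n, p=[0.6, 0.15, 0.25])
    act = rng.choice(ACTIVITY_CATS, size=n,
                     p=[0.25, 0.35, 0.02, 0.01, 0.15, 0.22])
    # composition and activity are only recorded on systematic surveys
    comp = np.where(systematic, comp, "")
    act = np.where(systematic, act, "")
    return gs, comp, act


def simulate_occurrences(stacks: Mapping[str, EnvStack],
                         truths: list[SpeciesTruth],
                         effort_surface: Raster,
                         seed: int = 0,
                         mixed_fraction: float = 0.04,
                         duplicate_fraction: float = 0.05) -> OccurrenceSet:
    """Draw sighting records from truth-times-effort sampling.

    For each season and species, sighting cells are drawn (with replacement,
    so same-cell duplicates occur) with probability proportional to true
    suitability times effort; positions are jittered uniformly within the
    cell.  A further ``duplicate_fraction`` of records is overwritten with
    copies of earlier cells to guarantee duplicates.  ``mixed_fraction`` of
    the smaller species' records per season are paired with a record of the
    other species placed within 100 m and tagged with a shared
    mixed_group_id.
    """
    if not truths:
        raise ValueError("truths list is empty")
    ev = effort_surface.valid_values()
    if np.any(ev < 0):
        raise ValueError("effort must be non-negative")
    if not np.any(ev > 0):
        raise ValueError("effort is zero everywhere")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    mixed_counter = 0
    for season, stack in sorted(stacks.items()):
        grid = stack.grid
        eff = effort_surface.values[grid.mask]
        cov = {name: stack[name].valid_values() for name in stack.names}
        rows_v, cols_v = np.nonzero(grid.mask)
        months = sorted(DEFAULT_SEASONS[season])
        season_rows: dict[str, list[int]] = {}
        for sp_idx, truth in enumerate(truths):
            w = truth.evaluate(cov) * eff
            tot = w.sum()
            if tot <= 0:
                raise ValueError(
                    f"no habitat with positive truth x effort for "
                    f"{truth.name!r} in season {season!r}")
            n = truth.n_sightings_per_season
            idx = rng.choice(len(w), size=n, replace=True, p=w / tot)
            n_dup = int(round(duplicate_fraction * n))
            if n_dup and n > n_dup:
                idx[-n_dup:] = idx[rng.integers(0, n - n_dup, size=n_dup)]
            r, c = rows_v[idx], cols_v[idx]
            jx = rng.uniform(0.05, 0.95, size=n)
            jy = rng.uniform(0.05, 0.95, size=n)
            x = grid.origin_x + (c + jx) * grid.cell_size
            y = grid.origin_y - (r + jy) * grid.cell_size
            month = rng.choice(months, size=n)
            year = rng.integers(2000, 2009, size=n)
            day = rng.integers(1, 29, size=n)
            dates = [f"{yy:04d}-{mm:02d}-{dd:02d}"
                     for yy, mm, dd in zip(year, month, day)]
            systematic = rng.random(n) < 0.6
            gs, comp, act = _draw_attributes(rng, sp_idx, n, systematic)
            start = len(records)
            for i in range(n):
                records.append({
                    "species": truth.name, "date": dates[i], "season": season,
                    "x": x[i], "y": y[i],
                    "source": "systematic" if systematic[i] else "opportunistic",
                    "group_size_cat": gs[i], "composition": comp[i],
                    "activity": act[i], "mixed_group_id": "",
                })
            season_rows[truth.name] = list(range(start, start + n))

        # pair some records of the two first species into mixed groups
        if len(truths) >= 2:
            a_rows = season_rows[truths[0].name]
            b_rows = season_rows[truths[1].name]
            n_mixed = int(round(mixed_fraction * min(len(a_rows), len(b_rows))))
            if n_mixed:
                pa = rng.choice(a_rows, size=n_mixed, replace=False)
                pb = rng.choice(b_rows, size=n_mixed, replace=False)
                for ia, ib in zip(pa, pb):
                    mixed_counter += 1
                    gid = f"MX{mixed_counter:03d}"
                    theta = rng.uniform(0, 2 * np.pi)
                    radius = rng.uniform(10.0, 50.0)  # < 100 m apart
                    records[ib]["x"] = records[ia]["x"] + radius * np.cos(theta)
                    records[ib]["y"] = records[ia]["y"] + radius * np.sin(theta)
                    records[ib]["date"] = records[ia]["date"]
                    records[ia]["mixed_group_id"] = gid
                    records[ib]["mixed_group_id"] = gid

    table = pd.DataFrame.from_records(records)
    return OccurrenceSet(table)


def export_truth(stacks: Mapping[str, EnvStack],
                 truths: list[SpeciesTruth]) -> dict[tuple[str, str], Raster]:
    """True-suitability rasters per (species, season), aligned to the stacks'
    grids, for parameter-recovery assertions."""
    out = {}
    for season, stack in stacks.items():
        cov = {name: stack[name].values for name in stack.names}
        for truth in truths:
            vals = np.clip(np.asarray(truth.suitability_fn(cov), float), 0, 1)
            vals = np.where(stack.grid.mask, vals, np.nan)
            out[(truth.name, season)] = Raster(
                stack.grid, vals, name=f"truth_{truth.name}_{season}")
    return out
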