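"""Presence-only maximum-entropy habitat modelling.

The model is the standard presence/background Gibbs formulation: over a
training domain of cells (the background sample united with the presence
cells) the species' distribution is q(x) = exp(eta(x)) / Z with
eta(x) = sum_f lambda_f f(x), and the weights maximise the L1-regularised
log-likelihood of the presence cells.  Feature classes follow the familiar
auto-features convention (linear always; quadratic from 10 presences; hinge
from 15; threshold and product from 80), each class carrying its own
regularisation scale.  Suitability is reported on the logistic scale
s = e^H q / (1 + e^H q), where H is the entropy of the fitted raw
distribution, so that a cell with "typical" presence conditions scores 0.5.

Model evaluation is by k-fold cross-validation of the presence cells
against the fixed background (test AUC), and variable contributions by
permutation importance: the normalised drop in training AUC when one
covariate's values are shuffled across the training points.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grids import EnvStack, GridSpec, Raster
from .occurrences import OccurrenceSet
from .overlap import SuitabilitySurface

logger = logging.getLogger(__name__)

ALL_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")

# auto-features activation thresholds (presence sample size)
AUTO_THRESHOLDS = {"linear": 0, "quadratic": 10, "hinge": 15,
                   "product": 80, "threshold": 80}

# per-class regularisation: interpolation nodes (sample size -> beta)
_BETA_TABLE = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "product": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "hinge": ([0, 1], [0.5, 0.5]),
    "threshold": ([0, 100], [2.0, 1.0]),
}


def _beta_for_class(cls: str, m: int) -> float:
    xs, ys = _BETA_TABLE[cls]
    return float(np.interp(m, xs, ys))


# ---------------------------------------------------------------------------
# presence handling


@dataclass
class PresenceSet:
    """Deduplicated presence cells for one species in one season."""

    species: str
    season: str
    cells: np.ndarray  # (n, 2) array of (row, col), unique

    def __post_init__(self):
        cells = np.asarray(self.cells, dtype=int).reshape(-1, 2)
        cells = np.unique(cells, axis=0)
        self.cells = cells
        if self.n_localities == 0:
            raise ValueError(
                f"no presence cells for {self.species}/{self.season}")

    @property
    def n_localities(self) -> int:
        return len(self.cells)


def dedupe_presences(occurrences: OccurrenceSet, grid: GridSpec,
                     species: str, season: str,
                     exclude_mixed: bool = False) -> PresenceSet:
    """Collapse sightings to one presence per occupied marine cell.

    Records falling on land or outside the grid are dropped (with a logged
    count); duplicate records in one cell count once.
    """
    sub = occurrences.subset(species=species, season=season,
                             exclude_mixed=exclude_mixed)
    if len(sub) == 0:
        raise ValueError(f"no records for {species}/{season}")
    x, y = sub.positions()
    row, col = grid.cell_of(x, y)
    inside = row >= 0
    on_sea = np.zeros(len(row), dtype=bool)
    on_sea[inside] = grid.mask[row[inside], col[inside]]
    dropped = int((~on_sea).sum())
    if dropped:
        logger.info("dedupe_presences(%s/%s): dropped %d record(s) on land "
                    "or outside grid", species, season, dropped)
    if not on_sea.any():
        raise ValueError(
            f"all records for {species}/{season} fall on land or off-grid")
    cells = np.column_stack([row[on_sea], col[on_sea]])
    return PresenceSet(species, season, cells)


def sample_background(grid: GridSpec, n: int, seed: int) -> np.ndarray:
    """Draw n distinct marine cells uniformly without replacement."""
    rows, cols = np.nonzero(grid.mask)
    if n > len(rows):
        raise ValueError(
            f"requested {n} background cells but only {len(rows)} marine "
            "cells exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=False)
    return np.column_stack([rows[idx], cols[idx]])


# ---------------------------------------------------------------------------
# features


@dataclass
class FeatureSet:
    """Feature expansion of the environmental covariates.

    Features are defined on min-max normalised covariates; the bounds are
    set from the training points (background plus presences), so every
    feature is bounded to [0, 1] on the training domain.  Out-of-range
    covariates at prediction time are clamped to the bounds.
    """

    stack: EnvStack
    classes: tuple[str, ...]
    n_hinge_knots: int = 8
    n_threshold_knots: int = 8
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    defs: list = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return self.stack.names

    @property
    def n_features(self) -> int:
        return len(self.defs)

    def set_bounds(self, X_train: np.ndarray) -> None:
        self.lower = X_train.min(axis=0)
        self.upper = X_train.max(axis=0)
        constant = self.upper - self.lower < 1e-12
        if constant.any():
            bad = [n for n, c in zip(self.names, constant) if c]
            warnings.warn(f"constant covariate(s) {bad}: non-linear features "
                          "degenerate and dropped")
        self._build_defs(constant)

    def _build_defs(self, constant: np.ndarray) -> None:
        nv = len(self.names)
        defs: list[tuple] = []
        for j in range(nv):
            if "linear" in self.classes:
                defs.append(("linear", j))
        for j in range(nv):
            if "quadratic" in self.classes and not constant[j]:
                defs.append(("quadratic", j))
        if "product" in self.classes:
            for j in range(nv):
                for k in range(j + 1, nv):
                    if not (constant[j] or constant[k]):
                        defs.append(("product", j, k))
        if "hinge" in self.classes:
            knots = np.linspace(0, 1, self.n_hinge_knots + 2)[1:-1]
            for j in range(nv):
                if constant[j]:
                    continue
                for t in knots:
                    defs.append(("hinge_fwd", j, float(t)))
                    defs.append(("hinge_rev", j, float(t)))
        if "threshold" in self.classes:
            knots = np.linspace(0, 1, self.n_threshold_knots + 2)[1:-1]
            for j in range(nv):
                if constant[j]:
                    continue
                for t in knots:
                    defs.append(("threshold", j, float(t)))
        self.defs = defs

    def normalize(self, X_raw: np.ndarray) -> np.ndarray:
        if self.lower is None:
            raise RuntimeError("bounds not set; call set_bounds first")
        rng = np.where(self.upper - self.lower < 1e-12, 1.0,
                       self.upper - self.lower)
        V = (np.clip(X_raw, self.lower, self.upper) - self.lower) / rng
        const = self.upper - self.lower < 1e-12
        V[:, const] = 0.5
        return V

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        """(n, n_features) feature matrix from raw covariates."""
        V = self.normalize(np.asarray(X_raw, dtype=float))
        cols = np.empty((V.shape[0], len(self.defs)))
        for i, d in enumerate(self.defs):
            kind, j = d[0], d[1]
            if kind == "linear":
                cols[:, i] = V[:, j]
            elif kind == "quadratic":
                cols[:, i] = V[:, j] ** 2
            elif kind == "product":
                cols[:, i] = V[:, j] * V[:, d[2]]
            elif kind == "hinge_fwd":
                t = d[2]
                cols[:, i] = np.clip((V[:, j] - t) / (1 - t), 0, 1)
            elif kind == "hinge_rev":
                t = d[2]
                cols[:, i] = np.clip((t - V[:, j]) / t, 0, 1)
            elif kind == "threshold":
                cols[:, i] = (V[:, j] >= d[2]).astype(float)
        return cols

    def feature_classes(self) -> np.ndarray:
        mapping = {"linear": "linear", "quadratic": "quadratic",
                   "product": "product", "hinge_fwd": "hinge",
                   "hinge_rev": "hinge", "threshold": "threshold"}
        return np.array([mapping[d[0]] for d in self.defs])

    def variable_of_feature(self) -> list[tuple[int, ...]]:
        """Indices of the covariates each feature depends on."""
        out = []
        for d in self.defs:
            out.append((d[1], d[2]) if d[0] == "product" else (d[1],))
        return out


def build_features(stack: EnvStack, presence_count: int,
                   classes: tuple[str, ...] | None = None,
                   n_hinge_knots: int = 8,
                   n_threshold_knots: int = 8) -> FeatureSet:
    """Assemble the feature set for a given presence sample size.

    With ``classes=None`` the auto-features convention applies: linear
    always, quadratic at >= 10 presences, hinge at >= 15, product and
    threshold at >= 80.
    """
    if classes is None:
        classes = tuple(c for c in ALL_CLASSES
                        if presence_count >= AUTO_THRESHOLDS[c])
    else:
        unknown = set(classes) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    return FeatureSet(stack, tuple(classes), n_hinge_knots, n_threshold_knots)


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model.

    weights are the feature coefficients lambda; log_z is the log normaliser
    over the training domain; entropy is H of the raw distribution q.
    """

    features: FeatureSet
    weights: np.ndarray
    log_z: float
    entropy: float
    n_train_domain: int
    converged: bool
    meta: dict = field(default_factory=dict)

    def eta(self, X_raw: np.ndarray) -> np.ndarray:
        return self.features.transform(X_raw) @ self.weights

    def raw(self, X_raw: np.ndarray) -> np.ndarray:
        """Raw (Gibbs) values q(x) = exp(eta - log Z)."""
        return np.exp(self.eta(X_raw) - self.log_z)

    def logistic(self, X_raw: np.ndarray) -> np.ndarray:
        """Logistic suitability in (0, 1); 0.5 at typical conditions."""
        t = self.entropy + self.eta(X_raw) - self.log_z
        return 1.0 / (1.0 + np.exp(-t))

    def to_json(self) -> str:
        fs = self.features
        doc = {
            "covariates": fs.names,
            "classes": list(fs.classes),
            "lower": fs.lower.tolist(),
            "upper": fs.upper.tolist(),
            "features": [list(d) for d in fs.defs],
            "weights": self.weights.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_train_domain": self.n_train_domain,
            "converged": self.converged,
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, bool, list))},
        }
        return json.dumps(doc, indent=1)


def _cells_union(presence_cells: np.ndarray, background: np.ndarray):
    dom = np.unique(np.vstack([presence_cells, background]), axis=0)
    return dom


def fit_maxent(features: FeatureSet, presences: PresenceSet,
               background: np.ndarray, reg_multiplier: float = 1.0,
               max_iter: int = 1000, tol: float = 1e-8) -> MaxentModel:
    """Fit the L1-penalised Gibbs model over background + presence cells.

    The penalised negative log-likelihood is minimised with L-BFGS-B on the
    positive/negative split of the weights, which handles the L1 penalty
    exactly; regularisation scales follow the per-class defaults times
    ``reg_multiplier``.  Non-convergence at ``max_iter`` returns the model
    with ``converged=False`` and a warning.
    """
    if presences.n_localities < 2:
        raise ValueError("need at least 2 presence cells")
    stack = features.stack
    background = np.asarray(background, dtype=int).reshape(-1, 2)
    domain = _cells_union(presences.cells, background)
    X_dom = stack.covariates_at(domain[:, 0], domain[:, 1])
    X_pres = stack.covariates_at(presences.cells[:, 0], presences.cells[:, 1])
    if features.lower is None:
        features.set_bounds(np.vstack([X_dom, X_pres]))

    F_dom = features.transform(X_dom)
    F_pres = features.transform(X_pres)
    f_bar = F_pres.mean(axis=0)

    m = presences.n_localities
    classes = features.feature_classes()
    s = F_pres.std(axis=0)
    s = np.maximum(s, 0.05)  # keep near-constant features regularised
    beta = np.array([_beta_for_class(c, m) for c in classes])
    beta = reg_multiplier * beta * s / np.sqrt(m)

    nf = features.n_features
    history: list[float] = []

    def objective(uv):
        lam = uv[:nf] - uv[nf:]
        eta = F_dom @ lam
        lse = logsumexp(eta)
        p = np.exp(eta - lse)
        nll = -(f_bar @ lam) + lse
        pen = beta @ (uv[:nf] + uv[nf:])
        g = F_dom.T @ p - f_bar
        grad = np.concatenate([g + beta, -g + beta])
        return nll + pen, grad

    x0 = np.zeros(2 * nf)

    def cb(xk):
        history.append(float(objective(xk)[0]))

    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * nf), callback=cb,
                   options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                            "ftol": tol, "gtol": 1e-9})
    lam = res.x[:nf] - res.x[nf:]
    converged = bool(res.success) or res.status == 0
    if not converged:
        warnings.warn(f"maxent optimiser did not converge: {res.message}")

    eta_dom = F_dom @ lam
    log_z = float(logsumexp(eta_dom))
    q = np.exp(eta_dom - log_z)
    entropy = float(log_z - q @ eta_dom)
    return MaxentModel(
        features=features, weights=lam, log_z=log_z, entropy=entropy,
        n_train_domain=len(domain), converged=converged,
        meta={"n_presences": m, "n_background": len(background),
              "reg_multiplier": reg_multiplier, "max_iter": max_iter,
              "n_iter": int(res.nit), "objective_history": history,
              "presence_cells": presences.cells,
              "background_cells": background},
    )


def predict_suitability(model: MaxentModel, stack: EnvStack | None = None
                        ) -> SuitabilitySurface:
    """Logistic suitability raster over the stack's marine cells.

    Covariates outside the training range are clamped to the range (a
    count is logged).
    """
    stack = stack or model.features.stack
    if stack.names != model.features.names:
        raise ValueError("stack layers do not match model covariates")
    X = stack.covariate_matrix()
    n_clamped = int(((X < model.features.lower)
                     | (X > model.features.upper)).any(axis=1).sum())
    if n_clamped:
        logger.info("predict_suitability: clamped covariates at %d cell(s)",
                    n_clamped)
    s = model.logistic(X)
    vals = np.full(stack.grid.shape, np.nan)
    vals[stack.grid.mask] = s
    raster = Raster(stack.grid, vals, name="suitability")
    return SuitabilitySurface(raster)


# ---------------------------------------------------------------------------
# evaluation


def compute_auc(scores_presence, scores_background) -> float:
    """Rank-based AUC: P(random presence outscores random background point),
    ties counted one half.  Equals the trapezoidal ROC area."""
    pos = np.asarray(scores_presence, dtype=float)
    neg = np.asarray(scores_background, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def permutation_importance(model: MaxentModel, presences: PresenceSet,
                           background: np.ndarray, seed: int = 0,
                           n_permutations: int = 5) -> pd.Series:
    """Per-variable importance percentages from the training-AUC drop.

    Each covariate's raw values are permuted jointly across all training
    points (presences and background); the mean drop in training AUC over
    ``n_permutations`` shuffles, floored at zero, is normalised to sum 100.
    """
    stack = model.features.stack
    background = np.asarray(background, dtype=int).reshape(-1, 2)
    X_pres = stack.covariates_at(presences.cells[:, 0], presences.cells[:, 1])
    X_bg = stack.covariates_at(background[:, 0], background[:, 1])
    X = np.vstack([X_pres, X_bg])
    n_pos = len(X_pres)
    base_scores = model.logistic(X)
    base_auc = compute_auc(base_scores[:n_pos], base_scores[n_pos:])
    rng = np.random.default_rng(seed)
    drops = np.zeros(len(stack.names))
    for j in range(len(stack.names)):
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            sc = model.logistic(Xp)
            drops[j] += base_auc - compute_auc(sc[:n_pos], sc[n_pos:])
    drops = np.maximum(drops / n_permutations, 0.0)
    if drops.sum() <= 0:
        warnings.warn("all permutation drops are zero; importance undefined, "
                      "reporting uniform")
        drops = np.ones_like(drops)
    pct = 100.0 * drops / drops.sum()
    return pd.Series(pct, index=stack.names, name="permutation_importance")


@dataclass
class CVResult:
    """Cross-validation summary for one species x season."""

    species: str
    season: str
    aucs: np.ndarray
    mean_surface: Raster
    sd_surface: Raster
    importance: pd.Series  # percentages, averaged over replicates
    models: list[MaxentModel] = field(default_factory=list)

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


def cross_validate(presences: PresenceSet, background: np.ndarray,
                   features: FeatureSet, k: int, seed: int = 0,
                   reg_multiplier: float = 1.0, max_iter: int = 1000,
                   n_permutations: int = 2,
                   keep_models: bool = False) -> CVResult:
    """k-fold cross-validation of the presence cells.

    Presence cells are shuffled and split into k folds; each replicate is
    fitted on k-1 folds and scored by AUC of the held-out presences against
    the full background.  Per-cell mean and SD suitability surfaces are
    taken across the k replicate models, and permutation importance is
    averaged over replicates.
    """
    n = presences.n_localities
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} presence localities")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    stack = features.stack

    aucs = []
    surfaces = []
    importances = []
    models = []
    for i, fold in enumerate(folds):
        train_idx = np.setdiff1d(order, fold)
        train = PresenceSet(presences.species, presences.season,
                            presences.cells[train_idx])
        fs = build_features(stack, train.n_localities,
                            classes=features.classes,
                            n_hinge_knots=features.n_hinge_knots,
                            n_threshold_knots=features.n_threshold_knots)
        model = fit_maxent(fs, train, background,
                           reg_multiplier=reg_multiplier, max_iter=max_iter)
        test_cells = presences.cells[fold]
        X_test = stack.covariates_at(test_cells[:, 0], test_cells[:, 1])
        X_bg = stack.covariates_at(background[:, 0], background[:, 1])
        aucs.append(compute_auc(model.logistic(X_test), model.logistic(X_bg)))
        surf = predict_suitability(model, stack)
        surfaces.append(surf.raster.values)
        importances.append(permutation_importance(
            model, train, background, seed=seed + 1000 + i,
            n_permutations=n_permutations))
        if keep_models:
            models.append(model)

    cube = np.stack(surfaces)
    mean_vals = cube.mean(axis=0)
    sd_vals = cube.std(axis=0, ddof=1) if len(surfaces) > 1 else np.zeros_like(mean_vals)
    imp = pd.concat(importances, axis=1).mean(axis=1)
    imp = 100.0 * imp / imp.sum()
    return CVResult(
        species=presences.species, season=presences.season,
        aucs=np.array(aucs),
        mean_surface=Raster(stack.grid, mean_vals, name="suitability_mean"),
        sd_surface=Raster(stack.grid, np.where(stack.grid.mask, sd_vals, np.nan),
                          name="suitability_sd"),
        importance=imp, models=models,
    )


def response_curve(stack: EnvStack, variable: str, presences: PresenceSet,
                   background: np.ndarray, n_points: int = 51,
                   reg_multiplier: float = 1.0,
                   max_iter: int = 1000) -> pd.DataFrame:
    """Univariate response curve: a model fitted on one variable alone,
    evaluated on a value grid spanning the training range.

    Returns a DataFrame with columns ``value`` and ``suitability``.
    """
    if variable not in stack:
        raise ValueError(f"variable {variable!r} not in stack")
    layer = stack[variable]
    sub = EnvStack([layer], season=stack.season)
    background = np.asarray(background, dtype=int).reshape(-1, 2)
    v_pres = layer.values[presences.cells[:, 0], presences.cells[:, 1]]
    v_bg = layer.values[background[:, 0], background[:, 1]]
    v_all = np.concatenate([v_pres, v_bg])
    if np.ptp(v_all) < 1e-12:
        raise ValueError(f"variable {variable!r} is constant over the "
                         "training points")
    # a single-variable model can afford a finer hinge/threshold lattice,
    # which sets the resolution of the curve's optimum
    fs = build_features(sub, presences.n_localities,
                        n_hinge_knots=16, n_threshold_knots=16)
    model = fit_maxent(fs, PresenceSet(presences.species, presences.season,
                                       presences.cells),
                       background, reg_multiplier=reg_multiplier,
                       max_iter=max_iter)
    grid_vals = np.linspace(v_all.min(), v_all.max(), n_points)
    suit = model.logistic(grid_vals[:, None])
    return pd.DataFrame({"value": grid_vals, "suitability": suit})


def response_optimum(curve: pd.DataFrame, frac: float = 0.90) -> float:
    """Location of a response curve's optimum.

    Hinge-based curves are piecewise linear and typically plateau near the
    maximum, so the bare argmax rides the plateau edge; the centre of the
    near-maximal region (suitability >= ``frac`` times the maximum) is a
    stabler estimate of the optimum.
    """
    v = curve["suitability"].to_numpy()
    x = curve["value"].to_numpy()
    top = x[v >= frac * v.max()]
    return float(top.mean())
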