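import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seaniche import (EnvStack, GridSpec, PresenceSet, build_features,
                      compute_auc, cross_validate, dedupe_presences,
                      fit_maxent, permutation_importance, predict_suitability,
                      response_curve, sample_background)
from seaniche.maxent import AUTO_THRESHOLDS, MaxentModel
from seaniche.occurrences import OccurrenceSet

from conftest import make_raster


def _occ_table(xy, species="sp", season="warm"):
    n = len(xy)
    return OccurrenceSet(pd.DataFrame({
        "species": species, "date": "2004-11-05", "season": season,
        "x": [p[0] for p in xy], "y": [p[1] for p in xy],
        "source": "systematic", "group_size_cat": "<10", "composition": "",
        "activity": "", "mixed_group_id": [""] * n,
    }))


def _toy_stack(seed=0, shape=(20, 20), n_layers=2, names=("u", "v")):
    rng = np.random.default_rng(seed)
    layers = [make_raster(rng.uniform(size=shape), name=names[i])
              for i in range(n_layers)]
    return EnvStack(layers)


# ---------------------------------------------------------------------------
# presences and background


def test_dedupe_counts_occupied_cells_once():
    grid = GridSpec(4, 4, 100.0, origin_y=400.0)
    occ = _occ_table([(50, 350), (60, 340), (55, 345), (250, 150), (260, 160)])
    pres = dedupe_presences(occ, grid, "sp", "warm")
    assert pres.n_localities == 2


def test_dedupe_distinct_cells_equals_sighting_count():
    grid = GridSpec(5, 5, 100.0, origin_y=500.0)
    xy = [(50 + 100 * i, 450) for i in range(5)]
    pres = dedupe_presences(_occ_table(xy), grid, "sp", "warm")
    assert pres.n_localities == 5


def test_dedupe_drops_land_and_offgrid_records():
    mask = np.ones((4, 4), dtype=bool)
    mask[0, 0] = True
    mask[3, :] = False
    grid = GridSpec(4, 4, 100.0, origin_y=400.0, mask=mask)
    occ = _occ_table([(50, 350), (50, 50), (-500, 50)])  # sea, land, off-grid
    pres = dedupe_presences(occ, grid, "sp", "warm")
    assert pres.n_localities == 1
    with pytest.raises(ValueError):
        dedupe_presences(_occ_table([(50, 50)]), grid, "sp", "warm")


def test_dedupe_known_occupancy(small_scape, small_occurrences):
    pres = dedupe_presences(small_occurrences, small_scape.grid,
                            "coastal_slope", "warm")
    row, col = small_scape.grid.cell_of(
        *small_occurrences.subset("coastal_slope", "warm").positions())
    expected = len(set(zip(row.tolist(), col.tolist())))
    assert pres.n_localities == expected


def test_background_sampling_contracts(small_scape):
    grid = small_scape.grid
    full = sample_background(grid, grid.n_valid, seed=0)
    assert len(np.unique(full, axis=0)) == grid.n_valid
    a = sample_background(grid, 100, seed=5)
    b = sample_background(grid, 100, seed=5)
    np.testing.assert_array_equal(a, b)
    assert len(np.unique(a, axis=0)) == 100
    assert grid.mask[a[:, 0], a[:, 1]].all()
    with pytest.raises(ValueError):
        sample_background(grid, grid.n_valid + 1, seed=0)


# ---------------------------------------------------------------------------
# features


def test_auto_feature_classes_follow_sample_size_thresholds():
    stack = _toy_stack()
    assert set(build_features(stack, 5).classes) == {"linear"}
    assert set(build_features(stack, 10).classes) == {"linear", "quadratic"}
    assert set(build_features(stack, 15).classes) == {"linear", "quadratic",
                                                      "hinge"}
    assert set(build_features(stack, 148).classes) == set(AUTO_THRESHOLDS)


def test_single_linear_feature_for_one_covariate():
    stack = _toy_stack(n_layers=1, names=("u",))
    fs = build_features(stack, 100, classes=("linear",))
    fs.set_bounds(stack.covariate_matrix())
    assert fs.n_features == 1


def test_features_bounded_to_unit_interval():
    stack = _toy_stack(seed=3)
    fs = build_features(stack, 100)
    X = stack.covariate_matrix()
    fs.set_bounds(X)
    F = fs.transform(X)
    assert F.min() >= 0.0 and F.max() <= 1.0


def test_constant_covariate_drops_nonlinear_features_with_warning():
    rng = np.random.default_rng(1)
    stack = EnvStack([make_raster(rng.uniform(size=(8, 8)), name="u"),
                      make_raster(np.full((8, 8), 2.0), name="c")])
    fs = build_features(stack, 148)
    with pytest.warns(UserWarning, match="constant"):
        fs.set_bounds(stack.covariate_matrix())
    kinds = {(d[0], d[1]) for d in fs.defs}
    assert ("quadratic", 1) not in kinds and ("linear", 1) in kinds


# ---------------------------------------------------------------------------
# fitting


def _fit_on(stack, presence_cells, n_bg=200, seed=0, **kw):
    pres = PresenceSet("sp", "warm", presence_cells)
    bg = sample_background(stack.grid, n_bg, seed=seed)
    fs = build_features(stack, pres.n_localities,
                        classes=kw.pop("classes", None))
    return fit_maxent(fs, pres, bg, **kw), pres, bg


def test_uniform_presences_give_near_uniform_model():
    stack = _toy_stack(seed=5)
    cells = sample_background(stack.grid, 300, seed=9)  # uniform presences
    model, pres, bg = _fit_on(stack, cells, n_bg=350, classes=("linear",))
    assert np.abs(model.weights).max() < 0.5
    assert model.entropy == pytest.approx(np.log(model.n_train_domain),
                                          rel=0.01)


def test_binary_covariate_gets_positive_weight_matching_1d_scan():
    vals = np.zeros((10, 10))
    vals[:, 5:] = 1.0
    stack = EnvStack([make_raster(vals, name="b")])
    cells = np.array([(r, c) for r in range(10) for c in range(5, 10)])
    model, pres, bg = _fit_on(stack, cells, n_bg=100, classes=("linear",))
    assert model.weights[0] > 0.5

    # dense 1-D scan of the penalised negative log-likelihood
    from scipy.special import logsumexp

    from seaniche.maxent import _beta_for_class

    fs = model.features
    dom = np.unique(np.vstack([pres.cells, bg]), axis=0)
    F_dom = fs.transform(stack.covariates_at(dom[:, 0], dom[:, 1]))[:, 0]
    F_pres = fs.transform(stack.covariates_at(pres.cells[:, 0],
                                              pres.cells[:, 1]))[:, 0]
    m = pres.n_localities
    b = (_beta_for_class("linear", m) * max(F_pres.std(), 0.05) / np.sqrt(m))

    def obj(lam):
        return -F_pres.mean() * lam + logsumexp(F_dom * lam) + b * abs(lam)

    lams = np.linspace(-1, 10, 11001)
    best = lams[np.argmin([obj(l) for l in lams])]
    assert model.weights[0] == pytest.approx(best, abs=1e-3)


def test_infinite_regularisation_shrinks_weights_to_zero():
    stack = _toy_stack(seed=6)
    rng = np.random.default_rng(2)
    cells = sample_background(stack.grid, 60, seed=3)
    model, _, _ = _fit_on(stack, cells, reg_multiplier=1e6)
    np.testing.assert_allclose(model.weights, 0.0, atol=1e-8)


def test_raw_distribution_sums_to_one(small_stacks, small_occurrences,
                                      small_scape):
    stack = small_stacks["warm"]
    pres = dedupe_presences(small_occurrences, small_scape.grid,
                            "offshore_thermal", "warm")
    bg = sample_background(stack.grid, 300, seed=1)
    fs = build_features(stack, pres.n_localities)
    model = fit_maxent(fs, pres, bg)
    dom = np.unique(np.vstack([pres.cells, bg]), axis=0)
    q = model.raw(stack.covariates_at(dom[:, 0], dom[:, 1]))
    assert q.sum() == pytest.approx(1.0, abs=1e-8)
    assert model.entropy >= 0.0


def test_penalised_objective_is_monotone_decreasing(small_stacks,
                                                    small_occurrences,
                                                    small_scape):
    stack = small_stacks["cold"]
    pres = dedupe_presences(small_occurrences, small_scape.grid,
                            "coastal_slope", "cold")
    bg = sample_background(stack.grid, 300, seed=2)
    fs = build_features(stack, pres.n_localities)
    model = fit_maxent(fs, pres, bg)
    hist = np.array(model.meta["objective_history"])
    assert len(hist) > 3
    assert (np.diff(hist) <= 1e-9).all()


def test_too_few_presences_rejected():
    stack = _toy_stack()
    with pytest.raises(ValueError, match="at least 2"):
        _fit_on(stack, np.array([[3, 3]]))


# ---------------------------------------------------------------------------
# prediction


def test_zero_weight_model_predicts_one_half_everywhere():
    stack = _toy_stack(seed=8)
    fs = build_features(stack, 50, classes=("linear",))
    X = stack.covariate_matrix()
    fs.set_bounds(X)
    n = len(X)
    model = MaxentModel(features=fs, weights=np.zeros(fs.n_features),
                        log_z=np.log(n), entropy=np.log(n),
                        n_train_domain=n, converged=True)
    surf = predict_suitability(model, stack)
    np.testing.assert_allclose(surf.raster.valid_values(), 0.5, atol=1e-12)


def test_monotone_model_preserves_covariate_order():
    stack = _toy_stack(seed=9, n_layers=1, names=("u",))
    fs = build_features(stack, 50, classes=("linear",))
    X = stack.covariate_matrix()
    fs.set_bounds(X)
    eta = X[:, 0] * 3.0
    log_z = float(np.log(np.sum(np.exp(eta))))
    q = np.exp(eta - log_z)
    model = MaxentModel(features=fs, weights=np.array([3.0]), log_z=log_z,
                        entropy=float(-(q * np.log(q)).sum()),
                        n_train_domain=len(X), converged=True)
    surf = predict_suitability(model, stack)
    s = surf.raster.valid_values()
    order = np.argsort(X[:, 0])
    assert (np.diff(s[order]) >= -1e-12).all()
    assert (s > 0).all() and (s < 1).all()


# ---------------------------------------------------------------------------
# AUC


def test_auc_trivial_cases():
    assert compute_auc([0.8, 0.9], [0.1, 0.2]) == 1.0
    assert compute_auc([0.9, 0.4], [0.5, 0.3]) == 0.75
    assert compute_auc([0.5], [0.5]) == 0.5  # tie counts one half


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=30),
       st.lists(st.floats(0, 1, width=32), min_size=1, max_size=30))
def test_auc_equals_allpairs_count(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    expected = wins / (len(pos) * len(neg))
    assert compute_auc(pos, neg) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# importance, cross-validation, response curves


def test_single_used_variable_takes_all_importance():
    rng = np.random.default_rng(11)
    stack = EnvStack([make_raster(rng.uniform(size=(15, 15)), name="u"),
                      make_raster(rng.uniform(size=(15, 15)), name="w")])
    vals = stack["u"].values
    cells = np.argwhere(vals > 0.6)
    model, pres, bg = _fit_on(stack, cells, n_bg=150, classes=("linear",))
    imp = permutation_importance(model, pres, bg, seed=0, n_permutations=10)
    assert imp["u"] > 95.0
    assert imp["w"] < 5.0


def test_cross_validation_mean_is_average_of_fold_aucs(small_stacks,
                                                       small_occurrences,
                                                       small_scape):
    stack = small_stacks["warm"]
    pres = dedupe_presences(small_occurrences, small_scape.grid,
                            "coastal_slope", "warm")
    bg = sample_background(stack.grid, 200, seed=3)
    fs = build_features(stack, pres.n_localities)
    cv = cross_validate(pres, bg, fs, k=2, seed=4, max_iter=200)
    assert len(cv.aucs) == 2
    assert cv.auc_mean == pytest.approx(np.mean(cv.aucs))
    assert cv.auc_sd == pytest.approx(np.std(cv.aucs, ddof=1))
    assert 0.0 <= cv.auc_mean <= 1.0
    assert cv.importance.sum() == pytest.approx(100.0)
    assert (cv.importance >= 0).all()
    # mean surface is an average over replicate predictions
    assert np.isfinite(cv.mean_surface.valid_values()).all()


def test_cross_validation_fold_contracts(small_stacks, small_occurrences,
                                         small_scape):
    stack = small_stacks["warm"]
    pres = dedupe_presences(small_occurrences, small_scape.grid,
                            "coastal_slope", "warm")
    bg = sample_background(stack.grid, 100, seed=3)
    fs = build_features(stack, pres.n_localities)
    with pytest.raises(ValueError):
        cross_validate(pres, bg, fs, k=1)
    with pytest.raises(ValueError):
        cross_validate(pres, bg, fs, k=pres.n_localities + 1)


def test_response_curve_contracts_and_range(small_stacks, small_occurrences,
                                            small_scape):
    stack = small_stacks["warm"]
    pres = dedupe_presences(small_occurrences, small_scape.grid,
                            "offshore_thermal", "warm")
    bg = sample_background(stack.grid, 200, seed=5)
    curve = response_curve(stack, "sst", pres, bg, n_points=15, max_iter=300)
    assert list(curve.columns) == ["value", "suitability"]
    assert len(curve) == 15
    assert ((curve["suitability"] > 0) & (curve["suitability"] < 1)).all()
    with pytest.raises(ValueError, match="not in stack"):
        response_curve(stack, "nope", pres, bg)
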