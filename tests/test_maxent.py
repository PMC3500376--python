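import numpy as np
import pytest
from scipy.special import logsumexp

from corridorscope.landscape import (
    LandscapeParams,
    gen_landscape,
    sample_presences_from_truth,
)
from corridorscope.maxent import (
    FeatureMatrix,
    auc_presence_background,
    build_features,
    constraint_violation,
    fit_maxent,
    jackknife,
    predict,
    presence_rows,
    split_points,
    suitability_to_resistance,
    variable_contributions,
)
from corridorscope.migration import pool_migration_points
from corridorscope.pointset import PointSet
from corridorscope.raster import GridSpec, RasterLayer


def feature_matrix_from_X(X, variables=None):
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    spec = GridSpec(n, 1, 30.0, origin_y=n * 30.0)
    cells = np.column_stack([np.arange(n), np.zeros(n, dtype=int)])
    names = tuple(f"f{j}" for j in range(k))
    return FeatureMatrix(
        X, names, tuple(variables) if variables else names, cells, spec, np.ones((n, 1), dtype=bool)
    )


@pytest.fixture(scope="module")
def spring_stack(default_landscape):
    return default_landscape.stacks["spring"]


@pytest.fixture(scope="module")
def spring_features(spring_stack):
    return build_features(spring_stack)


@pytest.fixture(scope="module")
def spring_fit(default_landscape, spring_features, default_tracks):
    tracks, _ = default_tracks
    pooled = pool_migration_points(tracks, "spring")
    train, test = split_points(pooled, 0.25, seed=7)
    rows = presence_rows(spring_features, train)
    model = fit_maxent(spring_features, rows, seed=7)
    return model, rows, train, test


class TestBuildFeatures:
    def test_feature_counting(self, spring_stack, spring_features):
        n_cont = 3  # dist_water, dist_roads, ndvi (dist_wells excluded)
        n_cats = sum(
            len(np.unique(spring_stack[r].valid_values()))
            for r in ("fence", "landcover", "topo_position")
        )
        assert spring_features.n_features == 2 * n_cont + n_cats

    def test_exclude_dist_wells_default(self, spring_features):
        assert all("dist_wells" not in n for n in spring_features.names)

    def test_continuous_standardized(self, spring_features):
        for j, name in enumerate(spring_features.names):
            if name.endswith(":linear") or name.endswith(":quadratic"):
                col = spring_features.X[:, j]
                assert abs(col.mean()) < 1e-9
                assert col.std() == pytest.approx(1.0)

    def test_zero_variance_rejected(self, default_landscape):
        import copy

        stack = copy.deepcopy(default_landscape.stacks["spring"])
        stack.layers["ndvi"] = stack["ndvi"].copy_with(np.full(stack.spec.shape, 0.5))
        with pytest.raises(ValueError, match="zero variance"):
            build_features(stack)


class TestFitMaxent:
    def test_toy_exact_constraint_satisfaction(self):
        # 5-cell landscape with per-cell indicators and beta=0: the Gibbs
        # weights must reproduce the empirical presence distribution
        X = np.eye(5)
        feats = feature_matrix_from_X(X)
        presence = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2, 3])
        model = fit_maxent(
            feats, presence, np.arange(5), beta=0.0, beta_mode="absolute", min_presence=1
        )
        scores = X @ model.lam
        q = np.exp(scores - logsumexp(scores))
        counts = np.bincount(presence, minlength=5) / len(presence)
        np.testing.assert_allclose(q, counts, atol=1e-6)

    def test_null_model_stays_at_zero(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((2000, 6))
        X = (X - X.mean(0)) / X.std(0)
        feats = feature_matrix_from_X(X)
        presence = rng.choice(2000, size=400, replace=False)
        model = fit_maxent(feats, presence, np.arange(2000), beta=0.1, beta_mode="absolute")
        assert np.all(np.abs(model.lam) <= 0.05)

    def test_concentrated_presences_positive_sign(self):
        rng = np.random.default_rng(6)
        x1 = rng.standard_normal(1000)
        X = np.column_stack([(x1 - x1.mean()) / x1.std()])
        feats = feature_matrix_from_X(X)
        presence = np.argsort(x1)[-100:]
        model = fit_maxent(feats, presence, np.arange(1000))
        assert model.lam[0] > 0

    def test_min_presence_enforced(self, spring_features):
        with pytest.raises(ValueError, match="at least 20"):
            fit_maxent(spring_features, np.arange(5))

    def test_objective_non_decreasing(self, spring_fit):
        model, *_ = spring_fit
        assert np.all(np.diff(model.objective_path) >= -1e-12)

    def test_constraint_satisfaction_on_real_fit(self, spring_features, spring_fit):
        model, rows, *_ = spring_fit
        assert constraint_violation(model, spring_features, rows) <= 1e-6


class TestPredict:
    def test_raw_sums_to_one_over_background(self, spring_features, spring_fit):
        model, *_ = spring_fit
        raw = predict(model, spring_features, "raw")
        cells = spring_features.cells[model.background_rows]
        assert raw.values[cells[:, 0], cells[:, 1]].sum() == pytest.approx(1.0)

    def test_uniform_model_logistic_half(self):
        X = np.eye(4)
        feats = feature_matrix_from_X(X)
        model = fit_maxent(
            feats, np.arange(4), np.arange(4), beta=10.0, beta_mode="absolute", min_presence=1
        )
        assert np.all(model.lam == 0)
        logi = predict(model, feats, "logistic")
        np.testing.assert_allclose(logi.values[feats.mask], 0.5, atol=1e-12)

    def test_log_rank_identical_to_raw(self, spring_features, spring_fit):
        model, *_ = spring_fit
        raw = predict(model, spring_features, "raw").values[spring_features.mask]
        log = predict(model, spring_features, "log").values[spring_features.mask]
        assert np.array_equal(np.argsort(raw), np.argsort(log))

    def test_feature_mismatch_rejected(self, spring_fit):
        model, *_ = spring_fit
        other = feature_matrix_from_X(np.eye(3))
        with pytest.raises(ValueError, match="match"):
            predict(model, other)


class TestSplitPoints:
    def test_100_points(self):
        pts = PointSet(np.arange(100.0), np.arange(100.0))
        train, test = split_points(pts, 0.25, seed=1)
        assert (len(train), len(test)) == (75, 25)

    def test_paper_scale_arithmetic(self):
        pts = PointSet(np.arange(5364.0), np.zeros(5364))
        train, test = split_points(pts, 0.25, seed=1)
        assert (len(train), len(test)) == (4023, 1341)

    def test_disjoint_exhaustive_deterministic(self):
        pts = PointSet(np.arange(57.0), np.zeros(57))
        t1a, t2a = split_points(pts, 0.25, seed=9)
        t1b, t2b = split_points(pts, 0.25, seed=9)
        np.testing.assert_array_equal(t1a.x, t1b.x)
        assert set(t1a.x) | set(t2a.x) == set(pts.x)
        assert not set(t1a.x) & set(t2a.x)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_presence_background([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_identical_distributions_expectation(self):
        rng = np.random.default_rng(0)
        aucs = [
            auc_presence_background(rng.random(200), rng.random(200)) for _ in range(50)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_brute_force_pair_example(self):
        # exhaustive over the 4 pairs: (0.9>0.5) + (0.9>0.1) + (0.4<0.5 -> 0) + (0.4>0.1) = 3/4
        presence, background = [0.9, 0.4], [0.5, 0.1]
        wins = sum(
            1.0 if p > b else (0.5 if p == b else 0.0) for p in presence for b in background
        )
        assert wins / 4 == 0.75
        assert auc_presence_background(presence, background) == pytest.approx(wins / 4)


class TestContributions:
    def test_single_variable_is_100(self):
        rng = np.random.default_rng(3)
        x1 = rng.standard_normal(500)
        feats = feature_matrix_from_X(
            np.column_stack([(x1 - x1.mean()) / x1.std()]), variables=["v"]
        )
        model = fit_maxent(feats, np.argsort(x1)[-80:], np.arange(500))
        contrib = variable_contributions(model)
        assert contrib == {"v": pytest.approx(100.0)}

    def test_sum_is_100(self, spring_fit):
        model, *_ = spring_fit
        assert sum(variable_contributions(model).values()) == pytest.approx(100.0, abs=0.1)

    def test_ndvi_recovery_across_seeds(self):
        wins = 0
        for seed in range(10):
            land = gen_landscape(LandscapeParams(seed=seed), seasons=("spring",))
            stack = land.stacks["spring"]
            suit = land.truths["spring"].suitability(stack)
            feats = build_features(stack)
            pres = presence_rows(feats, sample_presences_from_truth(suit, 2000, seed=seed + 1000))
            model = fit_maxent(feats, pres, seed=seed)
            contrib = variable_contributions(model)
            wins += max(contrib, key=contrib.get) == "ndvi"
        assert wins >= 9


@pytest.fixture(scope="module")
def jackknife_toy():
    rng = np.random.default_rng(11)
    signal = rng.standard_normal(1500)
    noise = rng.standard_normal(1500)
    X = np.column_stack(
        [
            (signal - signal.mean()) / signal.std(),
            (signal - signal.mean()) / signal.std(),  # duplicate of the informative variable
            (noise - noise.mean()) / noise.std(),
        ]
    )
    feats = feature_matrix_from_X(X, variables=["sig_a", "sig_b", "noise"])
    presence = np.argsort(signal)[-150:]
    return feats, jackknife(feats, presence, np.arange(1500))


class TestJackknife:
    def test_pure_noise_only_gain_near_zero(self, jackknife_toy):
        _, table = jackknife_toy
        assert table["noise"]["only_gain"] < 0.02 * table["sig_a"]["only_gain"]

    def test_duplicated_variable_withhold_loses_nothing(self, jackknife_toy):
        _, table = jackknife_toy
        assert table["sig_a"]["without_gain"] == pytest.approx(table["sig_a"]["full_gain"], rel=0.01)

    def test_gains_non_negative(self, jackknife_toy):
        _, table = jackknife_toy
        for row in table.values():
            assert row["only_gain"] >= -1e-9
            assert row["without_gain"] >= -1e-9


class TestResistance:
    def test_maxent_mode_endpoints_and_rank(self):
        rng = np.random.default_rng(4)
        vals = rng.random((6, 6)) * 1e-3 + 1e-6
        layer = RasterLayer(GridSpec(6, 6, 30.0), vals)
        res = suitability_to_resistance(layer, "maxent")
        assert res.values[np.unravel_index(vals.argmax(), vals.shape)] == pytest.approx(0.01)
        assert res.values[np.unravel_index(vals.argmin(), vals.shape)] == pytest.approx(1.0)
        assert np.array_equal(np.argsort(vals.ravel()), np.argsort(-res.values.ravel()))

    def test_constant_rejected(self):
        layer = RasterLayer(GridSpec(2, 2, 30.0), np.full((2, 2), 0.3))
        with pytest.raises(ValueError):
            suitability_to_resistance(layer, "maxent")


class TestHoldoutAUC:
    def test_auc_above_0_6(self, spring_features, spring_fit):
        model, _, _, test = spring_fit
        logi = predict(model, spring_features, "logistic")
        test_rows = presence_rows(spring_features, test, dedupe=False)
        cells = spring_features.cells
        sc = logi.values[cells[test_rows, 0], cells[test_rows, 1]]
        bg_cells = cells[model.background_rows]
        bg = logi.values[bg_cells[:, 0], bg_cells[:, 1]]
        assert auc_presence_background(sc, bg) > 0.6
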