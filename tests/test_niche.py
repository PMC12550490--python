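"""Occurrence thinning, raster PCA, Maxent fitting/selection, area series
and spatial autocorrelation."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from paleoterrapin import niche
from paleoterrapin.niche import (
    OccurrenceSet,
    auc_presence_background,
    crop_with_buffer,
    evaluate_and_select,
    expand_features,
    fit_maxent,
    model_predict,
    model_raw,
    morans_i,
    project_and_area,
    raster_pca,
    sample_background,
    suitability_surface,
    thin_occurrences,
)
from paleoterrapin.rasters import RasterStack, haversine_km


def grid_stack(layers, cell_deg=0.05, cell_km=4.5):
    return RasterStack(layers, cell_size_deg=cell_deg, cell_size_km=cell_km)


class TestThinning:
    def test_two_close_points_keep_one(self):
        occ = OccurrenceSet("sp", [0.0, 0.005], [0.0, 0.005])  # < 1 km apart
        assert len(thin_occurrences(occ, 4.5, seed=0)) == 1

    def test_distant_points_all_kept(self):
        occ = OccurrenceSet("sp", [0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert len(thin_occurrences(occ, 4.5, seed=0)) == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            thin_occurrences(OccurrenceSet("sp", [], []), 4.5)

    def test_matches_brute_force_max_independent_set(self):
        """On small clustered inputs the randomized greedy retains as many
        points as the exhaustive maximum independent set."""
        rng = np.random.default_rng(5)
        for trial in range(5):
            n = 10
            lon = rng.uniform(0, 0.15, n)
            lat = rng.uniform(0, 0.15, n)
            occ = OccurrenceSet("sp", lon, lat)
            d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
            conflict = d < 4.5
            np.fill_diagonal(conflict, False)
            best = 0
            for r in range(n, 0, -1):
                for subset in itertools.combinations(range(n), r):
                    if not any(conflict[i, j] for i, j in itertools.combinations(subset, 2)):
                        best = r
                        break
                if best:
                    break
            thinned = thin_occurrences(occ, 4.5, seed=trial, n_restarts=50)
            assert len(thinned) == best


class TestCrop:
    def test_buffer_expands_bbox(self):
        stack = grid_stack({"a": np.zeros((100, 100))}, cell_deg=0.1)
        occ = OccurrenceSet("sp", [0.45, 0.55], [-0.45, -0.55])
        cropped = crop_with_buffer(stack, occ, buffer_deg=0.2)
        # bbox 0.45-0.55 lon + 0.2 deg buffer, clipped to grid bounds
        assert cropped.lon0 == pytest.approx(0.2, abs=0.1)
        assert cropped.shape[0] < 100

    def test_zero_buffer_is_bbox_crop(self):
        stack = grid_stack({"a": np.zeros((50, 50))}, cell_deg=0.1)
        occ = OccurrenceSet("sp", [1.05, 2.05], [-1.05, -2.05])
        cropped = crop_with_buffer(stack, occ, buffer_deg=0.0)
        assert cropped.shape == (11, 11)

    def test_global_extent_unchanged(self):
        stack = grid_stack({"a": np.zeros((20, 20))}, cell_deg=0.1)
        occ = OccurrenceSet("sp", [0.05, 1.95], [-0.05, -1.95])
        cropped = crop_with_buffer(stack, occ, buffer_deg=10)
        assert cropped.shape == (20, 20)

    def test_disjoint_extent_rejected(self):
        stack = grid_stack({"a": np.zeros((10, 10))}, cell_deg=0.1)
        occ = OccurrenceSet("sp", [50.0], [50.0])
        with pytest.raises(ValueError):
            crop_with_buffer(stack, occ, buffer_deg=1)


class TestRasterPCA:
    def test_perfectly_correlated_layers_one_component(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(20, 20))
        _, pc = raster_pca(grid_stack({"a": base, "b": 2 * base + 1}))
        t, _ = raster_pca(grid_stack({"a": base, "b": 2 * base + 1}))
        assert t.n_components == 1
        assert t.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(1)
        layers = {f"L{i}": rng.normal(size=(30, 30)) for i in range(4)}
        t, _ = raster_pca(grid_stack(layers))
        X = np.column_stack([layers[f"L{i}"].ravel() for i in range(4)])
        Z = (X - X.mean(0)) / X.std(0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(Z.T)))[::-1]
        assert np.allclose(t.explained_variance_ratio, evals / evals.sum(), atol=1e-8)

    def test_constant_layer_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        layers = {"a": rng.normal(size=(10, 10)), "b": rng.normal(size=(10, 10)), "c": np.ones((10, 10))}
        with pytest.warns(UserWarning, match="constant"):
            t, _ = raster_pca(grid_stack(layers))
        assert "c" not in t.layer_names

    def test_scores_reconstruct_standardized_layers(self):
        rng = np.random.default_rng(3)
        layers = {f"L{i}": rng.normal(size=(15, 15)) for i in range(3)}
        t, pc = raster_pca(grid_stack(layers), var_target=0.999999, max_components=3)
        Z = np.column_stack([((layers[n] - layers[n].mean()) / layers[n].std()).ravel() for n in t.layer_names])
        # recenter as the transform does (mean over cells)
        Zc = np.column_stack([(layers[n].ravel() - t.means[i]) / t.sds[i] for i, n in enumerate(t.layer_names)])
        scores = np.column_stack([pc.layers[f"PC{j+1}"].ravel() for j in range(t.n_components)])
        assert np.allclose(scores @ t.components, Zc, atol=1e-8)


class TestMaxent:
    def presence_background(self, seed=0, n_pres=60, n_bg=400, beta=2.5):
        rng = np.random.default_rng(seed)
        bg = rng.normal(size=(n_bg, 2))
        # presences biased toward high values of the first variable
        cand = rng.normal(size=(n_pres * 20, 2))
        w = np.exp(beta * cand[:, 0])
        idx = rng.choice(len(cand), size=n_pres, replace=False, p=w / w.sum())
        return cand[idx], bg

    def test_positive_coefficient_for_preferred_variable(self):
        occ, bg = self.presence_background()
        m = fit_maxent(occ, bg, features="L", multiplier=1.0)
        assert m.coef[0] > 0

    def test_huge_multiplier_shrinks_everything(self):
        occ, bg = self.presence_background()
        m = fit_maxent(occ, bg, features="LQP", multiplier=1e6)
        assert np.allclose(m.coef, 0, atol=1e-8)
        raw = model_raw(m, bg)
        assert np.allclose(raw, raw[0], rtol=1e-8)  # uniform suitability

    def test_matches_independent_l1_logistic_solver(self):
        """Coefficients agree with scikit-learn's saga L1 logistic solver at
        the equivalent penalty."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(7)
        occ = rng.normal(loc=0.8, size=(20, 2))
        bg = rng.normal(size=(200, 2))
        m = fit_maxent(occ, bg, features="L", multiplier=1.0)
        lam = 1.0 * np.sqrt(20)
        F_bg, _ = expand_features(bg, "L")
        mu, sd = F_bg.mean(0), F_bg.std(0)
        Zp = (expand_features(occ, "L")[0] - mu) / sd
        Zb = (F_bg - mu) / sd
        X = np.vstack([Zp, Zb])
        y = np.r_[np.ones(20), np.zeros(200)]
        ref = LogisticRegression(
            l1_ratio=1.0, C=1.0 / lam, solver="saga", tol=1e-12, max_iter=200_000
        ).fit(X, y)
        assert np.allclose(m.coef, ref.coef_[0], atol=1e-4)
        assert m.intercept == pytest.approx(ref.intercept_[0], abs=1e-3)

    def test_feature_expansion_shapes(self):
        X = np.arange(6.0).reshape(3, 2)
        F, names = expand_features(X, "LQP")
        assert F.shape == (3, 5)  # 2 linear + 2 quadratic + 1 product
        assert names == ["x1", "x2", "x1^2", "x2^2", "x1*x2"]
        with pytest.raises(ValueError):
            expand_features(X, "LH")

    def test_predictions_in_unit_interval(self):
        occ, bg = self.presence_background(seed=3)
        m = fit_maxent(occ, bg, features="LQ", multiplier=1.0)
        for output in ("cloglog", "logistic"):
            p = model_predict(m, bg, output=output)
            assert np.all((p >= 0) & (p <= 1))


class TestAUC:
    def test_perfect_separation(self):
        assert auc_presence_background(np.array([5.0, 6.0]), np.array([1.0, 2.0])) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        assert auc_presence_background(a, b) == pytest.approx(0.5, abs=0.05)

    def test_equals_mann_whitney_statistic(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 1, 50), rng.normal(0, 1, 80)
        u = mannwhitneyu(a, b, alternative="two-sided").statistic
        assert auc_presence_background(a, b) == pytest.approx(u / (50 * 80), abs=1e-12)


class TestSelection:
    def test_selection_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        occ = rng.normal(loc=1.2, size=(40, 2))
        bg = rng.normal(size=(300, 2))
        r1 = evaluate_and_select(occ, bg, feature_grid=["L", "LQ"], multipliers=(1.0, 2.0), seed=3)
        r2 = evaluate_and_select(occ, bg, feature_grid=["L", "LQ"], multipliers=(1.0, 2.0), seed=3)
        sel1 = [e for e in r1[0] if e.selected]
        sel2 = [e for e in r2[0] if e.selected]
        assert sel1 and (sel1[0].feature_classes, sel1[0].multiplier) == (
            sel2[0].feature_classes, sel2[0].multiplier)

    def test_no_signal_yields_no_valid_model(self):
        rng = np.random.default_rng(6)
        occ = rng.normal(size=(30, 2))  # presences drawn like background
        bg = rng.normal(size=(300, 2))
        evals, best = evaluate_and_select(occ, bg, feature_grid=["L"], multipliers=(1.0,), seed=0)
        assert best is None
        assert all(not e.selected for e in evals)

    def test_fewer_presences_than_folds_rejected(self):
        with pytest.raises(ValueError):
            evaluate_and_select(np.zeros((2, 2)), np.zeros((10, 2)), k=4)


class TestAreaSeries:
    def build_model_and_stacks(self):
        rng = np.random.default_rng(8)
        base = np.linspace(-2, 2, 40)[None, :] * np.ones((40, 1))
        noise = rng.normal(scale=0.1, size=(40, 40))
        stack = grid_stack({"PC1": base + noise, "PC2": rng.normal(size=(40, 40))})
        occ = np.column_stack([rng.uniform(1, 2, 50), rng.normal(size=50)])
        bg = stack.table()
        m = fit_maxent(occ, bg[np.random.default_rng(0).choice(len(bg), 400, replace=False)], features="L")
        return m, stack

    def test_area_equals_cell_count_times_cell_area(self):
        m, stack = self.build_model_and_stacks()
        df = project_and_area(m, {"present": stack}, threshold=0.36)
        s = suitability_surface(m, stack)
        expect = np.nansum(s >= 0.36) * 4.5**2
        assert df.loc[0, "area_km2"] == pytest.approx(expect)

    def test_area_monotone_in_threshold(self):
        m, stack = self.build_model_and_stacks()
        areas = [
            project_and_area(m, {"present": stack}, threshold=t).loc[0, "area_km2"]
            for t in np.linspace(0.05, 0.95, 10)
        ]
        assert np.all(np.diff(areas) <= 0)

    def test_ice_mask_excludes_cells(self):
        m, stack = self.build_model_and_stacks()
        full = project_and_area(m, {"present": stack})
        mask = np.zeros(stack.shape, dtype=bool)
        mask[:, -10:] = True  # ice over the most suitable margin
        masked = project_and_area(m, {"present": stack}, ice_masks={"present": mask})
        assert masked.loc[0, "area_km2"] < full.loc[0, "area_km2"]

    def test_normalized_by_period_maximum(self):
        m, stack = self.build_model_and_stacks()
        shifted = grid_stack({"PC1": stack.layers["PC1"] - 1.5, "PC2": stack.layers["PC2"]})
        df = project_and_area(m, {"present": stack, "LGM": shifted})
        assert df["normalized"].max() == pytest.approx(1.0)
        assert df.set_index("period").loc["LGM", "area_km2"] < df.set_index("period").loc["present", "area_km2"]


class TestMoransI:
    def test_iid_residuals_near_null_expectation(self):
        rng = np.random.default_rng(0)
        n = 60
        lon = rng.uniform(0, 0.15, n)
        lat = rng.uniform(0, 0.15, n)
        res = morans_i(lon, lat, rng.normal(size=n), n_distance_bins=5, max_distance_km=15, n_permutations=199)
        finite = res.dropna(subset=["I"])
        assert (finite["I"].abs() < 0.35).all()
        assert (finite["p"] > 0.01).any()

    def test_clustered_identical_values_reach_upper_bound(self):
        # two balanced tight clusters with values +1/-1: every within-band
        # pair agrees in sign, so I hits its upper bound of 1
        lon = np.array([0.0, 0.001, 0.002, 0.003, 0.004, 0.5, 0.501, 0.502, 0.503, 0.504])
        lat = np.zeros(10)
        z = np.array([1, 1, 1, 1, 1, -1, -1, -1, -1, -1], dtype=float)
        res = morans_i(lon, lat, z, n_distance_bins=1, max_distance_km=1.0, n_permutations=99)
        assert res.loc[0, "I"] == pytest.approx(1.0)

    def test_empty_band_reported_missing(self):
        rng = np.random.default_rng(1)
        lon = np.concatenate([rng.uniform(0, 0.01, 10), [5.0]])
        lat = np.zeros(11)
        res = morans_i(lon, lat, rng.normal(size=11), n_distance_bins=21, max_distance_km=10)
        assert res["I"].isna().any()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            morans_i(np.zeros(3), np.zeros(3), np.zeros(3))
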