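"""Penalized maximum-entropy core: solver correctness and model behaviour."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from telemax import maxent as mx
from telemax.grid import Grid, LayerMeta, RasterStack
from telemax.synthio import SimConfig, generate_covariate_stack, sample_presence_points, true_intensity


def brute_force_lambda(F_p, F_b, penalties):
    """Maximise the identical penalized objective with L-BFGS-B on the
    positive/negative split (lambda = a - b, a,b >= 0)."""
    m = F_p.shape[1]

    def neg(ab):
        lam = ab[:m] - ab[m:]
        return -mx.penalized_objective(lam, F_p, F_b, penalties)

    best = None
    for x0 in (np.zeros(2 * m), np.full(2 * m, 0.1)):
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(0, None)] * (2 * m),
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:m] - best.x[m:], -best.fun


class TestSolver:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_tiny_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_p, n_b, m = 12, 50, 3
        F_b = rng.random((n_b, m))
        F_p = rng.random((n_p, m)) ** 2  # presence biased low/high per feature
        penalties = np.full(m, 0.02)
        res = mx.fit_penalized(F_p, F_b, penalties, max_cycles=3000, tol=1e-12)
        lam_bf, obj_bf = brute_force_lambda(F_p, F_b, penalties)
        assert res.objective == pytest.approx(obj_bf, abs=1e-6)
        np.testing.assert_allclose(res.lam, lam_bf, atol=1e-3)

    def test_objective_monotone_nondecreasing(self, rng):
        F_b = rng.random((200, 5))
        F_p = rng.random((40, 5)) ** 2
        res = mx.fit_penalized(F_p, F_b, np.full(5, 0.01))
        path = np.array(res.objective_path)
        assert np.all(np.diff(path) >= -1e-12)

    def test_stronger_regularization_shrinks_coefficients(self, rng):
        F_b = rng.random((300, 4))
        F_p = rng.random((60, 4)) ** 2
        base_pen = np.full(4, 0.01)
        l1 = np.abs(mx.fit_penalized(F_p, F_b, base_pen).lam).sum()
        l2 = np.abs(mx.fit_penalized(F_p, F_b, 4 * base_pen).lam).sum()
        assert l2 <= l1 + 1e-9

    def test_null_model_shrinks_to_uniform(self, rng):
        """Presence distributed exactly as the background: all coefficients
        stay at zero and the predicted surface is uniform.  With a sampled
        presence subset, sampling noise keeps the surface near-uniform at
        moderate regularization."""
        n_b = 2000
        X_b = rng.normal(size=(n_b, 3))
        fc = mx.FeatureConfig(product=False, threshold=False, hinge=False)
        model = mx.fit(X_b, X_b, ["a", "b", "c"], set(), reg_multiplier=1.0,
                       feature_config=fc)
        np.testing.assert_allclose(model.lam, 0.0, atol=1e-9)
        rel = model.intensity(X_b)
        assert (rel.max() - rel.min()) / rel.max() < 1e-9
        # sampled null: coefficients bounded by the sampling-noise scale
        X_p = X_b[rng.choice(n_b, 1000, replace=False)]
        noisy = mx.fit(X_p, X_b, ["a", "b", "c"], set(), reg_multiplier=4.0,
                       feature_config=fc)
        rel = noisy.intensity(X_b)
        assert (rel.max() - rel.min()) / rel.max() < 0.5


class TestFeatures:
    def test_feature_scaling_and_knots_deterministic(self, rng):
        X_b = rng.normal(size=(500, 2))
        cfg = mx.FeatureConfig(n_knots=5)
        a = mx.FeatureSet.build(X_b, ["u", "v"], set(), cfg)
        b = mx.FeatureSet.build(X_b, ["u", "v"], set(), cfg)
        assert a.names == b.names
        F = a.transform(X_b)
        assert F.min() >= 0.0 and F.max() <= 1.0 + 1e-12

    def test_categorical_expansion(self, rng):
        X_b = np.column_stack([rng.normal(size=200), rng.integers(0, 3, 200)])
        fs = mx.FeatureSet.build(
            X_b, ["cont", "eco"], {"eco"},
            mx.FeatureConfig(product=False, threshold=False, hinge=False),
        )
        cat_feats = [f for f in fs.features if f.kind == "categorical"]
        assert len(cat_feats) == 3

    def test_out_of_range_projection_clamped(self, rng):
        X_b = rng.uniform(0, 1, size=(300, 1))
        fs = mx.FeatureSet.build(X_b, ["u"], set(),
                                 mx.FeatureConfig(product=False, threshold=False, hinge=False))
        F = fs.transform(np.array([[5.0], [0.5]]))
        assert fs.last_clamped == 1
        assert F[0, 0] <= 1.0 + 1e-12


class TestBackground:
    def _grid(self):
        return Grid(nrows=100, ncols=100, resolution=1000.0, x0=0.0, y0=0.0)

    def test_all_samples_within_buffer(self, rng):
        g = self._grid()
        tx, ty = np.array([50_000.0]), np.array([50_000.0])
        bx, by, mask = mx.sample_background((tx, ty), g, buffer_km=20, n=5000, rng=rng)
        d = np.hypot(bx - 50_000, by - 50_000)
        assert d.max() <= 20_000 * 1.08  # cell-diagonal slack on the rasterised disc
        area_km2 = mask.sum() * g.cell_area_km2
        assert area_km2 == pytest.approx(np.pi * 20.0**2, rel=0.05)

    def test_same_seed_identical(self):
        g = self._grid()
        tx, ty = np.array([50_000.0, 20_000.0]), np.array([50_000.0, 70_000.0])
        a = mx.sample_background((tx, ty), g, n=1000, rng=np.random.default_rng(4))
        b = mx.sample_background((tx, ty), g, n=1000, rng=np.random.default_rng(4))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_uniform_over_modeled_area(self):
        """Chi-square GOF over 100 quadrats at n = 100,000."""
        g = self._grid()
        rng = np.random.default_rng(11)
        tx = rng.uniform(20_000, 80_000, 30)
        ty = rng.uniform(20_000, 80_000, 30)
        bx, by, mask = mx.sample_background((tx, ty), g, buffer_km=20, n=100_000, rng=rng)
        row, col = g.xy_to_rowcol(bx, by)
        q = (row // 10) * 10 + (col // 10)
        counts = np.bincount(q, minlength=100)
        cells_per_quadrat = np.array(
            [mask[10 * (i // 10): 10 * (i // 10) + 10, 10 * (i % 10): 10 * (i % 10) + 10].sum()
             for i in range(100)]
        )
        keep = cells_per_quadrat > 0
        expected = len(bx) * cells_per_quadrat[keep] / cells_per_quadrat[keep].sum()
        p = stats.chisquare(counts[keep], expected).pvalue
        assert p > 0.01

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            mx.sample_background((np.array([]), np.array([])), self._grid())


class TestModel:
    def _recovery_setup(self, seed=7, n=1000):
        cfg = SimConfig(
            nrows=100, ncols=100, resolution=1000.0,
            n_per_category={"climate_weather": 1, "vegetation_landcover": 1,
                            "developed": 1, "topography": 1, "wind_uplift": 1},
            n_ecoregions=0, true_betas={"wind_uplift_1": 1.2}, seed=seed,
        )
        stack = generate_covariate_stack(cfg)
        truth = true_intensity(stack, cfg.true_betas)
        rng = np.random.default_rng(seed + 100)
        px, py = sample_presence_points(truth, n, rng)
        bx, by, _ = mx.sample_background((px, py), stack.grid, n=4000, rng=rng)
        names = stack.names
        return stack, truth, names, stack.sample(names, px, py), stack.sample(names, bx, by)

    def test_parameter_recovery_rank_correlation(self):
        stack, truth, names, X_p, X_b = self._recovery_setup()
        model = mx.fit(X_p, X_b, names, set(), 1.0,
                       mx.FeatureConfig(product=False, threshold=False, hinge=False))
        surf = mx.project(model, stack, names)
        rho = stats.spearmanr(surf.data.ravel(), truth.data.ravel()).statistic
        assert rho > 0.9

    def test_contributions_sum_to_100_and_informative_leads(self):
        stack, truth, names, X_p, X_b = self._recovery_setup()
        model = mx.fit(X_p, X_b, names, set(), 1.0,
                       mx.FeatureConfig(product=False, threshold=False, hinge=False))
        contrib = model.percent_contribution()
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.1)
        assert max(contrib, key=contrib.get) == "wind_uplift_1"

    def test_single_covariate_contribution_is_total(self, rng):
        X_b = rng.normal(size=(500, 1))
        X_p = X_b[rng.choice(500, 100)] + 0.5
        model = mx.fit(X_p, X_b, ["only"], set(), 1.0,
                       mx.FeatureConfig(product=False, threshold=False, hinge=False))
        assert model.percent_contribution()["only"] == pytest.approx(100.0, abs=1e-9)

    def test_projection_scaling_contract(self):
        stack, truth, names, X_p, X_b = self._recovery_setup()
        model = mx.fit(X_p, X_b, names, set(), 1.0,
                       mx.FeatureConfig(product=False, threshold=False, hinge=False))
        surf = mx.project(model, stack, names)
        assert np.nanmax(surf.data) == pytest.approx(1.0)
        assert np.nanmin(surf.data) >= 0.0

    def test_constant_covariates_give_constant_surface(self):
        g = Grid(nrows=20, ncols=20, resolution=1000.0, x0=0.0, y0=0.0)
        stack = RasterStack(g)
        stack.add(np.full((20, 20), 2.0), LayerMeta("c", "c", "topography"))
        rng = np.random.default_rng(0)
        X = np.full((100, 1), 2.0)
        # constant feature is dropped at build; surface defaults to uniform
        model = mx.fit(X + rng.normal(0, 1e-9, X.shape), X, ["c"], set(), 1.0,
                       mx.FeatureConfig(product=False, threshold=False, hinge=False))
        surf = mx.project(model, stack, ["c"])
        assert np.nanmax(surf.data) == np.nanmin(surf.data)


class TestPruneAndTune:
    def test_prune_removes_pure_noise_covariate(self):
        rng = np.random.default_rng(3)
        n_b, n_p = 3000, 600
        X_b = rng.normal(size=(n_b, 2))
        w = np.exp(1.5 * X_b[:, 0])
        X_p = X_b[rng.choice(n_b, n_p, p=w / w.sum())]
        names = ["signal", "noise"]

        def fit_fn(subset):
            idx = [names.index(n) for n in subset]
            return mx.fit(X_p[:, idx], X_b[:, idx], subset, set(), 1.0,
                          mx.FeatureConfig(product=False, threshold=False, hinge=False))

        final, model, rounds = mx.prune_by_contribution(fit_fn, names, min_pct=1.0)
        assert set(final) <= set(names)
        assert "signal" in final

    def test_prune_no_op_when_all_contribute(self):
        rng = np.random.default_rng(5)
        X_b = rng.normal(size=(1000, 2))
        w = np.exp(X_b[:, 0] + X_b[:, 1])
        X_p = X_b[rng.choice(1000, 300, p=w / w.sum())]
        names = ["a", "b"]

        def fit_fn(subset):
            idx = [names.index(n) for n in subset]
            return mx.fit(X_p[:, idx], X_b[:, idx], subset, set(), 1.0,
                          mx.FeatureConfig(product=False, threshold=False, hinge=False))

        final, _, rounds = mx.prune_by_contribution(fit_fn, names)
        assert final == names and rounds == 1

    def test_tune_single_candidate_trivial(self):
        reg, table = mx.tune_regularization(
            (np.arange(10.0), np.arange(10.0)),
            lambda fit_xy, hold_xy, reg: 0.5,
            candidates=(2.0,), k=2,
        )
        assert reg == 2.0 and len(table) == 1

    def test_tune_deterministic_given_seed(self):
        calls = []

        def ev(fit_xy, hold_xy, reg):
            calls.append(len(fit_xy[0]))
            return float(np.sum(hold_xy[0])) % 1.0

        args = ((np.arange(40.0), np.arange(40.0)), ev, (0.5, 1.0), 3)
        r1, t1 = mx.tune_regularization(*args, rng=np.random.default_rng(8))
        r2, t2 = mx.tune_regularization(*args, rng=np.random.default_rng(8))
        assert r1 == r2 and t1 == t2

    def test_tune_ties_go_to_larger_multiplier(self):
        reg, _ = mx.tune_regularization(
            (np.arange(10.0), np.arange(10.0)),
            lambda fit_xy, hold_xy, reg: 1.0,
            candidates=(0.5, 1.0, 4.0), k=1,
        )
        assert reg == 4.0


class TestBetaInterpolation:
    def test_tables_interpolate_and_clamp(self):
        assert mx.class_beta("lqp", 10) == pytest.approx(1.0)
        assert mx.class_beta("lqp", 1000) == pytest.approx(0.05)
        assert mx.class_beta("lqp", 65) == pytest.approx((0.2 + 0.05) / 2)
        assert mx.class_beta("hinge", 500) == pytest.approx(0.5)
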