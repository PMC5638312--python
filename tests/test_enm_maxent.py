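import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import spearmanr

from genoclim.enm_maxent import (
    FeatureExpansion,
    MaxentFit,
    beta_class,
    expand_features,
    fit_maxent,
    kkt_violation,
    maxent_objective,
    predict_raw,
    project,
)
from genoclim.enm_eval import auc_rank
from genoclim.spatial import GridRaster
from genoclim.synthetic_data import (
    LandscapeSimSpec,
    sample_occurrences,
    shift_climate,
    simulate_landscape,
)


def oracle_fit(occ_f, bg_f, beta):
    """Independent convex solver: L-BFGS-B on the split-sign reformulation."""
    n = occ_f.shape[1]
    log_w = np.full(bg_f.shape[0], -np.log(bg_f.shape[0]))

    def obj(x):
        lam = x[:n] - x[n:]
        return maxent_objective(lam, occ_f, bg_f, np.zeros(n), log_w) + beta @ (
            x[:n] + x[n:]
        )

    res = minimize(
        obj, np.zeros(2 * n), method="L-BFGS-B", bounds=[(0, None)] * (2 * n),
        options={"maxiter": 200000, "ftol": 1e-18, "gtol": 1e-14},
    )
    return res.x[:n] - res.x[n:]


class TestFeatureExpansion:
    def setup_method(self):
        self.spec = FeatureExpansion(
            ("L", "Q", "H", "T"), ["x"], np.array([0.0]), np.array([10.0]),
            n_knots=3,
        )

    def test_linear_scaling(self):
        spec = FeatureExpansion(("L",), ["x"], np.array([0.0]), np.array([10.0]))
        f = expand_features(np.array([[5.0]]), spec)
        assert f[0, 0] == pytest.approx(0.5)

    def test_quadratic(self):
        spec = FeatureExpansion(("L", "Q"), ["x"], np.array([0.0]),
                                np.array([10.0]))
        f = expand_features(np.array([[5.0]]), spec)
        assert f[0, 1] == pytest.approx(0.25)

    def test_forward_hinge(self):
        spec = FeatureExpansion(("H",), ["x"], np.array([0.0]), np.array([1.0]),
                                n_knots=1)  # single knot at 0.5
        f = expand_features(np.array([[0.75]]), spec)
        # forward hinge at 0.5: (0.75-0.5)/(1-0.5) = 0.5; reverse hinge 0
        assert f[0, 0] == pytest.approx(0.5)
        assert f[0, 1] == pytest.approx(0.0)

    def test_product_features(self):
        spec = FeatureExpansion(("L", "P"), ["x", "y"], np.zeros(2), np.ones(2))
        f = expand_features(np.array([[0.5, 0.4]]), spec)
        assert f[0, 2] == pytest.approx(0.2)

    def test_clamping(self):
        spec = FeatureExpansion(("L",), ["x"], np.array([0.0]), np.array([1.0]))
        assert expand_features(np.array([[2.0]]), spec, clamp=True)[0, 0] == 1.0
        assert expand_features(np.array([[2.0]]), spec, clamp=False)[0, 0] == 2.0

    def test_constant_covariate_dropped(self):
        spec = FeatureExpansion(("L",), ["x", "flat"], np.array([0.0, 1.0]),
                                np.array([1.0, 1.0]))
        f = expand_features(np.array([[0.3, 1.0]]), spec)
        assert f.shape[1] == 1

    def test_labels_match_columns(self):
        vals = np.random.default_rng(0).random((4, 1)) * 10
        labels = self.spec.feature_labels()
        f = expand_features(vals, self.spec)
        assert len(labels) == f.shape[1]

    def test_beta_schedule_interpolation(self):
        assert beta_class("H", 57) == 0.5
        assert beta_class("L", 10) == 1.0
        assert beta_class("L", 200) == 0.05
        assert beta_class("L", 65) == pytest.approx((0.1 + 0.05) / 2)


class TestFitMaxent:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.bg = rng.random((200, 3))
        self.occ = rng.random((20, 3)) * 0.5 + 0.5
        self.spec = FeatureExpansion.from_training(
            self.bg, ["a", "b", "c"], classes="LQ", n_knots=5
        )
        self.occ_f = expand_features(self.occ, self.spec, clamp=True)
        self.bg_f = expand_features(self.bg, self.spec)

    def test_huge_rm_gives_null_model(self):
        fit = fit_maxent(self.occ_f, self.bg_f, rm=1e6, spec=self.spec)
        assert np.all(fit.weights == 0)
        raw = predict_raw(fit, self.bg_f)
        assert np.allclose(raw, 1.0 / len(self.bg_f))

    def test_kkt_certificate(self):
        for rm in (0.5, 1.0, 3.0):
            fit = fit_maxent(self.occ_f, self.bg_f, rm=rm, spec=self.spec,
                             tol=1e-12, max_iter=50000)
            assert kkt_violation(fit, self.occ_f, self.bg_f) < 1e-5

    def test_convex_oracle_agreement(self):
        fit = fit_maxent(self.occ_f, self.bg_f, rm=1.0, spec=self.spec,
                         tol=1e-14, max_iter=200000)
        lam_o = oracle_fit(self.occ_f, self.bg_f, fit.beta)
        log_w = np.full(self.bg_f.shape[0], -np.log(self.bg_f.shape[0]))
        obj_o = maxent_objective(lam_o, self.occ_f, self.bg_f, fit.beta, log_w)
        assert abs(obj_o - fit.objective) < 1e-5
        # weight space is nearly flat at the optimum; the oracle's own
        # stopping error dominates beyond ~1e-4
        assert np.abs(lam_o - fit.weights).max() < 1e-4

    def test_single_binary_feature_kkt_mean(self):
        rng = np.random.default_rng(2)
        bg_f = (rng.random((300, 1)) < 0.4).astype(float)
        occ_f = np.ones((25, 1))
        fit = fit_maxent(occ_f, bg_f, rm=1.0, feature_classes=["L"],
                         tol=1e-12, max_iter=20000)
        p = predict_raw(fit, bg_f)
        model_mean = float(p @ bg_f[:, 0])
        beta = fit.beta[0]
        assert abs(model_mean - 1.0) <= beta + 1e-6

    def test_raw_sums_to_one_on_training_bg(self):
        fit = fit_maxent(self.occ_f, self.bg_f, rm=1.0, spec=self.spec)
        assert predict_raw(fit, self.bg_f).sum() == pytest.approx(1.0)

    def test_monotone_in_feature(self):
        fit = fit_maxent(self.occ_f, self.bg_f, rm=1.0, spec=self.spec)
        j = int(np.argmax(np.abs(fit.weights)))
        x = self.bg_f.copy()
        base = predict_raw(fit, x)
        x[:, j] = x[:, j] + 0.1
        shifted = predict_raw(fit, x)
        if fit.weights[j] > 0:
            assert (shifted >= base).all()
        else:
            assert (shifted <= base).all()

    def test_validation(self):
        with pytest.raises(ValueError, match="RM"):
            fit_maxent(self.occ_f, self.bg_f, rm=0.0, spec=self.spec)
        with pytest.raises(ValueError, match="non-finite"):
            bad = self.occ_f.copy()
            bad[0, 0] = np.nan
            fit_maxent(bad, self.bg_f, spec=self.spec)

    def test_model_json_roundtrip(self, tmp_path):
        fit = fit_maxent(self.occ_f, self.bg_f, rm=1.0, spec=self.spec)
        p = tmp_path / "model.json"
        fit.to_json(p)
        back = MaxentFit.from_json(p)
        assert np.allclose(back.weights, fit.weights)
        assert back.spec.classes == fit.spec.classes
        assert np.allclose(predict_raw(back, self.bg_f),
                           predict_raw(fit, self.bg_f))


class TestRecoveryProperties:
    def test_linear_coefficient_recovery(self):
        spec = LandscapeSimSpec(
            n_rows=80, n_cols=80, n_covariates=3,
            coefficients=(1.2, -0.8, 0.5), smooth_cells=6, seed=4,
        )
        stack, suit = simulate_landscape(spec)
        occ = sample_occurrences(suit, 500, seed=5)
        names = list(stack)
        occ_cov = np.array([
            [stack[n].values[suit.cell_of(occ.lon[i], occ.lat[i])] for n in names]
            for i in range(len(occ))
        ])
        grid_cov = np.column_stack([stack[n].values.ravel() for n in names])
        rng = np.random.default_rng(6)
        bg_cov = grid_cov[rng.choice(len(grid_cov), 2000, replace=False)]
        fe = FeatureExpansion.from_training(bg_cov, names, classes="L")
        fit = fit_maxent(
            expand_features(occ_cov, fe, clamp=True),
            expand_features(bg_cov, fe),
            rm=0.1, spec=fe,
        )
        est = fit.weights / (fe.maxs - fe.mins)
        true = np.array(spec.coefficients)
        assert np.all(np.abs(est - true) / np.abs(true) < 0.15)

    def test_auc_one_on_separable_data(self):
        rng = np.random.default_rng(1)
        bg = rng.random((300, 1)) * 0.4
        occ = rng.random((40, 1)) * 0.4 + 0.6
        fe = FeatureExpansion.from_training(
            np.vstack([bg, occ]), ["x"], classes="LH", n_knots=20
        )
        occ_f = expand_features(occ, fe, clamp=True)
        bg_f = expand_features(bg, fe)
        fit = fit_maxent(occ_f, bg_f, rm=0.05, spec=fe, max_iter=20000)
        auc = auc_rank(predict_raw(fit, occ_f), predict_raw(fit, bg_f))
        assert auc == pytest.approx(1.0)


class TestProjection:
    def _fitted(self, landscape):
        stack, suit, occ = landscape
        names = list(stack)
        occ_cov = np.array([
            [stack[n].values[suit.cell_of(occ.lon[i], occ.lat[i])] for n in names]
            for i in range(len(occ))
        ])
        grid_cov = np.column_stack([stack[n].values.ravel() for n in names])
        rng = np.random.default_rng(9)
        bg_cov = grid_cov[rng.choice(len(grid_cov), 1000, replace=False)]
        fe = FeatureExpansion.from_training(bg_cov, names, classes="LQ")
        fit = fit_maxent(
            expand_features(occ_cov, fe, clamp=True),
            expand_features(bg_cov, fe), rm=1.0, spec=fe,
        )
        return fit, stack, suit

    def test_projection_matches_training_prediction(self, landscape):
        fit, stack, suit = self._fitted(landscape)
        proj = project(fit, stack, clamp=True)
        grid_cov = np.column_stack(
            [stack[n].values.ravel() for n in fit.spec.covariates]
        )
        raw = predict_raw(fit, expand_features(grid_cov, fit.spec, clamp=True))
        assert np.allclose(proj.values.ravel(), raw / raw.sum())

    def test_projection_correlates_with_truth(self, landscape):
        fit, stack, suit = self._fitted(landscape)
        proj = project(fit, stack, clamp=True)
        rho = spearmanr(proj.values.ravel(), suit.values.ravel()).statistic
        assert rho > 0.8

    def test_clamped_beyond_training_max(self, landscape):
        fit, stack, _ = self._fitted(landscape)
        shifted = shift_climate(stack, offsets={n: 100.0 for n in stack})
        proj = project(fit, shifted, clamp=True)
        # every covariate clamps to 1 -> constant prediction map
        vals = proj.values[proj.valid]
        assert np.allclose(vals, vals[0])

    def test_missing_layer_rejected(self, landscape):
        fit, stack, _ = self._fitted(landscape)
        partial = dict(list(stack.items())[:-1])
        with pytest.raises(ValueError, match="missing covariate"):
            project(fit, partial)
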