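import numpy as np
import pytest
from scipy import stats

import panelfa as pf
from panelfa.pca import fit_pca, standardize


def _fitted_model(n=12, m=6, seed=0, max_components=3):
    rng = np.random.default_rng(seed)
    X = rng.lognormal(sigma=0.7, size=(n, m))
    Z, means, sds, kept, dropped = standardize(
        X, markers=[f"mk{j}" for j in range(m)])
    model = fit_pca(Z, max_components, markers=kept, means=means, sds=sds)
    return X, model


class TestExtractRoiFa:
    def test_constant_volume_and_two_voxel_mean(self):
        data = np.full((3, 4, 4, 2), 0.4)
        stack = pf.VolumeStack(data, np.ones((4, 4, 2), bool))
        roi = np.zeros((4, 4, 2), bool)
        roi[0, 0, 0] = True
        assert np.allclose(pf.extract_roi_fa(stack, roi), 0.4)
        data2 = data.copy()
        data2[:, 1, 1, 1] = 0.2
        data2[:, 2, 2, 1] = 0.6
        roi2 = np.zeros((4, 4, 2), bool)
        roi2[1, 1, 1] = roi2[2, 2, 1] = True
        stack2 = pf.VolumeStack(data2, np.ones((4, 4, 2), bool))
        assert np.allclose(pf.extract_roi_fa(stack2, roi2), 0.4)

    def test_matches_explicit_loop(self, patient_stack):
        vols, model, design = patient_stack
        rng = np.random.default_rng(1)
        roi = rng.random(vols.mask.shape) < 0.2
        got = pf.extract_roi_fa(vols, roi)
        coords = np.argwhere(roi)
        for i in range(vols.n_subjects):
            acc = sum(vols.data[i, x, y, z] for x, y, z in coords)
            assert got[i] == pytest.approx(acc / len(coords), rel=1e-12)

    def test_empty_roi_rejected(self):
        stack = pf.VolumeStack(np.zeros((2, 3, 3, 3)), np.ones((3, 3, 3), bool))
        with pytest.raises(ValueError, match="empty"):
            pf.extract_roi_fa(stack, np.zeros((3, 3, 3), bool))


class TestPcrFit:
    def test_anova_bookkeeping_on_random_problems(self):
        for seed in range(8):
            X, model = _fitted_model(seed=seed)
            rng = np.random.default_rng(100 + seed)
            y = 0.4 + 0.05 * model.scores @ rng.normal(size=3) \
                + 0.02 * rng.normal(size=X.shape[0])
            res = pf.pcr_fit(y, model)
            a = res.anova
            assert a["ss_total"] == pytest.approx(
                a["ss_regression"] + a["ss_residual"], rel=1e-8)
            assert res.df_num + res.df_den == X.shape[0] - 1
            assert a["F"] == pytest.approx(
                a["ms_regression"] / a["ms_residual"], rel=1e-10)
            assert res.adjusted_r_squared <= res.r_squared

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        X, model = _fitted_model(seed=3)
        rng = np.random.default_rng(42)
        y = 0.5 + model.scores @ np.array([0.04, -0.02, 0.01]) \
            + 0.01 * rng.normal(size=X.shape[0])
        res = pf.pcr_fit(y, model)
        ref = sm.OLS(y, sm.add_constant(model.scores)).fit()
        assert res.r_squared == pytest.approx(ref.rsquared, rel=1e-10)
        assert res.adjusted_r_squared == pytest.approx(ref.rsquared_adj,
                                                       rel=1e-10)
        assert res.anova["F"] == pytest.approx(ref.fvalue, rel=1e-10)
        assert res.anova["p"] == pytest.approx(ref.f_pvalue, rel=1e-8)
        assert np.allclose(res.gamma, ref.params[1:], rtol=1e-10)
        assert np.allclose(np.sqrt(np.diag(res.gamma_cov)),
                           ref.bse[1:], rtol=1e-8)

    def test_back_projection_consistency(self):
        """Predicting from PC scores and from concentrations of the
        retained markers must agree subject by subject."""
        X, model = _fitted_model(seed=5)
        rng = np.random.default_rng(7)
        y = 0.45 + model.scores @ np.array([0.03, 0.02, -0.01]) \
            + 0.005 * rng.normal(size=X.shape[0])
        res = pf.pcr_fit(y, model)
        from_scores = res.predict_from_scores(model.scores)
        from_conc = res.predict_from_concentrations(X)
        assert np.allclose(from_scores, from_conc, atol=1e-10)

    def test_f_to_r2_inverts_fit(self):
        X, model = _fitted_model(seed=9)
        rng = np.random.default_rng(11)
        y = 0.4 + 0.02 * model.scores[:, 0] + 0.01 * rng.normal(size=X.shape[0])
        res = pf.pcr_fit(y, model)
        back = pf.f_to_r2(res.anova["F"], res.df_num, res.df_den)
        assert back["r_squared"] == pytest.approx(res.r_squared, abs=1e-10)
        assert back["adjusted_r_squared"] == pytest.approx(
            res.adjusted_r_squared, abs=1e-10)
        assert back["p"] == pytest.approx(res.anova["p"], rel=1e-10)

    def test_single_marker_single_component_closed_form(self):
        rng = np.random.default_rng(13)
        x = rng.lognormal(size=(10, 1))
        Z, means, sds, kept, _ = standardize(x, markers=["only"])
        model = fit_pca(Z, 1, markers=kept, means=means, sds=sds)
        y = 0.3 + 0.04 * x[:, 0] + 0.01 * rng.normal(size=10)
        res = pf.pcr_fit(y, model)
        slope_std = np.polyfit(Z[:, 0], y, 1)[0]
        assert res.coefficients["beta"].iloc[0] == pytest.approx(
            slope_std / sds[0], rel=1e-10)

    def test_perfect_fit_flagged_degenerate(self):
        X, model = _fitted_model(n=5, m=4, seed=2)
        y = 0.4 + model.scores @ np.array([0.1, 0.05, -0.02])
        res = pf.pcr_fit(y, model)
        assert res.degenerate and res.r_squared == pytest.approx(1.0)

    def test_constant_outcome_rejected(self):
        X, model = _fitted_model(seed=1)
        with pytest.raises(ValueError, match="constant"):
            pf.pcr_fit(np.full(X.shape[0], 0.5), model)

    def test_recovers_loading_signs_on_synthetic_truth(self, human_recovery,
                                                       patient_stack):
        cfg, truth = human_recovery
        vols, model, design = patient_stack
        y = pf.extract_roi_fa(vols, truth.effect_voxels())
        res = pf.pcr_fit(y, model)
        signs = np.sign(res.coefficients["beta"].to_numpy())
        assert (signs == np.sign(truth.marker_loadings)).all()


class TestFToR2:
    def test_null_limit(self):
        out = pf.f_to_r2(0.0, 3, 11)
        assert out["r_squared"] == 0.0
        assert out["adjusted_r_squared"] == pytest.approx(-3 / 11)
        assert out["p"] == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pf.f_to_r2(-1.0, 3, 4)


class TestShapiroWilk:
    def test_minimal_symmetric_sample(self):
        out = pf.shapiro_wilk([-1.0, 0.0, 1.0])
        assert 0.0 < out["W"] <= 1.0

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pf.shapiro_wilk([1.0, 1.0, 1.0, 1.0])

    def test_size_bounds(self):
        with pytest.raises(ValueError):
            pf.shapiro_wilk([0.0, 1.0])

    def test_power_against_heavy_tails(self):
        rng = np.random.default_rng(3)
        rejections = sum(pf.shapiro_wilk(rng.standard_t(1, size=50))["p"] < 0.05
                        for _ in range(300))
        assert rejections / 300 > 0.5
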