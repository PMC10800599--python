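import numpy as np
import pytest
from scipy import stats

import panelfa as pf
from panelfa.voxelwise import STAT_CAP, TFCEParams, _GlmEngine

from _reference import perm_test_single_voxel, tfce_reference


def _stack(data, mask=None, voxel=1.0):
    data = np.asarray(data, float)
    mask = np.ones(data.shape[1:], bool) if mask is None else mask
    aff = np.diag([voxel, voxel, voxel, 1.0])
    return pf.VolumeStack(data=data, mask=mask, affine=aff)


class TestDesign:
    def test_rank_deficient_design_rejected(self):
        s = np.ones((6, 2))
        with pytest.raises(ValueError, match="rank"):
            pf.Design.from_scores(s)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="n > K"):
            pf.Design.from_scores(np.random.default_rng(0).normal(size=(4, 3)))


class TestFitGlm:
    def test_perfect_fit_is_capped_not_infinite(self):
        rng = np.random.default_rng(0)
        score = rng.normal(size=6)
        data = (2.0 * score)[:, None, None, None] * np.ones((6, 1, 1, 1))
        t_maps, f_map = pf.fit_glm(_stack(data), pf.Design.from_scores(score))
        assert t_maps["PC1"][0, 0, 0] == STAT_CAP
        assert f_map[0, 0, 0] == STAT_CAP

    def test_zero_variance_voxels_report_zero(self):
        score = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        data = np.full((6, 2, 1, 1), 0.5)
        t_maps, f_map = pf.fit_glm(_stack(data), pf.Design.from_scores(score))
        assert (t_maps["PC1"] == 0).all() and (f_map == 0).all()

    def test_null_t_and_f_follow_reference_distributions(self):
        """With fixed X and independent normal outcomes, voxelwise t and F
        statistics follow Student t(n-K-1) and F(K, n-K-1)."""
        rng = np.random.default_rng(12)
        n, k, v = 20, 3, 10_000
        scores = rng.normal(size=(n, k))
        data = rng.normal(size=(n, 25, 20, 20))
        t_maps, f_map = pf.fit_glm(_stack(data), pf.Design.from_scores(scores))
        tvals = t_maps["PC1"].ravel()
        assert stats.kstest(tvals, "t", args=(n - k - 1,)).pvalue > 0.01
        fvals = f_map.ravel()
        assert stats.kstest(fvals, "f", args=(k, n - k - 1)).pvalue > 0.01


class TestTfce:
    def test_all_zero_map_stays_zero(self):
        assert (pf.tfce_enhance(np.zeros((4, 4, 4))) == 0).all()

    def test_negative_input_rejected(self):
        bad = np.zeros((3, 3, 3))
        bad[1, 1, 1] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            pf.tfce_enhance(bad)

    @pytest.mark.parametrize("mode", ["tfce", "cluster_mass"])
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_literal_relabelling_reference(self, mode, connectivity):
        rng = np.random.default_rng(17)
        mask = np.ones((10, 10, 6), bool)
        mask[0, :2, :] = False
        params = TFCEParams(mode=mode, connectivity=connectivity)
        for _ in range(5):
            m = np.clip(rng.standard_normal((10, 10, 6)), 0, None) * mask
            got = pf.tfce_enhance(m, params, mask=mask, voxel_volume=0.5)
            ref = tfce_reference(m, mask, connectivity=connectivity,
                                 voxel_volume=0.5, mass=(mode == "cluster_mass"))
            assert np.allclose(got, ref, rtol=1e-10, atol=1e-12)

    def test_mass_mode_single_peak_closed_form(self):
        h0, steps = 2.4, 50
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = h0
        got = pf.tfce_enhance(m, TFCEParams(mode="cluster_mass",
                                            n_steps=steps))
        hs = h0 * np.arange(1, steps + 1) / steps
        expected = np.sum((h0 - hs) ** 0.5 * hs ** 2 * (h0 / steps))
        assert got[2, 2, 2] == pytest.approx(expected, rel=1e-12)


class TestPermutationFwe:
    def test_corrected_p_monotone_in_enhanced_statistic(self, patient_stack):
        vols, model, design = patient_stack
        res = pf.permutation_fwe(vols, design, n_perm_requested=200, seed=3)
        enh = res.enhanced_maps["f"][vols.mask]
        p = res.corrp_maps["f"][vols.mask]
        order = np.argsort(enh)
        assert (np.diff(p[order]) <= 1e-12).all()
        assert p.min() >= 1.0 / res.n_perm - 1e-12

    def test_voxels_outside_mask_never_appear(self, patient_stack):
        vols, model, design = patient_stack
        mask = vols.mask.copy()
        mask[:, :8, :] = False
        vols2 = pf.VolumeStack(vols.data, mask, vols.affine)
        res = pf.permutation_fwe(vols2, design, n_perm_requested=150, seed=2)
        outside = ~mask
        assert (res.stat_maps["f"][outside] == 0).all()
        assert (res.corrp_maps["f"][outside] == 1.0).all()
        assert not res.sig_mask[outside].any()

    def test_exhaustive_mode_on_tiny_sample(self):
        rng = np.random.default_rng(21)
        score = rng.normal(size=5)
        y = 0.8 * score + 0.1 * rng.normal(size=5)
        data = y[:, None, None, None] * np.ones((5, 1, 1, 1))
        res = pf.permutation_fwe(_stack(data), pf.Design.from_scores(score),
                                 n_perm_requested=500, contrast="t", seed=0)
        assert res.exhaustive and res.n_perm == 120
        p_ref = perm_test_single_voxel(y, score)
        assert res.corrp_maps["PC1"][0, 0, 0] == pytest.approx(p_ref)

    def test_exhaustive_and_monte_carlo_agree(self):
        rng = np.random.default_rng(30)
        score = rng.normal(size=6)
        data = (0.7 * score)[:, None, None, None] + \
            0.4 * rng.normal(size=(6, 3, 3, 2))
        stack = _stack(data)
        design = pf.Design.from_scores(score)
        ex = pf.permutation_fwe(stack, design, n_perm_requested=720,
                                contrast="t", seed=0)
        mc = pf.permutation_fwe(stack, design, n_perm_requested=600,
                                contrast="t", seed=4)
        assert ex.exhaustive and not mc.exhaustive
        pe = ex.corrp_maps["PC1"][stack.mask]
        pm = mc.corrp_maps["PC1"][stack.mask]
        # Monte-Carlo standard error at 600 draws
        tol = 3 * np.sqrt(pe * (1 - pe) / 600) + 0.02
        assert (np.abs(pe - pm) <= tol).all()

    def test_empty_mask_rejected(self):
        data = np.random.default_rng(0).normal(size=(6, 2, 2, 2))
        stack = pf.VolumeStack(data, np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError, match="mask"):
            pf.permutation_fwe(stack, pf.Design.from_scores(
                np.arange(6.0)), n_perm_requested=100)

    def test_few_permutations_warn(self, patient_stack):
        vols, model, design = patient_stack
        with pytest.warns(UserWarning, match="granularity"):
            pf.permutation_fwe(vols, design, n_perm_requested=99, seed=0)


class TestExtractRois:
    def test_two_disjoint_blobs_labelled_by_size(self):
        sig = np.zeros((10, 10, 4), bool)
        sig[1:3, 1:3, 1] = True          # 4 voxels
        sig[6:9, 6:8, 2] = True          # 6 voxels -> label 1
        labels = pf.extract_rois(sig)
        assert labels.max() == 2
        assert (labels == 1).sum() == 6 and (labels == 2).sum() == 4

    def test_two_planted_clusters_recovered_with_high_dice(self):
        beta = np.zeros((16, 16, 8))
        blocks = [(slice(2, 6), slice(4, 8), slice(2, 6)),
                  (slice(10, 14), slice(8, 12), slice(2, 6))]
        for b in blocks:
            beta[b] = 0.12
        cfg = pf.human_config(seed=6, grid_shape=(16, 16, 8),
                              latent_effect_map=beta, noise_sd_fa=0.004,
                              noise_sd_panel=0.15, marker_loadings=0.3,
                              outlier_rate=0.0)
        truth = pf.generate_dataset(cfg)
        tbl = truth.panel.select(group="B")
        model = pf.fit(tbl, max_components=3)
        idx = np.arange(cfg.n_group_a, cfg.n_subjects)
        vols = pf.VolumeStack(truth.volumes[idx], truth.brain_mask,
                              cfg.affine)
        res = pf.permutation_fwe(vols, pf.Design.from_scores(
            pf.transform(model, tbl)), n_perm_requested=500, seed=2)
        labels = pf.extract_rois(res.sig_mask)
        assert labels.max() == 2
        for b in blocks:
            planted = np.zeros_like(beta, dtype=bool)
            planted[b] = True
            # the ROI overlapping this block must match it well
            lab = np.bincount(labels[planted].ravel()).argmax()
            assert lab >= 1
            roi = labels == lab
            dice = 2 * (roi & planted).sum() / (roi.sum() + planted.sum())
            assert dice >= 0.8

    def test_single_blob_and_empty_mask(self):
        sig = np.zeros((5, 5, 5), bool)
        assert pf.extract_rois(sig).max() == 0
        sig[2, 2, 2:4] = True
        labels = pf.extract_rois(sig)
        assert labels.max() == 1 and (labels == 1).sum() == 2
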