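"""Ventricular morphometry: the anterior/posterior split, parcellation,
feature computation and automated QC."""

import math

import numpy as np
import pytest
from scipy import stats

from oracles import bruteforce_anterior_split

import ventra.synthetic as syn
from ventra.features import (LobarAtlas, QCThresholds,
                             UndefinedFeatureError, compute_apr,
                             compute_features, parcellate_volumes,
                             qc_segmentation, split_anterior_posterior)
from ventra.io_model import GeometryError, LabelVolume


def _aff_centred(shape):
    a = np.eye(4)
    a[:3, 3] = -(np.array(shape) - 1) / 2
    return a


class TestAnteriorPosteriorSplit:
    def test_all_anterior_mask_has_empty_posterior(self):
        shape = (16, 16, 16)
        aff = _aff_centred(shape)
        m = np.zeros(shape, dtype=np.int32)
        m[:, 10:, :] = 1  # world y in [2.5, 7.5] > -12 everywhere
        ant, post = split_anterior_posterior(LabelVolume(m, aff))
        assert post.data.sum() == 0
        assert ant.data.sum() == m.sum()

    def test_symmetric_mask_splits_evenly(self):
        # grid centred so that world y = -12 falls between voxel rows
        shape = (8, 8, 8)
        aff = np.eye(4)
        aff[1, 3] = -12.0 - 3.5  # rows at y = -15.5 .. -8.5
        m = np.ones(shape, dtype=np.int32)
        ant, post = split_anterior_posterior(LabelVolume(m, aff))
        assert ant.data.sum() == post.data.sum() == m.sum() // 2

    def test_matches_per_voxel_oracle_on_random_mask(self):
        rng = np.random.default_rng(0)
        shape = (32, 32, 32)
        aff = _aff_centred(shape)
        m = (rng.random(shape) < 0.3).astype(np.int32)
        ant, post = split_anterior_posterior(LabelVolume(m, aff))
        n_ant, n_post = bruteforce_anterior_split(m, aff)
        assert ant.data.sum() == n_ant
        assert post.data.sum() == n_post

    def test_partition_properties(self):
        rng = np.random.default_rng(1)
        shape = (20, 20, 20)
        aff = _aff_centred(shape)
        m = (rng.random(shape) < 0.4).astype(np.int32)
        ant, post = split_anterior_posterior(LabelVolume(m, aff))
        assert not np.any((ant.data == 1) & (post.data == 1))
        np.testing.assert_array_equal(ant.data | post.data, m)


class TestAPR:
    def test_arithmetic(self):
        apr, apr_log = compute_apr(300.0, 200.0)
        assert apr == pytest.approx(1.5)
        assert apr_log == pytest.approx(0.4055, abs=1e-4)

    def test_equal_volumes_give_zero_log(self):
        apr, apr_log = compute_apr(250.0, 250.0)
        assert apr == 1.0 and apr_log == 0.0

    def test_zero_posterior_rejected(self):
        with pytest.raises(UndefinedFeatureError):
            compute_apr(100.0, 0.0)

    def test_antisymmetric_under_swap(self):
        _, fwd = compute_apr(320.0, 180.0)
        _, rev = compute_apr(180.0, 320.0)
        assert fwd == pytest.approx(-rev)

    def test_population_contrast_detectable(self):
        """Groups generated at the observed false-positive vs true-
        negative APR separation (means 1.26 vs 0.97, sd 0.3) must show a
        significant difference at n = 60 per group."""
        rng = np.random.default_rng(0)
        a = rng.normal(1.26, 0.3, 60)
        b = rng.normal(0.97, 0.3, 60)
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert p < 0.05


class TestParcellation:
    def test_mask_confined_to_one_compartment(self, template_art):
        atlas = template_art.atlas
        code = atlas.code_for("frontal", "L")
        m = (atlas.labels.data == code).astype(np.int32)
        # keep a subcube to stay strictly inside the compartment
        vol = parcellate_volumes(LabelVolume(m, atlas.labels.affine), atlas)
        assert vol[("frontal", "L")] == pytest.approx(m.sum())
        assert sum(v for k, v in vol.items()
                   if k != ("frontal", "L")) == 0.0

    def test_mirror_swaps_hemispheres(self, template_art):
        atlas = template_art.atlas
        m = template_art.ventricle_prior.data.copy()
        # make it asymmetric, avoiding the x = 0 plane
        half = m.shape[0] // 2
        m[:half - 2] = 0
        lv = LabelVolume(m, atlas.labels.affine)
        vol = parcellate_volumes(lv, atlas)
        mirrored = LabelVolume(m[::-1].copy(), atlas.labels.affine)
        vol_m = parcellate_volumes(mirrored, atlas)
        for lobe in ("frontal", "parietal", "temporal", "occipital"):
            assert vol[(lobe, "R")] == pytest.approx(vol_m[(lobe, "L")])
            assert vol[(lobe, "L")] == pytest.approx(vol_m[(lobe, "R")])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_compartments_sum_to_total(self, template_art, seed):
        rng = np.random.default_rng(seed)
        shape = template_art.icv_mask.shape
        m = ((rng.random(shape) < 0.05)
             & (template_art.icv_mask.data == 1)).astype(np.int32)
        lv = LabelVolume(m, template_art.icv_mask.affine)
        vol = parcellate_volumes(lv, template_art.atlas)
        assert sum(vol.values()) == pytest.approx(float(m.sum()))

    def test_out_of_atlas_voxels_reassigned_to_nearest(self, template_art):
        atlas = template_art.atlas
        m = np.zeros(atlas.labels.shape, dtype=np.int32)
        outside = np.argwhere(atlas.labels.data == 0)[0]
        m[tuple(outside)] = 1
        vol = parcellate_volumes(LabelVolume(m, atlas.labels.affine), atlas)
        assert sum(vol.values()) == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self, template_art):
        m = np.zeros((10, 10, 10), dtype=np.int32)
        with pytest.raises(GeometryError):
            parcellate_volumes(LabelVolume(m, np.eye(4)),
                               template_art.atlas)


class TestComputeFeatures:
    def test_symmetric_phantom_has_zero_log_ratios(self, template_art):
        f = compute_features(template_art.ventricle_prior,
                             template_art.atlas,
                             icv=template_art.icv_volume_mm3)
        assert f.lr_frontal_log == pytest.approx(0.0, abs=1e-12)
        assert f.lr_temporal_log == pytest.approx(0.0, abs=1e-12)
        assert abs(f.apr_log) < 0.05

    def test_normalised_volume_arithmetic(self, template_art):
        f = compute_features(template_art.ventricle_prior,
                             template_art.atlas,
                             icv=template_art.icv_volume_mm3)
        assert f.total_vv_norm == pytest.approx(f.total_vol / f.icv)
        assert f.anterior_vol + f.posterior_vol == pytest.approx(f.total_vol)
        assert sum(f.vol.values()) == pytest.approx(f.total_vol)

    def test_lr_ratio_tracks_generator_asymmetry(self, template_art):
        spec = syn.PhantomSpec(lr_frontal_factor=1.25,
                               lr_temporal_factor=0.8)
        mask = LabelVolume(syn.ventricle_mask_array(spec).astype(np.int32),
                           syn.template_affine(spec))
        f = compute_features(mask, template_art.atlas,
                             icv=template_art.icv_volume_mm3)
        assert f.lr_frontal_log > 0.05
        # the temporal compartment also contains ventricle-body voxels,
        # so the horn asymmetry is diluted: check the direction
        assert f.lr_temporal_log < -0.02

    def test_empty_mask_rejected(self, template_art):
        empty = LabelVolume(
            np.zeros(template_art.icv_mask.shape, dtype=np.int32),
            template_art.icv_mask.affine)
        with pytest.raises(UndefinedFeatureError):
            compute_features(empty, template_art.atlas, icv=1.0e6)


class TestQC:
    def test_perfect_segmentation_passes(self, template_art):
        qc = qc_segmentation(template_art.ventricle_prior,
                             template_art.ventricle_prior,
                             atlas=template_art.atlas)
        assert qc.passed
        assert qc.overlap_with_prior == pytest.approx(1.0)

    def test_empty_mask_fails_overlap_and_volume(self, template_art):
        empty = LabelVolume(
            np.zeros(template_art.icv_mask.shape, dtype=np.int32),
            template_art.icv_mask.affine)
        qc = qc_segmentation(empty, template_art.ventricle_prior,
                             atlas=template_art.atlas)
        assert not qc.passed
        assert "low_overlap" in qc.reasons
        assert "volume_out_of_range" in qc.reasons

    def test_large_shift_fails_overlap(self, template_art):
        prior = template_art.ventricle_prior
        shifted = np.roll(prior.data, 40, axis=1)
        qc = qc_segmentation(LabelVolume(shifted, prior.affine), prior,
                             atlas=template_art.atlas)
        assert "low_overlap" in qc.reasons

    def test_fragmentation_detected(self, template_art):
        shape = template_art.icv_mask.shape
        m = np.zeros(shape, dtype=np.int32)
        # five separated blobs of >= 50 voxels each near the prior
        for i, off in enumerate(range(10, 60, 10)):
            m[off:off + 4, 40:44, 40:44] = 1
        lv = LabelVolume(m, template_art.icv_mask.affine)
        qc = qc_segmentation(lv, template_art.ventricle_prior,
                             QCThresholds(min_prior_dice=0.0,
                                          volume_range_mm3=(0.0, 1e9)),
                             atlas=template_art.atlas)
        assert "fragmented" in qc.reasons

    def test_status_fail_iff_reasons(self, template_art):
        for mask in (template_art.ventricle_prior,
                     LabelVolume(np.zeros(template_art.icv_mask.shape,
                                          dtype=np.int32),
                                 template_art.icv_mask.affine)):
            qc = qc_segmentation(mask, template_art.ventricle_prior,
                                 atlas=template_art.atlas)
            assert (qc.status == "fail") == bool(qc.reasons)
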