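"""Patch-based label fusion: oracle equivalence, invariants, library."""

import numpy as np
import pytest
from scipy import ndimage

from oracles import bruteforce_label_fusion

from ventra.io_model import GeometryError, LabelVolume, VolumeImage
from ventra.label_fusion import (ConfigurationError, FusionParams,
                                 build_library, segment_ventricles,
                                 segmentation_volume)

AFF = np.eye(4)


def _pair(rng, shape, mask):
    img = rng.normal(60, 8, shape).astype(np.float32)
    img[mask == 1] = rng.normal(12, 3, int((mask == 1).sum()))
    return VolumeImage(img, AFF), LabelVolume(mask, AFF)


def _toy_library(rng, shape=(9, 9, 9), n=2):
    pairs = []
    for e in range(n):
        m = np.zeros(shape, dtype=np.int32)
        m[2 + e:6 + e, 3:7, 2:6] = 1
        pairs.append(_pair(rng, shape, m))
    return pairs


class TestBuildLibrary:
    def test_candidate_mask_is_dilated_union(self):
        rng = np.random.default_rng(0)
        pairs = _toy_library(rng)
        lib = build_library(pairs, d=1)
        union = (pairs[0][1].data | pairs[1][1].data).astype(bool)
        expected = ndimage.binary_dilation(
            union, structure=ndimage.generate_binary_structure(3, 1))
        # ball of radius 1 is the 6-connected structure
        np.testing.assert_array_equal(lib.candidate_mask.data,
                                      expected.astype(np.int32))

    def test_no_dilation_keeps_exact_union(self):
        rng = np.random.default_rng(1)
        pairs = _toy_library(rng)
        lib = build_library(pairs, d=0)
        union = (pairs[0][1].data | pairs[1][1].data).astype(np.int32)
        np.testing.assert_array_equal(lib.candidate_mask.data, union)

    def test_disjoint_labels_both_covered(self):
        rng = np.random.default_rng(2)
        m1 = np.zeros((12, 12, 12), dtype=np.int32)
        m1[1:3, 1:3, 1:3] = 1
        m2 = np.zeros((12, 12, 12), dtype=np.int32)
        m2[8:10, 8:10, 8:10] = 1
        pairs = [_pair(rng, (12, 12, 12), m1), _pair(rng, (12, 12, 12), m2)]
        lib = build_library(pairs, d=2)
        assert (lib.candidate_mask.data[m1 == 1] == 1).all()
        assert (lib.candidate_mask.data[m2 == 1] == 1).all()

    def test_grid_mismatch_reported(self):
        rng = np.random.default_rng(3)
        a = _pair(rng, (9, 9, 9), np.zeros((9, 9, 9), dtype=np.int32))
        b = _pair(rng, (10, 10, 10), np.zeros((10, 10, 10), dtype=np.int32))
        with pytest.raises(GeometryError, match="entry 1"):
            build_library([a, b], d=1)

    def test_single_entry_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ConfigurationError):
            build_library(_toy_library(rng, n=2)[:1], d=1)


class TestSegmentation:
    @pytest.mark.parametrize("seed,shape,sr", [(0, (9, 9, 9), 2),
                                               (1, (8, 10, 9), 1),
                                               (2, (10, 10, 10), 2)])
    def test_matches_bruteforce_oracle(self, seed, shape, sr):
        """Voxel-for-voxel equality with an independent triple-loop
        implementation on small instances."""
        rng = np.random.default_rng(seed)
        pairs = []
        for e in range(3):
            m = np.zeros(shape, dtype=np.int32)
            m[2:shape[0] - 2 - e, 3:shape[1] - 2, 2:shape[2] - 3] = 1
            pairs.append(_pair(rng, shape, m))
        params = FusionParams(patch_radius=1, search_radius=sr, dilation=1)
        lib = build_library(pairs, d=1)
        tmask = np.zeros(shape, dtype=np.int32)
        tmask[3:shape[0] - 3, 2:shape[1] - 3, 3:shape[2] - 2] = 1
        target, _ = _pair(rng, shape, tmask)
        seg, conf = segment_ventricles(target, lib, params)
        olab, ovotes = bruteforce_label_fusion(
            target.data, [(im.data, lb.data) for im, lb in pairs],
            lib.candidate_mask.data, params.patch_radius,
            params.search_radius, params.preselection_threshold,
            params.bandwidth_floor, params.decision_threshold)
        np.testing.assert_array_equal(seg.data, olab)
        np.testing.assert_allclose(conf, ovotes, atol=1e-5)

    def test_constant_positive_labels_fill_candidate_mask(self):
        rng = np.random.default_rng(5)
        shape = (10, 10, 10)
        m = np.ones(shape, dtype=np.int32)
        pairs = [_pair(rng, shape, m.copy()) for _ in range(2)]
        lib = build_library(pairs, d=0)
        target, _ = _pair(rng, shape, m)
        seg, conf = segment_ventricles(
            target, lib, FusionParams(search_radius=1))
        np.testing.assert_array_equal(seg.data, lib.candidate_mask.data)
        assert conf[lib.candidate_mask.data == 1].min() == pytest.approx(1.0)

    def test_best_matching_entry_dominates(self):
        """With one clean library match and heavily corrupted others, the
        adaptive bandwidth must recover the matching entry's label."""
        rng = np.random.default_rng(6)
        shape = (32, 32, 32)
        masks = []
        for e in range(3):
            g = np.indices(shape) - 15.5
            m = ((g[0] / (6 + e)) ** 2 + (g[1] / (8 - e)) ** 2
                 + (g[2] / 6) ** 2 <= 1).astype(np.int32)
            masks.append(m)
        pairs = [_pair(rng, shape, m) for m in masks]
        target = VolumeImage(pairs[0][0].data.copy(), AFF)
        corrupted = []
        for i, (im, lb) in enumerate(pairs):
            if i == 0:
                corrupted.append((im, lb))
            else:
                noisy = im.data + rng.normal(0, 40, shape).astype(np.float32)
                corrupted.append((VolumeImage(noisy, AFF), lb))
        lib = build_library(corrupted, d=2)
        seg, _ = segment_ventricles(target, lib, FusionParams(search_radius=2))
        a = seg.data == 1
        b = masks[0] == 1
        d = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert d >= 0.95

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        pairs = _toy_library(rng, n=3)
        target, _ = _pair(rng, (9, 9, 9),
                          np.zeros((9, 9, 9), dtype=np.int32))
        params = FusionParams(search_radius=2, dilation=1)
        seg1, conf1 = segment_ventricles(target,
                                         build_library(pairs, 1), params)
        seg2, conf2 = segment_ventricles(target,
                                         build_library(pairs[::-1], 1),
                                         params)
        np.testing.assert_array_equal(seg1.data, seg2.data)
        np.testing.assert_allclose(conf1, conf2, atol=1e-6)

    def test_votes_within_unit_interval(self):
        rng = np.random.default_rng(8)
        pairs = _toy_library(rng, n=3)
        target, _ = _pair(rng, (9, 9, 9),
                          np.zeros((9, 9, 9), dtype=np.int32))
        _, conf = segment_ventricles(target, build_library(pairs, 1),
                                     FusionParams(search_radius=2))
        assert conf.min() >= 0.0 and conf.max() <= 1.0

    def test_raising_threshold_never_adds_voxels(self):
        rng = np.random.default_rng(9)
        pairs = _toy_library(rng, n=3)
        tmask = np.zeros((9, 9, 9), dtype=np.int32)
        tmask[3:6, 3:6, 3:6] = 1
        target, _ = _pair(rng, (9, 9, 9), tmask)
        lib = build_library(pairs, 1)
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            seg, _ = segment_ventricles(
                target, lib, FusionParams(search_radius=2,
                                          decision_threshold=thr))
            if prev is not None:
                assert not np.any((seg.data == 1) & (prev == 0))
            prev = seg.data

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        pairs = _toy_library(rng)
        lib = build_library(pairs, 1)
        target = VolumeImage(rng.normal(50, 5, (11, 11, 11)), AFF)
        with pytest.raises(GeometryError):
            segment_ventricles(target, lib)


class TestSegmentationVolume:
    @pytest.mark.parametrize("spacing,expected", [((1, 1, 1), 100.0),
                                                  ((1, 1, 2), 200.0)])
    def test_volume_scales_with_spacing(self, spacing, expected):
        data = np.zeros((10, 10, 10), dtype=np.int32)
        data.ravel()[:100] = 1
        aff = np.diag(list(spacing) + [1.0])
        assert segmentation_volume(LabelVolume(data, aff)) == \
            pytest.approx(expected)

    def test_empty_mask_zero(self):
        assert segmentation_volume(
            LabelVolume(np.zeros((8, 8, 8), dtype=np.int32), AFF)) == 0.0

    def test_non_binary_rejected(self):
        data = np.full((8, 8, 8), 2, dtype=np.int32)
        with pytest.raises(TypeError):
            segmentation_volume(LabelVolume(data, AFF))
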