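"""Texture features against brute-force enumerators and worked examples."""

import numpy as np
import pytest

import oracles as O
from ctamuscle.features import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    DiscretizationParams,
)
from ctamuscle.features import texture as T
from ctamuscle.features.discretization import discretize


def random_roi(rng, max_side=8, n_levels=5, p_mask=0.8):
    shape = tuple(int(s) for s in rng.integers(2, max_side + 1, size=3))
    hu = rng.integers(0, n_levels, size=shape).astype(float)
    mask = rng.random(shape) < p_mask
    if mask.sum() < 2:
        mask[tuple(np.unravel_index([0, 1], shape))] = True
    return hu, mask


def all_texture(volume, mask, disc):
    out = {}
    out.update(T.glcm_features(volume, mask, disc))
    out.update(T.gldm_features(volume, mask, disc))
    out.update(T.glrlm_features(volume, mask, disc))
    out.update(T.glszm_features(volume, mask, disc))
    out.update(T.ngtdm_features(volume, mask, disc))
    return out


def all_texture_oracle(hu, mask, disc):
    lv, ng = O.discretize_oracle(hu, mask, disc.bin_width)
    out = {}
    out.update(O.glcm_features_oracle(lv, mask, ng, disc.angles))
    out.update(O.gldm_features_oracle(lv, mask, ng, disc.neighborhood))
    out.update(O.glrlm_features_oracle(lv, mask, ng, disc.angles, T._GLRLM_MAP))
    out.update(O.glszm_features_oracle(lv, mask, ng, disc.neighborhood, T._GLSZM_MAP))
    out.update(O.ngtdm_features_oracle(lv, mask, ng, disc.neighborhood))
    return out


class TestWorkedExamples:
    def test_glcm_row_example(self):
        """Row [1,1,2], one direction: P = [[.5,.25],[.25,0]]."""
        hu = np.array([1.0, 1.0, 2.0]).reshape(3, 1, 1)
        mask = np.ones_like(hu, dtype=bool)
        lv, ng = discretize(hu, mask, 1.0)
        p = T.glcm_matrix(lv, mask, ng, (1, 0, 0))
        assert np.allclose(p, [[0.5, 0.25], [0.25, 0.0]])
        feats = T._glcm_single(p)
        assert feats["glcm_MaximumProbability"] == pytest.approx(0.5)
        assert feats["glcm_JointEnergy"] == pytest.approx(0.375)

    def test_glcm_constant_image(self):
        hu = np.full((4, 4, 4), 7.0)
        mask = np.ones_like(hu, dtype=bool)
        feats = T.glcm_features(hu, mask, DiscretizationParams())
        assert feats["glcm_Contrast"] == 0
        assert feats["glcm_MaximumProbability"] == 1
        assert feats["glcm_Correlation"] == 1  # documented degenerate value

    def test_glrlm_row_example(self):
        """[1,1,1,2] along one direction: runs (1,len3),(2,len1)."""
        hu = np.array([1.0, 1.0, 1.0, 2.0]).reshape(4, 1, 1)
        mask = np.ones_like(hu, dtype=bool)
        lv, ng = discretize(hu, mask, 1.0)
        mat = T.glrlm_matrix(lv, mask, ng, (1, 0, 0))
        assert mat[0, 2] == 1 and mat[1, 0] == 1 and mat.sum() == 2
        feats = T._rl_style_features(mat, 4, "glrlm", T._GLRLM_MAP)
        assert feats["glrlm_ShortRunEmphasis"] == pytest.approx((1 / 9 + 1) / 2)

    def test_gldm_constant_cube(self):
        """Constant 3x3x3 cube: each voxel's dependence = its neighbor count."""
        hu = np.full((3, 3, 3), 5.0)
        mask = np.ones_like(hu, dtype=bool)
        lv, ng = discretize(hu, mask, 5.0)
        mat = T.gldm_matrix(lv, mask, ng, DiscretizationParams().neighborhood)
        # corner 8, edge 12, face 18, center 27 dependent sizes (count+1)
        sizes = {j + 1: mat[0, j] for j in range(mat.shape[1]) if mat[0, j]}
        assert sizes == {8: 8, 12: 12, 18: 6, 27: 1}

    def test_gldm_single_voxel(self):
        hu = np.full((1, 1, 1), 5.0)
        mask = np.ones_like(hu, dtype=bool)
        feats = T.gldm_features(hu, mask, DiscretizationParams())
        assert feats["gldm_DependenceNonUniformityNormalized"] == pytest.approx(1.0)

    def test_glszm_constant_image_single_zone(self):
        hu = np.full((4, 4, 2), 3.0)
        mask = np.ones_like(hu, dtype=bool)
        feats = T.glszm_features(hu, mask, DiscretizationParams())
        assert feats["glszm_ZonePercentage"] == pytest.approx(1.0 / 32)
        assert feats["glszm_SizeZoneNonUniformity"] == pytest.approx(1.0)

    def test_ngtdm_constant_image(self):
        hu = np.full((4, 4, 4), 3.0)
        mask = np.ones_like(hu, dtype=bool)
        feats = T.ngtdm_features(hu, mask, DiscretizationParams())
        assert feats["ngtdm_Contrast"] == 0


class TestOracleEquivalence:
    """Vectorized implementations match plain-loop enumerators exactly."""

    @pytest.mark.parametrize("seed", range(8))
    def test_all_families_random_roi(self, seed):
        rng = np.random.default_rng(seed)
        disc = DiscretizationParams(bin_width=1.0)
        hu, mask = random_roi(rng, max_side=6)
        mine = all_texture(hu, mask, disc)
        ref = all_texture_oracle(hu, mask, disc)
        assert set(mine) == set(ref)
        for k in ref:
            assert mine[k] == pytest.approx(ref[k], rel=1e-9, abs=1e-9), k

    def test_2d_mode_matches_oracle(self):
        rng = np.random.default_rng(99)
        disc = DiscretizationParams(bin_width=1.0, mode="2d")
        hu, mask = random_roi(rng, max_side=6)
        mine = all_texture(hu, mask, disc)
        ref = all_texture_oracle(hu, mask, disc)
        for k in ref:
            assert mine[k] == pytest.approx(ref[k], rel=1e-9, abs=1e-9), k


class TestInvariants:
    def test_matrices_are_normalized(self, rng):
        disc = DiscretizationParams(bin_width=1.0)
        hu, mask = random_roi(rng)
        lv, ng = discretize(hu, mask, 1.0)
        for a in disc.angles:
            p = T.glcm_matrix(lv, mask, ng, a)
            if p is not None:
                assert p.sum() == pytest.approx(1.0)
                assert (p >= 0).all() and (p <= 1).all()

    def test_translation_invariance(self, rng):
        disc = DiscretizationParams(bin_width=1.0)
        hu = rng.integers(0, 4, size=(4, 4, 4)).astype(float)
        mask = np.zeros((10, 10, 10), dtype=bool)
        vol = np.zeros((10, 10, 10))
        mask[1:5, 1:5, 1:5] = True
        vol[1:5, 1:5, 1:5] = hu
        a = all_texture(vol, mask, disc)
        mask2 = np.roll(mask, (3, 2, 4), axis=(0, 1, 2))
        vol2 = np.roll(vol, (3, 2, 4), axis=(0, 1, 2))
        b = all_texture(vol2, mask2, disc)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12), k

    def test_hu_shift_leaves_texture_unchanged(self, rng):
        """Adding a constant shifts the binning anchor, not the levels."""
        disc = DiscretizationParams(bin_width=2.0)
        hu, mask = random_roi(rng, n_levels=8)
        a = all_texture(hu, mask, disc)
        b = all_texture(hu + 42.0, mask, disc)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12), k

    def test_feature_name_counts(self):
        assert len(GLCM_FEATURES) == 24
        assert len(GLDM_FEATURES) == 14
        assert len(GLRLM_FEATURES) == 16
        assert len(GLSZM_FEATURES) == 16
        assert len(NGTDM_FEATURES) == 5
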