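"""Texture matrix families against brute-force voxel-scanning oracles."""

import numpy as np
import pytest

from fltrad import _texture
from fltrad.features import (
    DiscretizedVoi,
    discretize_fbn,
    glcm_features,
    glrlm_features,
)
from fltrad.io import SuvVolume, VoiMask

from _oracles import (
    gldzm_oracle,
    glcm_oracle,
    glrlm_oracle,
    glszm_oracle,
    ngldm_oracle,
    ngtdm_coarseness_oracle,
)


def random_block(seed, n_bins=4, max_side=5):
    """A random discretized block with a random mask (levels 0 outside)."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(1, n_bins + 1, size=shape)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[0] = True
    return np.where(mask, levels, 0).astype(np.int64)


class TestDiscretize:
    def test_min_and_max_map_to_first_and_last_level(self):
        data = np.full((2, 2, 2), 3.0)
        data[0, 0, 0], data[1, 1, 1] = 1.0, 9.0
        vol = SuvVolume(data, (1, 1, 1))
        mask = VoiMask(np.ones((2, 2, 2), bool), (1, 1, 1))
        disc = discretize_fbn(vol, mask, n_bins=32)
        assert disc.levels[0, 0, 0] == 1
        assert disc.levels[1, 1, 1] == 32

    def test_constant_voi_all_level_one(self):
        vol = SuvVolume(np.full((3, 3, 3), 4.2), (1, 1, 1))
        mask = VoiMask(np.ones((3, 3, 3), bool), (1, 1, 1))
        disc = discretize_fbn(vol, mask)
        assert np.all(disc.levels == 1)

    def test_integer_ramp_is_bijective(self):
        data = np.arange(32, dtype=float).reshape(2, 4, 4)
        vol = SuvVolume(data, (1, 1, 1))
        mask = VoiMask(np.ones(data.shape, bool), (1, 1, 1))
        disc = discretize_fbn(vol, mask, n_bins=32)
        assert sorted(disc.levels.ravel()) == list(range(1, 33))


class TestGlcm:
    def test_uniform_levels(self):
        disc = DiscretizedVoi(np.ones((3, 3, 3), dtype=np.int64), 4, 0, 1)
        out = glcm_features(disc)
        assert out["GLCM_JointAverage"] == pytest.approx(1.0)
        assert out["GLCM_AutoCorrelation"] == pytest.approx(1.0)
        assert out["GLCM_InformationMeasureCor1"] == 0.0

    def test_checkerboard_sum_average(self):
        idx = np.indices((4, 4, 4)).sum(axis=0)
        levels = (idx % 2 + 1).astype(np.int64)
        p = _texture.glcm_matrix(levels, 2)
        out = _texture.glcm_features(p)
        assert out["GLCM_SumAverage"] == pytest.approx(3.0)

    def test_two_by_two_grid_against_pair_enumeration(self):
        levels = np.array([[[1], [2]], [[1], [2]]], dtype=np.int64)
        mine = _texture.glcm_matrix(levels, 2)
        np.testing.assert_allclose(mine, glcm_oracle(levels, 2), atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_blocks_match_oracle(self, seed):
        levels = random_block(seed)
        mine = _texture.glcm_matrix(levels, 4)
        np.testing.assert_allclose(mine, glcm_oracle(levels, 4), atol=1e-12)


class TestGlrlm:
    def test_constant_line_single_direction(self):
        n = 7
        levels = np.ones((1, 1, n), dtype=np.int64)
        rlm = _texture.glrlm_matrix(levels, 1, directions=[(0, 0, 1)])
        feats = _texture.glrlm_features(rlm, n, n_directions=1)
        assert rlm[0, n - 1] == 1 and rlm.sum() == 1
        assert feats["GLRLM_LongRunEmphasis"] == pytest.approx(n**2)

    def test_alternating_line_short_runs(self):
        levels = np.array([[[1, 2, 1, 2, 1, 2]]], dtype=np.int64)
        rlm = _texture.glrlm_matrix(levels, 2, directions=[(0, 0, 1)])
        feats = _texture.glrlm_features(rlm, 6, n_directions=1)
        assert feats["GLRLM_ShortRunEmphasis"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_blocks_match_run_scanner(self, seed):
        levels = random_block(seed)
        mine = _texture.glrlm_matrix(levels, 4)
        oracle = glrlm_oracle(levels, 4)
        np.testing.assert_allclose(mine, oracle, atol=1e-12)


class TestZoneMatrices:
    def test_single_uniform_zone(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        szm, _ = _texture.glszm_gldzm_matrices(levels, 1)
        assert _texture.glszm_features(szm)["GLSZM_GLNonuniformity"] == pytest.approx(1.0)

    def test_two_disjoint_single_voxel_zones(self):
        levels = np.zeros((5, 1, 1), dtype=np.int64)
        levels[0] = levels[4] = 1
        szm, _ = _texture.glszm_gldzm_matrices(levels, 1)
        assert _texture.glszm_features(szm)["GLSZM_GLNonuniformity"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_blocks_match_flood_fill(self, seed):
        levels = random_block(seed)
        szm, dzm = _texture.glszm_gldzm_matrices(levels, 4)
        assert szm == glszm_oracle(levels)
        assert dzm == gldzm_oracle(levels)


class TestNgldmNgtdm:
    def test_constant_block_interior_dependence(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        mat = _texture.ngldm_matrix(levels, 1)
        # only the center voxel has all 26 neighbors equal: j = 27
        assert mat[0, 26] == 1.0

    def test_constant_block_coarseness_guard(self):
        levels = np.ones((4, 4, 4), dtype=np.int64)
        assert _texture.ngtdm_coarseness(levels, 1) == pytest.approx(1e6)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_blocks_match_neighbor_scan(self, seed):
        levels = random_block(seed)
        mine = _texture.ngldm_matrix(levels, 4)
        np.testing.assert_allclose(mine, ngldm_oracle(levels, 4), atol=1e-12)
        assert _texture.ngtdm_coarseness(levels, 4) == pytest.approx(
            ngtdm_coarseness_oracle(levels), rel=1e-12
        )


def test_features_invariant_under_rigid_rotation(rng):
    """Every merged-direction family is unchanged by a 90-degree rotation of
    an isotropic block (neighborhoods are preserved)."""
    levels = np.where(rng.random((5, 5, 5)) < 0.9, rng.integers(1, 5, (5, 5, 5)), 0)
    rot = np.rot90(levels, k=1, axes=(0, 1)).copy()

    def all_feats(lv):
        out = {}
        out.update(_texture.glcm_features(_texture.glcm_matrix(lv, 4)))
        out.update(_texture.glrlm_features(_texture.glrlm_matrix(lv, 4), int((lv > 0).sum())))
        szm, dzm = _texture.glszm_gldzm_matrices(lv, 4)
        out.update(_texture.glszm_features(szm))
        out.update(_texture.gldzm_features(dzm))
        out.update(_texture.ngldm_features(_texture.ngldm_matrix(lv, 4)))
        out["NID_Coarseness"] = _texture.ngtdm_coarseness(lv, 4)
        return out

    a, b = all_feats(levels), all_feats(rot)
    for key in a:
        assert a[key] == pytest.approx(b[key], rel=1e-10), key
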