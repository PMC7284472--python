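"""GLCM construction, the 36 statistics, and histogram features."""

import numpy as np
import pytest

import oracles
import weedvision as wv
from weedvision.texture import (ANGLES, GLCM_STAT_NAMES, GLCMConfig,
                                DegeneratePatchError, texture_features)


def _random_glcm(rng, levels=8):
    m = rng.uniform(size=(levels, levels))
    m = m + m.T
    return m / m.sum()


class TestComputeGLCM:
    def test_constant_2x2_patch_single_entry(self):
        q = np.full((2, 2), 3, dtype=int)
        glcm = wv.compute_glcm(q, GLCMConfig(levels=8, angle=0))
        expected = np.zeros((8, 8))
        expected[2, 2] = 1.0
        assert np.array_equal(glcm, expected)

    @pytest.mark.parametrize("angle", ANGLES)
    def test_normalized_sum_one(self, rng, angle):
        q = rng.integers(1, 9, size=(10, 10))
        glcm = wv.compute_glcm(q, GLCMConfig(levels=8, angle=angle))
        assert glcm.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(glcm, glcm.T)

    @pytest.mark.parametrize("angle", ANGLES)
    def test_matches_pair_enumeration_oracle(self, rng, angle):
        q = rng.integers(1, 9, size=(4, 4))
        mine = wv.compute_glcm(q, GLCMConfig(levels=8, angle=angle))
        brute = oracles.brute_glcm(q, angle, levels=8)
        assert np.allclose(mine, brute, atol=1e-12)

    @pytest.mark.parametrize("angle", ANGLES)
    def test_mask_excludes_pixels_from_pairing(self, rng, angle):
        q = rng.integers(1, 9, size=(6, 6))
        mask = rng.uniform(size=(6, 6)) > 0.3
        q_masked = q.copy()
        q_masked[~mask] = 0
        mine = wv.compute_glcm(q, GLCMConfig(levels=8, angle=angle), mask=mask)
        brute = oracles.brute_glcm(q_masked, angle, levels=8)
        assert np.allclose(mine, brute, atol=1e-12)

    def test_degenerate_patch_signalled(self):
        with pytest.raises(DegeneratePatchError):
            wv.compute_glcm(np.array([[1]]), GLCMConfig(angle=0))


class TestGLCMStatistics:
    def test_uniform_2x2_entropy_two_bits(self):
        glcm = np.full((2, 2), 0.25)
        assert wv.glcm_statistics(glcm)["Entropy"] == pytest.approx(2.0)

    def test_single_entry_autocorrelation(self):
        # lone co-occurrence of gray values (2, 3) -> sum ij N_g = 6
        glcm = np.zeros((8, 8))
        glcm[1, 2] = 1.0
        assert wv.glcm_statistics(glcm)["Autocorrelation"] == pytest.approx(6.0)

    def test_all_36_match_summation_oracles(self, rng):
        for _ in range(5):
            glcm = _random_glcm(rng)
            mine = wv.glcm_statistics(glcm)
            brute = oracles.brute_glcm_statistics(glcm)
            assert set(mine) == set(GLCM_STAT_NAMES)
            for name in GLCM_STAT_NAMES:
                assert mine[name] == pytest.approx(brute[name], rel=1e-9, abs=1e-12), name

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            wv.glcm_statistics(np.ones((4, 4)))


class TestHistogramFeatures:
    def test_constant_patch(self):
        feats = wv.histogram_features(np.full((5, 5), 130.0))
        assert feats["Histogram entropy"] == pytest.approx(0.0)
        assert feats["Smoothness"] == pytest.approx(0.0)

    def test_two_equiprobable_levels_one_bit(self):
        vals = np.array([10.0] * 8 + [200.0] * 8)
        assert wv.histogram_features(vals)["Histogram entropy"] == pytest.approx(1.0)

    def test_matches_direct_oracle(self, rng):
        vals = rng.uniform(0, 255, size=(12, 12))
        mine = wv.histogram_features(vals)
        brute = oracles.brute_histogram_features(vals)
        assert mine["Histogram entropy"] == pytest.approx(brute["Histogram entropy"], rel=1e-9)
        assert mine["Smoothness"] == pytest.approx(brute["Smoothness"], rel=1e-9)


def test_rotation_permutes_angle_blocks(rng):
    """Rotating a patch by 90 degrees swaps the 0/90 and 45/135 blocks."""
    gray = rng.uniform(0, 255, size=(12, 12))
    base = texture_features(gray)
    rotated = texture_features(np.rot90(gray))
    swap = {0: 90, 45: 135, 90: 0, 135: 45}
    for stat in GLCM_STAT_NAMES:
        for ang, other in swap.items():
            assert rotated[f"{stat}-{ang}"] == pytest.approx(
                base[f"{stat}-{other}"], rel=1e-9, abs=1e-12)
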