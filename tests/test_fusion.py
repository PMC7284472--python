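"""Stereo object matching and feature fusion."""

import numpy as np
import pytest

import weedvision as wv
from weedvision.segmentation import PlantObject


def _obj(row, col):
    mask = np.ones((3, 3), dtype=bool)
    return PlantObject(mask=mask, bbox=(row, col, row + 3, col + 3),
                       centroid=(row + 1.0, col + 1.0), area=9)


class TestMatchObjects:
    def test_identical_lists_identity_zero_cost(self):
        objs = [_obj(5, 5), _obj(20, 40), _obj(50, 10)]
        report = wv.match_objects(objs, objs)
        assert [(m.left_index, m.right_index) for m in report.matches] == \
            [(0, 0), (1, 1), (2, 2)]
        assert all(m.cost == pytest.approx(0.0) for m in report.matches)
        assert report.unmatched_left == [] and report.unmatched_right == []

    def test_disparity_shifted_scene_matches_fully(self):
        """Objects rendered with a 12 px disparity pair up with centroid
        offset (0, 12)."""
        cfg = wv.SceneConfig(frame_size=(240, 320), n_objects_per_class=(2, 2, 2),
                             disparity_px=12, seed=17)
        left, right, _ = wv.generate_scene(cfg)
        _, objs_l = wv.segment_frame(left)
        _, objs_r = wv.segment_frame(right)
        report = wv.match_objects(objs_l, objs_r, max_offset=30)
        assert len(report.matches) == len(objs_l) == len(objs_r)
        for m in report.matches:
            assert m.centroid_offset[0] == pytest.approx(0.0, abs=1.0)
            assert m.centroid_offset[1] == pytest.approx(12.0, abs=1.0)

    def test_extra_right_object_reported_unmatched(self):
        left = [_obj(5, 5), _obj(30, 30)]
        right = [_obj(5, 5), _obj(30, 30), _obj(80, 80)]
        report = wv.match_objects(left, right)
        assert report.unmatched_right == [2]
        assert len(report.matches) == 2

    def test_empty_inputs(self):
        report = wv.match_objects([], [_obj(1, 1)])
        assert report.matches == [] and report.unmatched_right == [0]


class TestFuseFeatures:
    def test_arithmetic_and_geometric_of_4_and_9(self):
        left = np.array([4.0])
        right = np.array([9.0])
        assert wv.fuse_features(left, right, "arithmetic")[0] == pytest.approx(6.5)
        assert wv.fuse_features(left, right, "geometric")[0] == pytest.approx(6.0)

    def test_identical_vectors_fixed_point(self, rng):
        v = rng.uniform(0.5, 5.0, size=302)
        for mode in wv.FUSION_MODES:
            assert np.allclose(wv.fuse_features(v, v, mode), v)

    def test_symmetric(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        for mode in wv.FUSION_MODES:
            assert np.allclose(wv.fuse_features(a, b, mode),
                               wv.fuse_features(b, a, mode))

    def test_am_gm_inequality_on_positive_vectors(self, rng):
        a = rng.uniform(0.1, 10.0, size=500)
        b = rng.uniform(0.1, 10.0, size=500)
        am = wv.fuse_features(a, b, "arithmetic")
        gm = wv.fuse_features(a, b, "geometric")
        assert np.all(am >= gm - 1e-12)

    def test_shift_makes_any_vector_pair_am_dominant(self, rng):
        pool = rng.normal(scale=40.0, size=(60, 20))
        shift = wv.PositivityShift.fit(pool)
        a, b = pool[0], pool[1]
        am = wv.fuse_features(a, b, "arithmetic", shift=shift)
        gm = wv.fuse_features(a, b, "geometric", shift=shift)
        assert np.all(gm >= 1.0 - 1e-12)  # shifted domain is positive
        assert np.all(am >= gm - 1e-12)

    def test_mismatched_registries_rejected(self):
        with pytest.raises(ValueError):
            wv.fuse_features(np.ones(3), np.ones(4), "arithmetic")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            wv.fuse_features(np.ones(3), np.ones(3), "harmonic")


def test_positivity_shift_round_trip():
    pool = np.array([[0.0, -5.0], [10.0, 5.0]])
    shift = wv.PositivityShift.fit(pool)
    restored = wv.PositivityShift.from_dict(shift.to_dict())
    x = np.array([5.0, 0.0])
    assert np.allclose(shift.transform(x), restored.transform(x))
    assert np.allclose(shift.transform(x), [1.5, 1.5])
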