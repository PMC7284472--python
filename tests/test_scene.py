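"""Synthetic scene and feature-table generators."""

import numpy as np
import pytest
from scipy import stats

import weedvision as wv


class TestGenerateScene:
    def test_empty_config_gives_background_only(self):
        cfg = wv.SceneConfig(frame_size=(60, 80), n_objects_per_class=(0, 0, 0), seed=1)
        left, right, truth = wv.generate_scene(cfg)
        assert truth.objects == []
        assert not truth.label_mask.any()
        assert not wv.green_mask(left).any()
        assert not wv.green_mask(right).any()

    def test_identical_seeds_bitwise_identical(self):
        cfg = wv.SceneConfig(frame_size=(120, 160), n_objects_per_class=(1, 1, 1), seed=9)
        a = wv.generate_scene(cfg)
        b = wv.generate_scene(cfg)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert np.array_equal(a[2].label_mask, b[2].label_mask)

    def test_segmentation_recovers_objects_and_labels(self):
        """12 rendered plants come back as 12 segmented objects whose
        majority-overlap labels match the ground truth."""
        cfg = wv.SceneConfig(n_objects_per_class=(4, 4, 4), seed=7)
        left, _, truth = wv.generate_scene(cfg)
        _, objects = wv.segment_frame(left)
        assert len(objects) == 12
        for obj in objects:
            r0, c0, r1, c1 = obj.bbox
            vals = truth.label_mask[r0:r1, c0:c1][obj.mask]
            vals = vals[vals > 0]
            majority = np.bincount(vals).argmax()
            nearest = min(
                truth.objects,
                key=lambda t: abs(t["centroid"][0] - obj.centroid[0])
                + abs(t["centroid"][1] - obj.centroid[1]),
            )
            assert majority == nearest["class_label"]

    def test_plant_pixels_satisfy_rule_soil_violates(self, small_scene):
        _, left, right, truth = small_scene
        mask = wv.green_mask(left)
        plant = truth.label_mask > 0
        assert mask[plant].all()
        assert not mask[~plant].any()

    def test_right_frame_is_disparity_shifted(self, small_scene):
        cfg, left, right, truth = small_scene
        right_mask = wv.green_mask(right)
        left_mask = wv.green_mask(left)
        shifted = np.zeros_like(left_mask)
        shifted[:, cfg.disparity_px:] = left_mask[:, :-cfg.disparity_px]
        assert np.array_equal(right_mask, shifted)

    def test_placement_failure_signalled(self):
        cfg = wv.SceneConfig(frame_size=(30, 30), n_objects_per_class=(1, 0, 0), seed=0)
        with pytest.raises(wv.PlacementError):
            wv.generate_scene(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            wv.SceneConfig(frame_size=(0, 10))
        with pytest.raises(ValueError):
            wv.SceneConfig(disparity_px=-1)


class TestGenerateFeatureTable:
    def test_high_separation_is_nn_separable(self):
        """With one informative column at 10 sigma separation a 1-NN
        classifier on a held-out half scores 100%."""
        table = wv.generate_feature_table(120, 1, 0, 10.0, seed=3)
        X, y = table.values, table.labels
        train, test = np.arange(0, 120, 2), np.arange(1, 120, 2)
        from oracles import brute_knn

        preds = [brute_knn(X[train], y[train], x, k=1) for x in X[test]]
        assert np.mean(np.array(preds) == y[test]) == 1.0

    def test_zero_separation_has_no_association(self):
        """At class_sep=0 a permutation test on the informative column
        finds no label association at alpha=0.05 in >=95% of 100 runs."""
        hits = 0
        for seed in range(100):
            table = wv.generate_feature_table(60, 1, 0, 0.0, seed=seed)
            x = table.values[:, 0]
            groups = [x[table.labels == c] for c in (1, 2, 3)]
            f_obs = stats.f_oneway(*groups).statistic
            rng = np.random.default_rng(seed + 10_000)
            perm_f = []
            for _ in range(200):
                yp = rng.permutation(table.labels)
                perm_f.append(stats.f_oneway(*[x[yp == c] for c in (1, 2, 3)]).statistic)
            p = np.mean(np.asarray(perm_f) >= f_obs)
            hits += p > 0.05
        assert hits >= 95

    def test_deterministic(self):
        a = wv.generate_feature_table(50, 2, 3, 4.0, seed=8)
        b = wv.generate_feature_table(50, 2, 3, 4.0, seed=8)
        assert a.features.equals(b.features)
        assert np.array_equal(a.labels, b.labels)
        assert a.informative == b.informative

    def test_noise_columns_label_independent_metadata(self):
        table = wv.generate_feature_table(90, 2, 5, 6.0, seed=4)
        assert len(table.informative) == 2
        assert table.n_features == 7

    @pytest.mark.parametrize("kwargs", [
        {"n_samples": 0, "n_informative": 1, "n_noise": 0},
        {"n_samples": 10, "n_informative": 0, "n_noise": 2},
        {"n_samples": 10, "n_informative": 1, "n_noise": -1},
    ])
    def test_invalid_counts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            wv.generate_feature_table(class_sep=1.0, seed=0, **kwargs)


def test_save_scene_roundtrip(tmp_path, small_scene):
    import imageio.v3 as iio

    _, left, right, truth = small_scene
    wv.save_scene(tmp_path, left, right, truth, frame_id="f7")
    assert np.array_equal(iio.imread(tmp_path / "f7_L.png"), left)
    labels = iio.imread(tmp_path / "f7_labels.png")
    assert np.array_equal(labels, truth.label_mask)
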