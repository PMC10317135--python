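"""Synthetic well generator: determinism, UV contrast, ground truth."""

import numpy as np
import pytest

from artscore.synthgen import (
    SceneObject,
    SceneSpec,
    _scene_raster,
    generate_chop_dataset,
    generate_well,
    ground_truth_label,
    scene_for_class,
)
from artscore.tiling import Window


def obj_support(spec, index):
    _, _, _, sups = _scene_raster(spec)
    return sups[index][1]


class TestGenerateWell:
    def test_empty_drop_is_clear(self, full13):
        spec = SceneSpec(image_height=256, image_width=256, seed=1)
        well = generate_well(spec, scheme=full13)
        assert well.well_label.score_no == 1 and not well.well_label.is_rim

    def test_same_spec_same_pixels(self, full13):
        spec = scene_for_class(full13.by_score(13), 256, 256, seed=9)
        a, b = generate_well(spec), generate_well(spec)
        assert np.array_equal(a.visible, b.visible)
        assert np.array_equal(a.uv, b.uv)
        assert np.array_equal(a.droplet_mask, b.droplet_mask)

    def test_images_share_dimensions_and_range(self, crystal_well):
        w = crystal_well
        assert w.visible.shape == w.uv.shape == w.droplet_mask.shape
        for img in (w.visible, w.uv):
            assert img.min() >= 0.0 and img.max() <= 1.0

    def test_droplet_mask_is_one_connected_component(self, crystal_well):
        from scipy import ndimage

        _, n = ndimage.label(crystal_well.droplet_mask)
        assert n == 1

    def test_protein_crystal_fluoresces_salt_does_not(self, full13):
        sp = scene_for_class(full13.by_score(23), 384, 384, seed=5)
        ss = scene_for_class(full13.by_score(23), 384, 384, seed=5, salt=True)
        wp, ws = generate_well(sp), generate_well(ss)
        mp, ms = obj_support(sp, 0), obj_support(ss, 0)
        protein_uv = wp.uv[mp].mean()
        salt_uv = ws.uv[ms].mean()
        assert protein_uv - wp.uv[~mp].mean() >= 0.3
        assert protein_uv - salt_uv >= 0.3

    def test_object_outside_droplet_is_rejected(self):
        with pytest.raises(ValueError, match="outside the droplet"):
            SceneSpec(
                image_height=256, image_width=256,
                objects=(SceneObject("spherolite", 32, 10.0, 10.0, radius=5.0),),
            )

    def test_well_label_is_highest_priority_object(self, full13):
        stub = SceneSpec(image_height=256, image_width=256)
        cy, cx = stub.center
        spec = SceneSpec(
            image_height=256, image_width=256,
            objects=(
                SceneObject("phase_separation", 31, cy, cx, radius=20.0),
                SceneObject("precipitate", 12, cy + 30, cx, radius=20.0),
            ),
        )
        assert generate_well(spec, scheme=full13).well_label.score_no == 12


class TestGroundTruthLabel:
    def test_background_window_is_clear(self, full13):
        spec = scene_for_class(full13.by_score(23), 384, 384, seed=5)
        label = ground_truth_label(spec, Window(0, 0, 48, 48), scheme=full13)
        assert label.score_no == 1 and not label.is_rim

    def test_window_on_crystal_centroid_is_crystal(self, full13):
        spec = scene_for_class(full13.by_score(23), 384, 384, seed=5)
        o = spec.objects[0]
        win = Window(int(o.center_x) - 48, int(o.center_y) - 48, 96, 96)
        assert ground_truth_label(spec, win, scheme=full13).group == "crystal"

    def test_window_straddling_rim_only_is_rim(self, full13):
        spec = SceneSpec(image_height=384, image_width=384, seed=2)
        cy, cx = spec.center
        win = Window(int(cx + spec.radius) - 32, int(cy) - 32, 64, 64)
        assert ground_truth_label(spec, win, scheme=full13).is_rim

    def test_higher_priority_object_wins_within_a_window(self, full13):
        stub = SceneSpec(image_height=384, image_width=384)
        cy, cx = stub.center
        spec = SceneSpec(
            image_height=384, image_width=384,
            objects=(
                SceneObject("precipitate", 13, cy, cx, radius=50.0),
                SceneObject(
                    "protein_crystal", 23, cy, cx,
                    vertices=((cy - 20, cx - 20), (cy - 20, cx + 20),
                              (cy + 20, cx + 20), (cy + 20, cx - 20)),
                ),
            ),
        )
        win = Window(int(cx) - 48, int(cy) - 48, 96, 96)
        assert ground_truth_label(spec, win, scheme=full13).score_no == 23

    def test_agrees_with_chop_labels_from_generate_well(self, crystal_well, full13):
        for win, label in crystal_well.chop_labels.items():
            assert ground_truth_label(crystal_well.spec, win, scheme=full13) == label


class TestChopDataset:
    def test_balanced_counts(self, merged5):
        ds = generate_chop_dataset(10, merged5, 64, seed=7)
        assert ds.chops.shape == (50, 64, 64)
        assert np.bincount(ds.labels, minlength=5).tolist() == [10] * 5

    def test_rim_chops_intersect_the_rim_annulus(self, merged5):
        # regenerate scenes and verify the geometric content of rim chops
        ds = generate_chop_dataset(5, merged5, 64, seed=3)
        rim_idx = merged5.index_of(merged5.by_name("rim"))
        rim_chops = ds.chops[ds.labels == rim_idx]
        assert len(rim_chops) == 5
        # a rim chop contains the dark ring arc: strong intensity spread
        for chop in rim_chops:
            assert chop.std() > 0.03

    def test_different_seeds_differ_in_pixels_not_counts(self, merged5):
        a = generate_chop_dataset(6, merged5, 64, seed=1)
        b = generate_chop_dataset(6, merged5, 64, seed=2)
        assert not np.array_equal(a.chops, b.chops)
        assert np.array_equal(
            np.bincount(a.labels, minlength=5), np.bincount(b.labels, minlength=5)
        )

    def test_same_seed_reproduces(self, merged5):
        a = generate_chop_dataset(4, merged5, 64, seed=5)
        b = generate_chop_dataset(4, merged5, 64, seed=5)
        assert np.array_equal(a.chops, b.chops)
        assert np.array_equal(a.labels, b.labels)

    def test_full_scheme_dataset_covers_all_13_classes(self, full13):
        ds = generate_chop_dataset(2, full13, 64, seed=11)
        assert len(ds.chops) == 26
        assert set(ds.labels.tolist()) == set(range(13))

    def test_invalid_arguments_rejected(self, merged5):
        with pytest.raises(ValueError):
            generate_chop_dataset(0, merged5, 64)
        with pytest.raises(ValueError):
            generate_chop_dataset(1, merged5, 16)
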