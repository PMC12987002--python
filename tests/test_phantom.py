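import numpy as np
import pytest
from scipy import ndimage

from embryofuse import phantom
from embryofuse.metrics import average_gradient
from embryofuse.phantom import (CLASSES, CLINICAL_PROPORTIONS, Blastomere,
                                PhantomScene, apportion, make_dataset,
                                make_scene, render_all_in_focus, render_stack)

CELL_COUNTS = {"1cell": 1, "2cells": 2, "3cells": 3, "4cells": 4}


def _oracle_apportion(n, proportions):
    """Independent largest-remainder implementation (sorted loop)."""
    keys = list(proportions)
    total = sum(proportions.values())
    quotas = {k: n * proportions[k] / total for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    remainders = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), keys.index(k)))
    for k in remainders[: n - sum(counts.values())]:
        counts[k] += 1
    return counts


def count_rendered_cells(reference, scene):
    """Blastomere count by smoothing, thresholding and connected components."""
    smoothed = ndimage.gaussian_filter(reference, 1.5)
    mask = smoothed < 0.49
    labeled, n = ndimage.label(mask)
    if n == 0:
        return 0
    sizes = ndimage.sum(mask, labeled, range(1, n + 1))
    if scene.blastomeres:
        min_area = 0.4 * np.pi * min(b.radius for b in scene.blastomeres) ** 2
    else:
        min_area = 300.0
    return int((sizes > min_area).sum())


class TestApportionment:
    def test_matches_oracle_on_clinical_proportions(self):
        for n in (7, 53, 100, 1000, 9973):
            assert apportion(n, CLINICAL_PROPORTIONS) == _oracle_apportion(n, CLINICAL_PROPORTIONS)

    def test_clinical_counts_at_n1000(self):
        counts = apportion(1000, CLINICAL_PROPORTIONS)
        assert counts == {"1cell": 192, "2cells": 185, "3cells": 47, "4cells": 174,
                          "more": 216, "empty": 76, "not_defined": 110}
        assert sum(counts.values()) == 1000

    def test_uniform_n7_gives_one_each(self):
        counts = apportion(7, {c: 1 / 7 for c in CLASSES})
        assert all(v == 1 for v in counts.values())

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            apportion(10, {"1cell": -0.1, "2cells": 1.1})


class TestMakeScene:
    @pytest.mark.parametrize("label", CLASSES)
    def test_scene_invariants_hold(self, label):
        for seed in range(5):
            scene = make_scene(label, 128, seed)
            scene.validate()
            if label in CELL_COUNTS:
                assert len(scene.blastomeres) == CELL_COUNTS[label]
            elif label == "more":
                assert len(scene.blastomeres) >= 5
            else:
                assert len(scene.blastomeres) == 0
            assert scene.embryo_radius >= 4 * scene.zona_thickness
            depths = {f.depth for f in scene.features}
            if len(scene.features) >= 2:
                assert len(depths) >= 2

    def test_deterministic_and_seed_sensitive(self):
        a = make_scene("4cells", 256, 1)
        b = make_scene("4cells", 256, 1)
        c = make_scene("4cells", 256, 2)
        assert a == b
        assert a.blastomeres != c.blastomeres

    def test_empty_scene_has_no_features(self):
        scene = make_scene("empty", 256, 0)
        assert not scene.blastomeres and not scene.fragments

    def test_unknown_class_and_small_size_rejected(self):
        with pytest.raises(ValueError):
            make_scene("5cells", 128, 0)
        with pytest.raises(ValueError):
            make_scene("2cells", 32, 0)


def _single_depth_scene(depth=0.0, size=96):
    base = make_scene("1cell", size, 0)
    b = base.blastomeres[0]
    return PhantomScene(
        class_label="1cell", image_size=size, well_center=base.well_center,
        embryo_radius=base.embryo_radius, zona_thickness=base.zona_thickness,
        blastomeres=(Blastomere(b.center, b.radius, depth, b.texture_seed),),
        fragments=(), background_seed=base.background_seed,
    )


class TestRenderStack:
    def test_seven_planes_with_correct_offsets(self):
        stack = render_stack(make_scene("2cells", 96, 0), delta_z=0.8)
        stack.validate()
        assert np.allclose(stack.focal_offsets, np.arange(-3, 4) * 0.8)

    def test_delta_z_range_and_blur_scale_validated(self):
        scene = make_scene("2cells", 96, 0)
        with pytest.raises(ValueError):
            render_stack(scene, delta_z=2.0)
        with pytest.raises(ValueError):
            render_stack(scene, blur_scale=0.0)

    def test_plane_nearest_feature_depth_is_sharpest(self):
        # all structure at z = 0: F0 must out-sharpen the other six planes
        stack = render_stack(_single_depth_scene(0.0), noise_sigma=0.0)
        ags = [average_gradient(p) for p in stack.planes]
        assert np.argmax(ags) == 3

    def test_zero_defocus_is_identity(self):
        # single-depth scene, no noise: plane F0 equals the sharp rendering
        scene = _single_depth_scene(0.0)
        stack = render_stack(scene, noise_sigma=0.0)
        reference = render_all_in_focus(scene, noise_sigma=0.0)
        assert np.abs(np.asarray(stack.planes[3]) - reference).max() < 1e-12

    def test_extreme_depth_split_defeats_every_single_plane(self):
        scene = make_scene("2cells", 128, 4)
        spread = PhantomScene(
            class_label="2cells", image_size=128, well_center=scene.well_center,
            embryo_radius=scene.embryo_radius, zona_thickness=scene.zona_thickness,
            blastomeres=(
                Blastomere(scene.blastomeres[0].center, scene.blastomeres[0].radius,
                           -3.0, scene.blastomeres[0].texture_seed),
                Blastomere(scene.blastomeres[1].center, scene.blastomeres[1].radius,
                           3.0, scene.blastomeres[1].texture_seed),
            ),
            fragments=(), background_seed=scene.background_seed,
        )
        stack = render_stack(spread, delta_z=1.0)
        ag_ref = average_gradient(render_all_in_focus(spread))
        assert all(average_gradient(p) < ag_ref for p in stack.planes)

    def test_rendering_is_deterministic(self):
        scene = make_scene("3cells", 96, 7)
        a, b = render_stack(scene), render_stack(scene)
        assert np.array_equal(np.asarray(a.planes), np.asarray(b.planes))


class TestAllInFocus:
    def test_sharpness_ordering_over_seeded_scenes(self):
        # all-in-focus must dominate every defocused plane whenever the scene
        # spans at least two feature depths
        checked = 0
        for seed in range(10):
            for label in ("2cells", "3cells", "4cells", "more", "not_defined"):
                scene = make_scene(label, 128, seed)
                if len({f.depth for f in scene.features}) < 2:
                    continue
                ag_ref = average_gradient(render_all_in_focus(scene))
                stack = render_stack(scene)
                assert all(average_gradient(p) <= ag_ref for p in stack.planes), (label, seed)
                checked += 1
        assert checked >= 40

    def test_bright_disk_maximum_inside_disk(self):
        scene = _single_depth_scene()
        ref = render_all_in_focus(scene, noise_sigma=0.0)
        # blastomeres are darker than background: minimum lies inside the cell
        iy, ix = np.unravel_index(np.argmin(ndimage.gaussian_filter(ref, 2)), ref.shape)
        b = scene.blastomeres[0]
        assert np.hypot(ix - b.center[0], iy - b.center[1]) <= b.radius

    def test_empty_scene_is_background_only(self):
        scene = make_scene("empty", 128, 2)
        ref = render_all_in_focus(scene)
        assert count_rendered_cells(ref, scene) == 0
        assert ref.min() > 0.6  # no dark feature anywhere

    def test_rendered_cell_count_matches_declared(self):
        for seed in range(5):
            for label, want in CELL_COUNTS.items():
                scene = make_scene(label, 256, seed)
                ref = render_all_in_focus(scene)
                assert count_rendered_cells(ref, scene) == want, (label, seed)


class TestMakeDataset:
    def test_split_conservation_and_fractions(self):
        ds = make_dataset(50, seed=1, image_size=64)
        counts = {s: ds.split_assignment.count(s) for s in ("train", "val", "test")}
        assert sum(counts.values()) == 50
        assert counts == {"train": 34, "val": 6, "test": 10}

    def test_class_counts_follow_apportionment(self):
        ds = make_dataset(40, seed=2, image_size=64)
        assert ds.class_counts() == apportion(40, CLINICAL_PROPORTIONS)

    def test_regeneration_is_bit_identical(self):
        a = make_dataset(10, seed=9, image_size=64)
        b = make_dataset(10, seed=9, image_size=64)
        assert a.split_assignment == b.split_assignment
        for ia, ib in zip(a.items, b.items):
            assert ia.class_label == ib.class_label
            assert np.array_equal(np.asarray(ia.stack.planes), np.asarray(ib.stack.planes))
            assert np.array_equal(ia.reference, ib.reference)

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(5)
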