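import numpy as np
import pytest

from embryofuse import phantom, pyramid, roi


def _disk_image(cx, cy, radius, size=256, inside=0.8, outside=0.2):
    y, x = np.mgrid[0:size, 0:size]
    return np.where(np.hypot(x - cx, y - cy) < radius, inside, outside).astype(float)


class TestCoarseDetect:
    def test_uniform_image_raises_no_detection(self):
        with pytest.raises(roi.NoDetectionError):
            roi.coarse_detect(np.full((128, 128), 0.5))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            roi.coarse_detect(np.full((16, 16), 0.5))

    def test_centered_disk_found_accurately(self):
        box = roi.coarse_detect(_disk_image(130, 120, 60))
        assert np.hypot(box.center[0] - 130, box.center[1] - 120) < 10
        assert not box.clipped

    def test_corner_disk_clipped_with_flag(self):
        box = roi.coarse_detect(_disk_image(10, 12, 60))
        assert box.clipped
        cx, cy = box.center
        hw = box.half_width
        assert cx - hw >= -1 and cy - hw >= -1

    def test_phantom_center_within_ten_percent_of_width(self):
        for seed in range(8):
            scene = phantom.make_scene("4cells", 256, seed)
            fused = pyramid.fuse_lp(phantom.render_stack(scene), 4)
            box = roi.coarse_detect(fused)
            err = np.hypot(box.center[0] - scene.well_center[0],
                           box.center[1] - scene.well_center[1])
            assert err < 25.6, seed

    def test_empty_phantom_takes_no_detection_path(self):
        scene = phantom.make_scene("empty", 256, 0)
        fused = pyramid.fuse_lp(phantom.render_stack(scene), 4)
        with pytest.raises(roi.NoDetectionError):
            roi.coarse_detect(fused)


class TestRadialRefine:
    def test_disk_recovery_from_offset_init(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            cx, cy = rng.uniform(100, 156, 2)
            radius = rng.uniform(40, 60)
            img = _disk_image(cx, cy, radius)
            init = (cx + rng.uniform(-10, 10), cy + rng.uniform(-10, 10))
            est = roi.radial_refine(img, init, n_rays=180, r_min=20, r_max=90)
            assert abs(est.radius - radius) <= 2.0
            assert np.hypot(est.center[0] - cx, est.center[1] - cy) <= 2.0

    def test_uniform_image_raises_weak_edge(self):
        with pytest.raises(roi.WeakEdgeError):
            roi.radial_refine(np.full((128, 128), 0.5), (64, 64), r_min=10, r_max=50)

    def test_ray_count_insensitivity_on_clean_disk(self):
        img = _disk_image(128, 128, 50)
        est8 = roi.radial_refine(img, (125, 130), n_rays=8, r_min=20, r_max=90)
        est360 = roi.radial_refine(img, (125, 130), n_rays=360, r_min=20, r_max=90)
        assert abs(est8.radius - est360.radius) <= 1.0

    def test_invalid_ray_and_range_arguments_rejected(self):
        img = _disk_image(128, 128, 50)
        with pytest.raises(ValueError):
            roi.radial_refine(img, (128, 128), n_rays=4, r_min=10, r_max=60)
        with pytest.raises(ValueError):
            roi.radial_refine(img, (128, 128), r_min=50, r_max=40)
        with pytest.raises(ValueError):
            roi.radial_refine(img, (10, 128), r_min=20, r_max=200)

    def test_per_ray_radii_length_and_median(self):
        est = roi.radial_refine(_disk_image(128, 128, 50), (128, 128),
                                n_rays=36, r_min=20, r_max=90)
        assert est.n_rays == 36 and len(est.per_ray_radii) == 36
        assert est.radius == pytest.approx(np.median(est.per_ray_radii))

    def test_rotation_equivariance(self):
        img = _disk_image(100, 140, 45)
        est = roi.radial_refine(img, (105, 135), r_min=20, r_max=80)
        rot = np.rot90(img)  # (x, y) -> (y, W-1-x)
        size = img.shape[1]
        init_rot = (135, size - 1 - 105)
        est_rot = roi.radial_refine(rot, init_rot, r_min=20, r_max=80)
        assert abs(est.radius - est_rot.radius) <= 1.0
        assert est_rot.center[0] == pytest.approx(est.center[1], abs=1.0)
        assert est_rot.center[1] == pytest.approx(size - 1 - est.center[0], abs=1.0)


class TestCropResize:
    def test_output_is_always_224(self):
        img = _disk_image(128, 128, 50)
        for radius in (20.0, 50.0, 90.0):
            out = roi.crop_resize(img, roi.BoundaryEstimate((128, 128), radius))
            assert out.shape == (224, 224)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_identity_when_crop_side_equals_out_size(self):
        img = np.random.default_rng(1).random((256, 256))
        boundary = roi.BoundaryEstimate((128.0, 128.0), 40.0)
        side = int(round(2 * 40.0 * 1.1))
        out = roi.crop_resize(img, boundary, out_size=side, margin=0.1)
        x0 = int(round(128 - side / 2))
        assert np.array_equal(out, img[x0:x0 + side, x0:x0 + side])

    def test_edge_padding_handles_border_boundaries(self):
        img = _disk_image(10, 10, 30, size=128)
        out = roi.crop_resize(img, roi.BoundaryEstimate((10.0, 10.0), 30.0))
        assert out.shape == (224, 224)

    def test_scale_normalization_across_input_sizes(self):
        def disk_fraction(size):
            img = _disk_image(size / 2, size / 2, size / 5, size=size)
            est = roi.radial_refine(img, (size / 2 + 4, size / 2 - 3),
                                    r_min=size / 10, r_max=size / 3)
            crop = roi.crop_resize(img, est)
            return (crop > 0.5).mean()

        assert disk_fraction(256) == pytest.approx(disk_fraction(512), abs=0.02)


class TestLocateEmbryo:
    def test_phantom_boundary_recovery(self):
        for seed in (0, 1, 2):
            scene = phantom.make_scene("2cells", 256, seed)
            fused = pyramid.fuse_lp(phantom.render_stack(scene), 4)
            est = roi.locate_embryo(fused)
            assert abs(est.radius - scene.embryo_radius) / scene.embryo_radius < 0.08
            assert np.hypot(est.center[0] - scene.well_center[0],
                            est.center[1] - scene.well_center[1]) < 6.0

    def test_detector_hook_is_used(self):
        img = _disk_image(128, 128, 50)
        calls = []

        def fake_detector(image):
            calls.append(1)
            return roi.CandidateBox(center=(126.0, 129.0), half_width=48.0, score=1.0)

        est = roi.locate_embryo(img, detector=fake_detector)
        assert calls and abs(est.radius - 50) <= 2.0
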