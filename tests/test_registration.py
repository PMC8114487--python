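"""Keypoint detection, matching, MLS similarity warps and full registration."""

import numpy as np
import pytest
from scipy import ndimage

from matisse.config import RegistrationParams
from matisse.model import Raster
from matisse.registration import (
    DegenerateGeometryError,
    MatchSet,
    MLSTransform,
    detect_keypoints,
    fit_mls_similarity,
    match_keypoints,
    register_modalities,
    warp_raster,
)


def _blob_image(rng, shape=(128, 128), n=25):
    img = np.zeros(shape)
    for _ in range(n):
        r, c = rng.uniform(15, shape[0] - 15), rng.uniform(15, shape[1] - 15)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        img += np.exp(-(((rr - r) ** 2 + (cc - c) ** 2) / (2 * rng.uniform(2, 4) ** 2)))
    return img


class TestDetectKeypoints:
    def test_constant_image_yields_no_keypoints(self):
        kps = detect_keypoints(Raster(np.full((64, 64), 5.0), 1.0), n_pyramid_levels=1)
        assert kps == []

    def test_bright_square_corners_found(self):
        img = np.zeros((64, 64))
        img[20:29, 30:39] = 1.0  # 9x9 square; corners at (20,30),(20,38),(28,30),(28,38)
        kps = detect_keypoints(Raster(img, 1.0), n_pyramid_levels=1, max_points=50)
        pos = np.array([k.position for k in kps])
        for corner in [(20, 30), (20, 38), (28, 30), (28, 38)]:
            d = np.linalg.norm(pos - np.array(corner), axis=1).min()
            assert d <= 2.0, f"corner {corner} missed by {d:.2f} px"

    def test_rotation_equivariance(self, rng):
        img = _blob_image(rng)
        kps = detect_keypoints(Raster(img, 1.0), n_pyramid_levels=1, max_points=200)
        kps_rot = detect_keypoints(
            Raster(np.rot90(img).copy(), 1.0), n_pyramid_levels=1, max_points=200
        )
        assert len(kps) == len(kps_rot)
        n = img.shape[1]
        # (r, c) -> (n-1-c, r) under one CCW quarter turn
        mapped = {(round(n - 1 - k.position[1], 3), round(k.position[0], 3)): k for k in kps}
        checked = 0
        for kr in kps_rot:
            key = (round(kr.position[0], 3), round(kr.position[1], 3))
            if key in mapped:
                dtheta = (kr.orientation_rad - mapped[key].orientation_rad) % (2 * np.pi)
                dist = min(abs(dtheta - np.pi / 2), abs(dtheta - 3 * np.pi / 2))
                assert dist < 0.1
                checked += 1
        assert checked >= 0.8 * len(kps)

    def test_descriptor_normalized(self, rng):
        img = _blob_image(rng)
        kps = detect_keypoints(Raster(img, 1.0), n_pyramid_levels=2)
        for k in kps:
            assert abs(k.descriptor.mean()) < 1e-9
            assert abs(k.descriptor.std() - 1.0) < 1e-9
            assert 0 <= k.orientation_rad < 2 * np.pi

    def test_too_small_for_pyramid_depth(self):
        with pytest.raises(ValueError, match="pyramid"):
            detect_keypoints(Raster(np.zeros((40, 40)), 1.0), n_pyramid_levels=4)
        with pytest.raises(ValueError, match="small"):
            detect_keypoints(Raster(np.zeros((20, 20)), 1.0), n_pyramid_levels=1)


class TestMatching:
    def test_identity_lists_match_to_self(self, rng):
        img = _blob_image(rng)
        kps = detect_keypoints(Raster(img, 1.0), n_pyramid_levels=1, max_points=60)
        ms = match_keypoints(kps, kps, ratio_threshold=0.9)
        assert len(ms) > 0
        np.testing.assert_allclose(ms.src, ms.dst)
        assert np.all(ms.descriptor_distance < 1e-5)

    def test_shifted_view_recovers_offset(self, rng):
        big = _blob_image(rng, shape=(160, 160), n=40)
        fixed = big[:128, :128]
        moving = big[10:138, 4:132]  # moving (r,c) == fixed (r+10, c+4)
        kf = detect_keypoints(Raster(fixed, 1.0), n_pyramid_levels=1, max_points=150)
        km = detect_keypoints(Raster(moving, 1.0), n_pyramid_levels=1, max_points=150)
        ms = match_keypoints(km, kf, ratio_threshold=0.8)
        assert len(ms) >= 10
        err = np.linalg.norm(ms.dst - ms.src - np.array([10.0, 4.0]), axis=1)
        assert (err < 1.0).mean() >= 0.8

    def test_empty_result_is_valid(self, rng):
        # orthogonal random descriptors: ratio test rejects everything
        from matisse.registration import Keypoint

        def mk(seed):
            r = np.random.default_rng(seed)
            out = []
            for i in range(8):
                d = r.standard_normal(64)
                d = (d - d.mean()) / d.std()
                out.append(Keypoint((float(i), float(i)), 0, 0.0, d))
            return out

        ms = match_keypoints(mk(0), mk(1), ratio_threshold=0.01)
        assert len(ms) == 0


class TestMLS:
    def test_exact_similarity_recovered(self, rng):
        theta = np.deg2rad(30)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        src = rng.uniform(0, 100, size=(6, 2))
        dst = 2.0 * src @ R.T + np.array([5.0, -3.0])
        tf = fit_mls_similarity(MatchSet(src, dst, np.zeros(6)), outlier_reject_px=3.0,
                                min_inliers=6)
        query = rng.uniform(0, 100, size=(20, 2))
        expected = 2.0 * query @ R.T + np.array([5.0, -3.0])
        np.testing.assert_allclose(tf.map_points(query), expected, atol=1e-6)
        np.testing.assert_allclose(tf.map_points(src), dst, atol=1e-9)

    def test_identity_pairs_map_identity(self, rng):
        pts = rng.uniform(0, 50, size=(5, 2))
        tf = MLSTransform(MatchSet(pts, pts.copy(), np.zeros(5)))
        q = rng.uniform(0, 50, size=(10, 2))
        np.testing.assert_allclose(tf.map_points(q), q, atol=1e-8)

    def test_single_pair_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            fit_mls_similarity(MatchSet([[0.0, 0.0]], [[1.0, 1.0]], [0.0]))

    def test_outliers_rejected(self, rng):
        src = rng.uniform(0, 100, size=(12, 2))
        dst = src + np.array([3.0, -2.0])
        dst[0] += 40  # gross outlier
        tf = fit_mls_similarity(MatchSet(src, dst, np.zeros(12)), outlier_reject_px=3.0)
        assert len(tf.control_points) == 11


class TestWarp:
    def _identity_tf(self, extent=100.0):
        pts = np.array([[0.0, 0.0], [0.0, extent], [extent, 0.0], [extent, extent]])
        return MLSTransform(MatchSet(pts, pts.copy(), np.zeros(4)))

    def test_identity_transform_returns_input(self, rng):
        img = rng.uniform(0, 1, size=(64, 64))
        out = warp_raster(Raster(img, 1.0), self._identity_tf(63.0), (64, 64), 1.0)
        np.testing.assert_allclose(out.values, img, atol=1e-9)

    def test_translation_moves_blob(self):
        img = np.zeros((128, 128))
        img[40:46, 50:56] = 1.0
        pts = np.array([[0.0, 0.0], [0.0, 127.0], [127.0, 0.0], [127.0, 127.0]])
        tf = MLSTransform(MatchSet(pts, pts + np.array([10.0, 4.0]), np.zeros(4)))
        out = warp_raster(Raster(img, 1.0), tf, (128, 128), 1.0)
        cy, cx = ndimage.center_of_mass(out.values)
        cy0, cx0 = ndimage.center_of_mass(img)
        # moving->fixed translation (10, 4): the blob lands 10 rows down, 4 right
        assert abs(cy - cy0 - 10) < 0.1 and abs(cx - cx0 - 4) < 0.1

    def test_output_grid_covers_fixed_extent_at_moving_pitch(self, rng):
        img = rng.uniform(0, 1, size=(64, 64))
        out = warp_raster(
            Raster(img, 0.5), self._identity_tf(), (200, 200), 1.0,
            keep_moving_resolution=True,
        )
        assert out.shape == (400, 400)
        assert out.pixel_size_um == 0.5


class TestRegisterModalities:
    def test_aligned_pair_low_residual(self, small_scene):
        res = register_modalities(
            small_scene.if_nuclear, small_scene.imc_stack["DNA-Ir193"],
            RegistrationParams(n_pyramid_levels=2),
        )
        assert res.median_residual_um <= 0.5
        assert res.if_registered.pixel_size_um == small_scene.if_nuclear.pixel_size_um

    def test_known_misalignment_recovered(self, misaligned_scene):
        sc = misaligned_scene
        res = register_modalities(
            sc.if_nuclear, sc.imc_stack["DNA-Ir193"], RegistrationParams()
        )
        tf = sc.true_transform
        centers_if = tf.world_um_to_if_px(sc.centers_um)
        disp = np.linalg.norm(
            res.transform.map_points(centers_if) - tf.if_px_to_imc_px(centers_if), axis=1
        )
        assert (disp <= 1.0).mean() >= 0.9  # small scene; full batch in acceptance

    def test_nonoverlapping_images_degenerate(self, rng):
        a = _blob_image(rng, shape=(96, 96))
        b = _blob_image(np.random.default_rng(999), shape=(96, 96))
        with pytest.raises(DegenerateGeometryError):
            register_modalities(
                Raster(a, 1.0), Raster(b, 1.0), RegistrationParams(n_pyramid_levels=2)
            )
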