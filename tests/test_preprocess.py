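"""Background subtraction, motion correction, affine registration."""

import numpy as np
import pytest
from scipy import ndimage

from wdi.preprocess import (
    AffineTransform2D,
    RegistrationError,
    correct_motion,
    estimate_rigid_shift,
    map_rois,
    mean_image,
    register_sessions,
    subtract_background,
)
from wdi.synthetic import SimParams, layout_rois, render_movie
from wdi.traces import RoiMask


def _textured(shape=(128, 128), seed=0, sigma=3.0):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.normal(size=shape), sigma)


def _fourier_shift(img, shift):
    """Band-limited subpixel shift (circular)."""
    return np.fft.ifftn(
        ndimage.fourier_shift(np.fft.fftn(img), shift)
    ).real


class TestSubtractBackground:
    def test_constant_movie_becomes_zero(self):
        movie = np.full((5, 8, 8), 7.0)
        np.testing.assert_array_equal(subtract_background(movie), 0.0)

    def test_per_trial_minima_subtracted(self):
        movie = np.zeros((6, 4, 4))
        movie[:3] = 3.0 + np.arange(3)[:, None, None]  # trial 1, min 3
        movie[3:] = 5.0 + np.arange(3)[:, None, None]  # trial 2, min 5
        out = subtract_background(movie, trial_boundaries=[0, 3])
        np.testing.assert_allclose(out[:3], movie[:3] - 3.0)
        np.testing.assert_allclose(out[3:], movie[3:] - 5.0)
        assert out[:3].min() == 0.0 and out[3:].min() == 0.0

    def test_idempotent(self, rng):
        movie = rng.uniform(5, 10, size=(8, 6, 6))
        once = subtract_background(movie, trial_boundaries=[0, 4])
        twice = subtract_background(once, trial_boundaries=[0, 4])
        np.testing.assert_array_equal(once, twice)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            subtract_background(np.zeros((4, 2, 2)), trial_boundaries=[0, 4])


class TestRigidShift:
    def test_identical_frames_give_zero(self):
        ref = _textured()
        assert estimate_rigid_shift(ref, ref) == (0.0, 0.0)

    def test_integer_shift_exact(self):
        ref = _textured()
        frame = np.roll(np.roll(ref, 3, axis=0), -2, axis=1)
        assert estimate_rigid_shift(frame, ref) == (3.0, -2.0)

    def test_subpixel_shift_recovered(self):
        ref = _textured()
        frame = _fourier_shift(ref, (0.5, 0.25))
        dr, dc = estimate_rigid_shift(frame, ref, upsample=20)
        assert abs(dr - 0.5) < 0.1 and abs(dc - 0.25) < 0.1

    def test_flat_frame_warns_and_returns_zero(self):
        ref = _textured()
        with pytest.warns(UserWarning, match="flat"):
            assert estimate_rigid_shift(np.zeros_like(ref), ref) == (0.0, 0.0)


class TestCorrectMotion:
    def _movie(self, motion_sd, seed=3, T=60):
        p = SimParams(n_s2p=3, n_m1p=3, motion_sd_px=motion_sd,
                      shot_noise=False, noise_sd=0.0, seed=seed)
        rois = layout_rois(6, ["S2p"] * 3 + ["M1p"] * 3, p.fov_shape)
        rng = np.random.default_rng(seed)
        traces = 0.1 * rng.normal(size=(6, T))
        rng_still = np.random.default_rng(seed)
        still, _ = render_movie(traces, rois, p, rng=rng_still,
                                shifts=np.zeros((T, 2)))
        rng_mov = np.random.default_rng(seed)
        movie, shifts = render_movie(traces, rois, p, rng=rng_mov)
        return still.mean(axis=0), movie, shifts

    def test_identity_on_motionless_movie(self):
        ref, movie, shifts = self._movie(0.0)
        assert np.all(shifts == 0)
        corrected, est = correct_motion(movie, reference=ref)
        np.testing.assert_allclose(est, 0.0, atol=1e-3)
        np.testing.assert_allclose(corrected, movie, atol=1e-6)

    @pytest.mark.parametrize("sd", [1.0, 3.0])
    def test_ground_truth_shifts_recovered(self, sd):
        ref, movie, shifts = self._movie(sd)
        _, est = correct_motion(movie, reference=ref, upsample=20)
        assert np.abs(est - shifts).mean() < 0.1

    def test_correction_raises_frame_correlation(self):
        ref, movie, _ = self._movie(3.0)
        corrected, _ = correct_motion(movie, reference=ref, upsample=20)

        def mean_corr(stack):
            # crop away borders that the correction fills with 0
            sl = slice(15, -15)
            r = ref[sl, sl] - ref[sl, sl].mean()
            cs = []
            for f in stack:
                fc = f[sl, sl] - f[sl, sl].mean()
                cs.append((fc * r).sum()
                          / np.sqrt((fc**2).sum() * (r**2).sum()))
            return np.mean(cs)

        assert mean_corr(corrected) > mean_corr(movie)


class TestMeanImage:
    def test_constant_and_two_frame(self):
        movie = np.stack([np.zeros((4, 4)), np.full((4, 4), 2.0)])
        np.testing.assert_array_equal(mean_image(movie), 1.0)

    def test_matches_brute_force(self, rng):
        movie = rng.uniform(size=(10, 5, 5))
        got = mean_image(movie, (2, 7))
        brute = sum(movie[i] for i in range(2, 7)) / 5
        np.testing.assert_allclose(got, brute)

    def test_range_outside_movie_rejected(self):
        with pytest.raises(ValueError):
            mean_image(np.zeros((3, 2, 2)), (0, 5))


class TestAffine:
    def test_identity_images_give_identity_transform(self):
        img = np.clip(_textured(seed=1), 0, None) * 10 + 5
        t = register_sessions(img, img)
        np.testing.assert_allclose(t.A, np.eye(2), atol=0.01)
        np.testing.assert_allclose(t.t, 0.0, atol=0.5)

    def test_known_warp_recovered(self):
        img = np.clip(_textured(seed=2, sigma=2.0), 0, None) * 10 + 5
        center = (63.5, 63.5)
        true = AffineTransform2D.from_params(
            translation=(4.0, -1.0), rotation_deg=2.0, scale=1.02,
            center=center,
        )
        warped = true.warp_image(img)
        rec = register_sessions(warped, img)
        inv = rec.inverse()
        rot = np.rad2deg(np.arctan2(inv.A[1, 0], inv.A[0, 0]))
        scale = np.sqrt(abs(np.linalg.det(inv.A)))
        assert rot == pytest.approx(2.0, rel=0.05)
        assert scale == pytest.approx(1.02, rel=0.05)
        # residual displacement of the composed map stays subpixel-ish
        pts = np.array([[63.5, 63.5], [30, 30], [90, 100]])
        err = np.abs(rec.compose(true).apply(pts) - pts)
        assert err.max() < 0.5

    def test_pure_translation_has_identity_linear_part(self):
        img = np.clip(_textured(seed=4, sigma=2.0), 0, None) * 10 + 5
        true = AffineTransform2D.from_params(translation=(3.0, 2.0))
        warped = true.warp_image(img)
        rec = register_sessions(warped, img)
        np.testing.assert_allclose(rec.A, np.eye(2), atol=0.01)
        np.testing.assert_allclose(rec.t, (-3.0, -2.0), atol=0.3)

    def test_uncorrelated_images_raise(self):
        a = np.clip(_textured(seed=5, sigma=1.0), 0, None) * 10 + 5
        b = np.clip(_textured(seed=6, sigma=1.0), 0, None) * 10 + 5
        with pytest.raises(RegistrationError):
            register_sessions(a, b, min_correlation=0.8)

    def test_compose_inverse_is_identity(self):
        t = AffineTransform2D.from_params(
            translation=(2.0, -3.0), rotation_deg=5.0, scale=1.1, shear=0.05
        )
        comp = t.compose(t.inverse())
        np.testing.assert_allclose(comp.A, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(comp.t, 0.0, atol=1e-12)

    def test_json_round_trip(self, tmp_path):
        t = AffineTransform2D.from_params(
            translation=(1.0, 2.0), rotation_deg=3.0, scale=0.98
        )
        t.to_json(tmp_path / "t.json")
        back = AffineTransform2D.from_json(tmp_path / "t.json")
        np.testing.assert_allclose(back.A, t.A)
        np.testing.assert_allclose(back.t, t.t)


class TestMapRois:
    def _mask(self, cr=40, cc=70, radius=4):
        rows, cols = np.mgrid[0:128, 0:128]
        disk = np.hypot(rows - cr, cols - cc) <= radius
        return RoiMask(0, np.argwhere(disk), "S2p")

    def test_identity_preserves_masks(self):
        m = self._mask()
        out = map_rois([m], AffineTransform2D.identity(), (128, 128))
        assert out[0].pixel_set() == m.pixel_set()
        assert out[0].class_label == "S2p" and not out[0].lost

    def test_integer_translation_translates_pixel_set(self):
        m = self._mask()
        t = AffineTransform2D.from_params(translation=(5.0, -7.0))
        out = map_rois([m], t, (128, 128))
        expected = {(r + 5, c - 7) for r, c in m.pixel_set()}
        assert out[0].pixel_set() == expected

    def test_round_trip_overlap(self):
        m = self._mask()
        t = AffineTransform2D.from_params(
            translation=(3.0, -2.0), rotation_deg=2.0, scale=1.02,
            center=(63.5, 63.5),
        )
        back = map_rois(map_rois([m], t, (128, 128)), t.inverse(),
                        (128, 128))
        orig = m.pixel_set()
        overlap = len(orig & back[0].pixel_set()) / len(orig)
        assert overlap >= 0.95

    def test_mask_leaving_frame_flagged_lost(self):
        m = self._mask()
        t = AffineTransform2D.from_params(translation=(500.0, 0.0))
        out = map_rois([m], t, (128, 128))
        assert out[0].lost and out[0].roi_id == 0
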