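import numpy as np
import pytest
from scipy import ndimage

from longcal.config import DemonsConfig
from longcal.demons import (compose_fields, demons_force, exp_field,
                            is_diffeomorphic, jacobian_determinant,
                            log_demons_register, motion_correct_session, warp)


def _blob_phantom(shape=(80, 100), n=12, seed=0):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    for _ in range(n):
        y, x = rng.uniform(10, shape[0] - 10), rng.uniform(10, shape[1] - 10)
        img += rng.uniform(0.5, 1) * np.exp(-(((yy - y) / 8) ** 2 + ((xx - x) / 8) ** 2))
    return img


class TestForce:
    def test_zero_when_images_match(self, rng):
        img = rng.random((10, 10))
        assert not demons_force(img, img).any()

    def test_zero_for_flat_moving_image(self, rng):
        F = rng.random((10, 10))
        M = np.full((10, 10), 0.5)
        assert not demons_force(F, M).any()

    def test_matches_scalar_transcription(self, rng):
        # independent elementwise oracle of the printed force formula
        F = rng.random((7, 9))
        M = rng.random((7, 9))
        sx2, si2 = 2.0, 1.0
        v = demons_force(F, M, sigma_x2=sx2, sigma_i2=si2)
        gy, gx = np.gradient(M)
        for i in range(7):
            for j in range(9):
                diff = F[i, j] - M[i, j]
                den = gy[i, j] ** 2 + gx[i, j] ** 2 + (si2 / sx2) * diff ** 2
                vy = diff * gy[i, j] / den if den > 0 else 0.0
                vx = diff * gx[i, j] / den if den > 0 else 0.0
                assert abs(v[0, i, j] - vy) < 1e-12
                assert abs(v[1, i, j] - vx) < 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            demons_force(np.zeros((3, 3)), np.zeros((4, 4)))


class TestWarp:
    def test_zero_field_identity_to_the_bit(self, rng):
        img = rng.random((12, 15))
        out = warp(img, np.zeros((2, 12, 15)))
        np.testing.assert_array_equal(out, img)

    def test_integer_shift_moves_impulse(self):
        img = np.zeros((10, 10))
        img[6, 7] = 1.0
        field = np.zeros((2, 10, 10))
        field[0] += 2.0  # sample from 2 rows below -> impulse moves up 2
        field[1] += 3.0
        out = warp(img, field)
        assert out[4, 4] == 1.0 and out.sum() == 1.0

    def test_nearest_mode_for_labels(self):
        labels = np.arange(16.0).reshape(4, 4)
        field = np.full((2, 4, 4), 0.4)
        out = warp(labels, field, mode="nearest")
        assert set(np.unique(out)) <= set(np.unique(labels))

    def test_nonfinite_field_rejected(self):
        f = np.zeros((2, 4, 4))
        f[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            warp(np.zeros((4, 4)), f)

    def test_video_warp_per_frame(self, rng):
        video = rng.random((3, 8, 8))
        field = np.zeros((2, 8, 8))
        out = warp(video, field)
        np.testing.assert_array_equal(out, video)

    def test_round_trip_with_inverse(self):
        from longcal.simulate import gradient_gaussian_field
        rng = np.random.default_rng(1)
        img = ndimage.gaussian_filter(rng.random((60, 80)), 3)
        f = gradient_gaussian_field((60, 80), 15.0, 6.0, rng)
        # fixed-point approximate inverse: g(x) = -f(x + g(x))
        g = -f.copy()
        for _ in range(10):
            g = -np.stack([
                ndimage.map_coordinates(f[c], [np.mgrid[0:60, 0:80][0] + g[0],
                                               np.mgrid[0:60, 0:80][1] + g[1]],
                                        order=1, mode="nearest")
                for c in range(2)])
        back = warp(warp(img, f), g)
        err = np.abs(back - img)[8:-8, 8:-8].max()
        assert err < 0.02 * np.ptp(img)


class TestComposeExp:
    def test_compose_with_zero_field(self, rng):
        f = rng.normal(size=(2, 9, 9))
        z = np.zeros_like(f)
        np.testing.assert_allclose(compose_fields(z, f), f, atol=1e-12)
        np.testing.assert_allclose(compose_fields(f, z), f, atol=1e-12)

    def test_constant_translations_add(self):
        a = np.zeros((2, 8, 8))
        a[0] += 1.0
        b = np.zeros((2, 8, 8))
        b[1] += 2.0
        out = compose_fields(a, b)
        np.testing.assert_allclose(out[0], 1.0)
        np.testing.assert_allclose(out[1], 2.0)

    def test_sequential_warp_oracle(self):
        from longcal.simulate import gradient_gaussian_field
        rng = np.random.default_rng(2)
        img = ndimage.gaussian_filter(rng.random((50, 60)), 3)
        a = gradient_gaussian_field((50, 60), 10.0, 3.0, rng)
        b = gradient_gaussian_field((50, 60), 10.0, 3.0, rng)
        direct = warp(img, compose_fields(a, b))
        sequential = warp(warp(img, b), a)
        err = np.abs(direct - sequential)[5:-5, 5:-5].max()
        assert err < 0.02 * np.ptp(img)

    def test_exp_of_small_field_is_identityish(self):
        from longcal.simulate import gradient_gaussian_field
        rng = np.random.default_rng(3)
        v = gradient_gaussian_field((40, 40), 8.0, 0.1, rng)
        np.testing.assert_allclose(exp_field(v), v, atol=0.01)

    def test_exp_field_is_diffeomorphic(self):
        from longcal.simulate import gradient_gaussian_field
        rng = np.random.default_rng(4)
        v = gradient_gaussian_field((40, 40), 8.0, 6.0, rng)
        assert is_diffeomorphic(exp_field(v))


class TestRegistration:
    def test_self_registration_near_zero_field(self):
        img = _blob_phantom()
        S = log_demons_register(img, img)
        assert np.abs(S).max() < 1e-3

    def test_translation_recovery(self):
        img = _blob_phantom()
        M = ndimage.shift(img, (-3, 2), order=1, mode="nearest")
        cfg = DemonsConfig(max_iters=(150,) * 4)
        S = log_demons_register(img, M, cfg)
        # measure where the image has structure: gradient-weighted mean
        gy, gx = np.gradient(img)
        wgt = np.hypot(gy, gx)[10:-10, 10:-10]
        inner = S[:, 10:-10, 10:-10]
        dy = (inner[0] * wgt).sum() / wgt.sum()
        dx = (inner[1] * wgt).sum() / wgt.sum()
        assert np.hypot(dy - (-3), dx - 2) < 0.5

    def test_energy_non_increasing_with_small_blips(self):
        img = _blob_phantom()
        M = ndimage.shift(img, (2, -1), order=1, mode="nearest")
        _, energies = log_demons_register(img, M, return_energies=True)
        e = np.array(energies)
        growth = np.diff(e) / e[:-1]
        assert (growth < 0.01).all()

    def test_registered_field_is_diffeomorphic(self):
        img = _blob_phantom()
        M = ndimage.shift(img, (2, 2), order=1, mode="nearest")
        S = log_demons_register(img, M)
        assert (jacobian_determinant(S)[1:-1, 1:-1] > 0).all()

    def test_forward_backward_fields_approximately_inverse(self):
        A = _blob_phantom(seed=5)
        rng = np.random.default_rng(6)
        from longcal.simulate import gradient_gaussian_field
        f = gradient_gaussian_field(A.shape, 20.0, 3.0, rng)
        B = warp(A, f)
        S_ab = log_demons_register(A, B)  # B -> A
        S_ba = log_demons_register(B, A)  # A -> B
        comp = compose_fields(S_ab, S_ba)
        # composition should be near identity where there is structure
        gy, gx = np.gradient(A)
        wgt = np.hypot(gy, gx)[10:-10, 10:-10]
        mag = np.hypot(comp[0], comp[1])[10:-10, 10:-10]
        assert (mag * wgt).sum() / wgt.sum() < 0.5

    def test_diffusion_smoothing_reduces_high_frequency_energy(self, rng):
        field = rng.normal(size=(2, 64, 64))
        smoothed = np.stack([ndimage.gaussian_filter(field[c], 3.0) for c in range(2)])

        def hf_energy(f):
            spec = np.abs(np.fft.rfft2(f[0])) ** 2
            return spec[spec.shape[0] // 4:, spec.shape[1] // 4:].sum()

        assert hf_energy(smoothed) < hf_energy(field)


class TestMotionCorrection:
    def test_still_video_unchanged(self):
        img = _blob_phantom(shape=(48, 64), seed=7)
        video = np.stack([img] * 4)
        out = motion_correct_session(video)
        assert np.abs(np.stack(out.fields)).max() < 0.05
        np.testing.assert_allclose(out.video, video, atol=0.05 * np.ptp(img))

    def test_known_jitter_removed(self):
        base = _blob_phantom(shape=(48, 64), seed=8)
        # add vessel-like dark curves so the vessel-enhanced template has
        # structure to lock onto
        yy, xx = np.mgrid[0:48, 0:64]
        base = base + 1.0
        base[np.abs(yy - 2 * np.sqrt(np.maximum(xx, 1)) - 10) < 2] *= 0.4
        shifts = [(0, 0), (2, 1), (-2, 3), (1, -2)]
        video = np.stack([ndimage.shift(base, s, order=1, mode="nearest")
                          for s in shifts])
        out = motion_correct_session(video)
        gy, gx = np.gradient(base)
        wgt = np.hypot(gy, gx)[8:-8, 8:-8]
        errs = []
        for t, (dy, dx) in enumerate(shifts):
            f = out.fields[t][:, 8:-8, 8:-8]
            errs.append([(f[0] * wgt).sum() / wgt.sum() - dy,
                         (f[1] * wgt).sum() / wgt.sum() - dx])
        errs = np.array(errs)
        # the template (vessel-enhanced median frame) carries a common
        # offset; the jitter residual is what remains after removing it
        resid = errs - errs.mean(axis=0)
        assert np.hypot(resid[:, 0], resid[:, 1]).mean() < 0.5

    def test_deterministic(self):
        video = np.stack([_blob_phantom(shape=(40, 50), seed=9)] * 3)
        out1 = motion_correct_session(video)
        out2 = motion_correct_session(video)
        np.testing.assert_array_equal(out1.video, out2.video)
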