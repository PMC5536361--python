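"""Local linear kernel regression: fits, WRMS and jump diagnostics."""

import numpy as np
import pytest

import cassdetect as cd
from cassdetect.exceptions import InvalidInputError, InvalidParameterError
from cassdetect.surface import kernel_K


def oracle_wls(image, x, y, h, side_mask=None):
    """Independent normal-equations solve (dense design matrix + lstsq)."""
    H, W = image.shape
    r = int(np.floor(h))
    rows = []
    for dv in range(-r, r + 1):
        for du in range(-r, r + 1):
            xx, yy = x + du, y + dv
            if not (0 <= xx < W and 0 <= yy < H):
                continue
            wgt = kernel_K(du / h, dv / h)
            if side_mask is not None and not side_mask(du, dv):
                continue
            if wgt <= 0:
                continue
            rows.append((du, dv, wgt, image[yy, xx]))
    du = np.array([r_[0] for r_ in rows], dtype=float)
    dv = np.array([r_[1] for r_ in rows], dtype=float)
    wgt = np.array([r_[2] for r_ in rows])
    z = np.array([r_[3] for r_ in rows])
    X = np.stack([np.ones_like(du), du, dv], axis=1)
    sw = np.sqrt(wgt)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    resid = z - X @ beta
    wrms = np.sum(wgt * resid**2) / np.sum(wgt)
    return beta, wrms


class TestKernelK:
    def test_zero_on_and_outside_unit_circle(self):
        assert kernel_K(1.0, 0.0) == 0.0
        assert kernel_K(np.sqrt(0.5), np.sqrt(0.5)) == pytest.approx(0.0, abs=1e-15)
        assert kernel_K(2.0, 0.0) == 0.0

    def test_center_value_matches_direct_formula(self):
        expected = (1 - np.exp(-0.5)) / (2 * np.pi - 3 * np.pi * np.exp(-0.5))
        assert kernel_K(0.0, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_and_radial(self, rng):
        pts = rng.uniform(-1.5, 1.5, (100, 2))
        vals = kernel_K(pts[:, 0], pts[:, 1])
        assert np.all(vals >= 0)
        r = np.hypot(pts[:, 0], pts[:, 1])
        swapped = kernel_K(pts[:, 1], pts[:, 0])
        assert np.allclose(vals, swapped)
        del r


class TestFitLocalPlane:
    @pytest.mark.parametrize("h", [3.0, 5.0, 8.0])
    @pytest.mark.parametrize("masked", [False, True])
    def test_exact_plane_recovered(self, h, masked):
        yy, xx = np.indices((30, 30)).astype(float)
        img = 3.0 + 2.0 * xx - 1.0 * yy
        mask = cd.half_plane_mask(0.7, 1) if masked else None
        fit = cd.fit_local_plane(img, 15, 15, h, side_mask=mask)
        assert fit.a == pytest.approx(3.0 + 2.0 * 15 - 15.0, abs=1e-6)
        assert fit.b == pytest.approx(2.0, abs=1e-6)
        assert fit.c == pytest.approx(-1.0, abs=1e-6)
        assert fit.wrms == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        for x, y, h, mask in [
            (16, 16, 5.0, None),
            (16, 16, 5.0, cd.half_plane_mask(1.1, 2)),
            (4, 27, 4.0, None),
        ]:
            fit = cd.fit_local_plane(img, x, y, h, side_mask=mask)
            beta, wrms = oracle_wls(img, x, y, h, side_mask=mask)
            assert np.allclose([fit.a, fit.b, fit.c], beta, atol=1e-8)
            assert fit.wrms == pytest.approx(wrms, abs=1e-8)

    def test_noisy_constant_wrms_near_noise_variance(self):
        """Mean WRMS over replicate noisy windows tracks the injected variance."""
        rng = np.random.default_rng(99)
        sigma2 = 16.0
        vals = []
        for _ in range(200):
            img = 50.0 + rng.normal(0, np.sqrt(sigma2), (13, 13))
            vals.append(cd.fit_local_plane(img, 6, 6, 5.0).wrms)
        mean_wrms = float(np.mean(vals))
        assert abs(mean_wrms - sigma2) / sigma2 < 0.15

    def test_one_sided_fits_much_better_across_step(self):
        img = np.zeros((21, 21))
        img[:, 10:] = 50.0
        center = cd.fit_local_plane(img, 10, 10, 5.0)
        s1 = cd.fit_local_plane(img, 10, 10, 5.0, side_mask=cd.half_plane_mask(0.0, 1))
        s2 = cd.fit_local_plane(img, 10, 10, 5.0, side_mask=cd.half_plane_mask(0.0, 2))
        assert center.wrms > 10 * max(s1.wrms, s2.wrms)

    def test_constant_shift_moves_intercept_only(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 50, (25, 25))
        f0 = cd.fit_local_plane(img, 12, 12, 5.0)
        f1 = cd.fit_local_plane(img + 100.0, 12, 12, 5.0)
        assert f1.a == pytest.approx(f0.a + 100.0, abs=1e-9)
        assert f1.b == pytest.approx(f0.b, abs=1e-9)
        assert f1.c == pytest.approx(f0.c, abs=1e-9)
        assert f1.wrms == pytest.approx(f0.wrms, abs=1e-9)

    def test_window_too_small_raises(self):
        img = np.zeros((30, 30))
        with pytest.raises(InvalidParameterError):
            cd.fit_local_plane(img, 5, 5, 1.0)
        with pytest.raises(InvalidInputError):
            # window entirely outside except a sliver
            cd.fit_local_plane(img, 0, 0, 2.0, side_mask=lambda du, dv: (du > 1) & (dv > 1))


class TestDiagnostics:
    def test_constant_image_all_flat(self):
        img = np.full((32, 32), 42.0)
        grad = cd.scale_gradient(img, 1.0)
        d = cd.diagnostics(img, grad)
        assert np.allclose(d.diff, 0.0, atol=1e-9)
        assert np.allclose(d.w_t, 1.0)

    def test_step_edge_diff_exceeds_threshold(self):
        """A 50-level jump must trip the default Thr = 30 decision."""
        rng = np.random.default_rng(2)
        img = np.zeros((40, 40))
        img[:, 20:] = 50.0
        img += rng.normal(0, 2.0, img.shape)
        grad = cd.scale_gradient(img, 1.0)
        d = cd.diagnostics(img, grad)
        edge_cols = d.diff[5:-5, 19:22]
        assert np.median(edge_cols) > 30.0

    def test_fine_texture_diff_small_relative_to_wrms(self):
        """Period-2 checkerboard: both half-windows see the same pattern."""
        yy, xx = np.indices((48, 48))
        img = 128.0 + 20.0 * (((xx // 1 + yy // 1) % 2) * 2.0 - 1.0)
        grad = cd.scale_gradient(img, 1.0)
        d = cd.diagnostics(img, grad)
        inner = (slice(8, -8), slice(8, -8))
        ratio = np.median(np.abs(d.diff[inner])) / np.median(d.wrms_c[inner])
        assert ratio < 0.15

    def test_matches_per_pixel_oracle_on_interior(self, rng):
        """Vectorized moment algebra equals the explicit per-pixel solve."""
        img = rng.uniform(0, 255, (24, 24))
        grad = cd.scale_gradient(img, 1.0)
        h = 4.0
        d = cd.diagnostics(img, grad, h=h)
        for y in (8, 12, 15):
            for x in (9, 12, 16):
                theta = grad.orientation[y, x]
                _, wc = oracle_wls(img, x, y, h)
                _, w1 = oracle_wls(img, x, y, h, side_mask=cd.half_plane_mask(theta, 1))
                _, w2 = oracle_wls(img, x, y, h, side_mask=cd.half_plane_mask(theta, 2))
                assert d.wrms_c[y, x] == pytest.approx(wc, abs=1e-8)
                assert d.wrms_1[y, x] == pytest.approx(w1, abs=1e-8)
                assert d.wrms_2[y, x] == pytest.approx(w2, abs=1e-8)
                assert d.diff[y, x] == pytest.approx(max(wc - w1, wc - w2), abs=1e-8)

    def test_wt_forms(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        grad = cd.scale_gradient(img, 1.0)
        amp = cd.diagnostics(img, grad, sigma_m=100.0)
        damp = cd.diagnostics(img, grad, sigma_m=100.0, damped_wt=True)
        assert np.all(amp.w_t >= 1.0)
        assert np.all((damp.w_t > 0) & (damp.w_t <= 1.0))
        assert np.allclose(amp.w_t * damp.w_t, 1.0, rtol=1e-12)
        # sigma_m = inf disables the weight entirely, in both forms
        flat = cd.diagnostics(img, grad, sigma_m=np.inf)
        assert np.all(flat.w_t == 1.0)
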