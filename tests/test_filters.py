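"""Gradient front end, annular weights, and the classical suppression term."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cassdetect as cd
from cassdetect.exceptions import (
    DegenerateKernelError,
    InvalidInputError,
    InvalidParameterError,
)
from cassdetect.filters import _gaussian_1d, _gaussian_deriv_1d, dog_sigma


def brute_force_suppression(M, theta, w):
    """Literal double-loop realization of the surround sum (reflect borders)."""
    r = (w.shape[0] - 1) // 2
    H, W = M.shape
    Mp = np.pad(M, r, mode="reflect")
    Tp = np.pad(theta, r, mode="reflect")
    out = np.zeros_like(M)
    for y in range(H):
        for x in range(W):
            acc = 0.0
            for i in range(w.shape[0]):
                for j in range(w.shape[1]):
                    if w[i, j] == 0:
                        continue
                    dv, du = i - r, j - r
                    acc += (
                        w[i, j]
                        * Mp[y + dv + r, x + du + r]
                        * abs(np.cos(theta[y, x] - Tp[y + dv + r, x + du + r]))
                    )
            out[y, x] = acc
    return out


class TestScaleGradient:
    def test_constant_image_has_zero_gradient(self):
        g = cd.scale_gradient(np.full((32, 32), 7.0), 1.3)
        assert np.allclose(g.magnitude, 0.0, atol=1e-12)

    def test_linear_ramp_recovers_unit_slope_and_orientation(self):
        xx = np.tile(np.arange(40, dtype=float), (40, 1))
        g = cd.scale_gradient(xx, 1.0)
        interior = g.magnitude[5:-5, 5:-5]
        assert np.allclose(interior, 1.0, atol=1e-10)
        assert np.allclose(g.orientation[5:-5, 5:-5], 0.0, atol=1e-10)

    def test_step_response_matches_dense_convolution_oracle(self):
        """Full separable filtering equals brute-force 2-D kernel summation."""
        sigma, h = 1.0, 40.0
        img = np.zeros((21, 21))
        img[:, 10:] = h
        x, g1 = _gaussian_1d(sigma)
        d1 = _gaussian_deriv_1d(sigma)
        kx = np.outer(g1, d1)  # rows: y smoothing, cols: x derivative
        ky = np.outer(d1, g1)
        r = len(x) // 2
        pad = np.pad(img, r, mode="reflect")
        H, W = img.shape
        gx = np.zeros_like(img)
        gy = np.zeros_like(img)
        for y in range(H):
            for xcol in range(W):
                win = pad[y : y + 2 * r + 1, xcol : xcol + 2 * r + 1]
                # scipy convolution flips the kernel; do the same here
                gx[y, xcol] = np.sum(win * kx[::-1, ::-1])
                gy[y, xcol] = np.sum(win * ky[::-1, ::-1])
        expected = np.hypot(gx, gy)
        got = cd.scale_gradient(img, sigma)
        assert np.allclose(got.magnitude, expected, atol=1e-10)

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidParameterError):
            cd.scale_gradient(np.zeros((8, 8)), -1.0)
        with pytest.raises(InvalidInputError):
            cd.scale_gradient(np.full((8, 8), np.nan), 1.0)


class TestDistanceWeights:
    @pytest.mark.parametrize("sigma", np.arange(0.25, 2.51, 0.25))
    def test_l1_normalized_over_scale_sweep(self, sigma):
        k = cd.build_distance_weights(float(sigma))
        assert abs(k.w.sum() - 1.0) < 1e-10
        assert k.w.shape[0] % 2 == 1

    def test_center_entry_is_zero(self):
        for sigma in (0.5, 1.0, 2.0):
            k = cd.build_distance_weights(sigma)
            c = k.support_radius
            assert k.w[c, c] == 0.0

    def test_sign_change_radius_separates_support(self):
        """Bisection root of the radial DoG profile bounds the zero entries."""
        sigma = 1.0
        lo, hi = 1e-3, 4.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if dog_sigma(np.float64(mid * mid), sigma) < 0:
                lo = mid
            else:
                hi = mid
        r0 = 0.5 * (lo + hi)
        k = cd.build_distance_weights(sigma)
        assert abs(k.annulus_inner - r0) < 1e-6
        assert abs(k.annulus_outer - 4 * r0) < 1e-6
        c = k.support_radius
        uu, vv = np.meshgrid(*[np.arange(-c, c + 1)] * 2)
        rr = np.hypot(uu, vv)
        assert np.all(k.w[rr < r0 - 0.5] == 0.0)
        assert np.all(k.w[(rr > r0 + 0.5) & (rr <= c)] > 0.0)

    def test_degenerate_sigma_raises(self):
        with pytest.raises((DegenerateKernelError, InvalidParameterError)):
            cd.build_distance_weights(0.0)


class TestOrientationWeight:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(0.3, 0.3, 1.0), (0.0, np.pi / 2, 0.0), (0.0, np.pi / 3, 0.5)],
    )
    def test_reference_angles(self, a, b, expected):
        assert cd.orientation_weight(a, b) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_symmetric(self, a, b):
        v = cd.orientation_weight(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(cd.orientation_weight(b, a), abs=1e-12)


class TestSuppressionTerm:
    def test_zero_magnitude_gives_zero(self):
        k = cd.build_distance_weights(1.0)
        g = cd.GradientField(np.zeros((24, 24)), np.zeros((24, 24)), 1.0)
        assert np.all(cd.suppression_term(g, k) == 0.0)

    def test_uniform_field_preserved_by_normalization(self):
        k = cd.build_distance_weights(1.0)
        g = cd.GradientField(np.full((40, 40), 3.5), np.full((40, 40), 0.7), 1.0)
        s = cd.suppression_term(g, k)
        assert np.allclose(s, 3.5, atol=1e-10)

    def test_single_impulse_spreads_by_stencil(self, rng):
        k = cd.build_distance_weights(0.5)
        M = np.zeros((31, 31))
        M[15, 15] = 10.0
        theta = np.full_like(M, 0.4)
        s = cd.suppression_term(cd.GradientField(M, theta, 0.5), k)
        r = k.support_radius
        # the stencil is radially symmetric, so the spread around the impulse
        # equals the stencil itself scaled by the impulse value
        assert np.allclose(
            s[15 - r : 15 + r + 1, 15 - r : 15 + r + 1], 10.0 * k.w, atol=1e-12
        )

    def test_matches_double_loop_oracle_on_random_input(self, rng):
        k = cd.build_distance_weights(0.6)
        M = rng.uniform(0, 20, (32, 32))
        theta = rng.uniform(0, np.pi, (32, 32))
        got = cd.suppression_term(cd.GradientField(M, theta, 0.6), k)
        want = brute_force_suppression(M, theta, k.w)
        assert np.allclose(got, want, rtol=1e-8, atol=1e-10)

    def test_isotropy_under_quarter_rotation(self, rng):
        """Rotating the input by 90 degrees and rotating back is a no-op."""
        img = np.random.default_rng(3).uniform(0, 255, (48, 48))
        k = cd.build_distance_weights(1.0)

        def response(image):
            g = cd.scale_gradient(image, 1.0)
            s = cd.suppression_term(g, k)
            return cd.halfwave_suppress(g.magnitude, s, 1.0)

        direct = response(img)
        rotated = np.rot90(response(np.rot90(img)), -1)
        assert np.allclose(direct, rotated, atol=1e-6)


class TestHalfwaveSuppress:
    def test_alpha_zero_returns_magnitude(self, rng):
        M = rng.uniform(0, 10, (16, 16))
        s = rng.uniform(0, 10, (16, 16))
        assert np.array_equal(cd.halfwave_suppress(M, s, 0.0), M)

    def test_rectification_and_arithmetic(self):
        M = np.array([[5.0, 5.0]])
        s = np.array([[80.0, 20.0]])
        out = cd.halfwave_suppress(M, s, 0.1)
        assert out[0, 0] == 0.0  # 5 - 8 rectified
        assert out[0, 1] == pytest.approx(3.0)

    def test_never_exceeds_magnitude(self, rng):
        M = rng.uniform(0, 10, (20, 20))
        s = rng.uniform(0, 5, (20, 20))
        for alpha in (0.0, 0.1, 1.0, 3.0):
            E = cd.halfwave_suppress(M, s, alpha)
            assert np.all(E <= M + 1e-15)
            assert np.all(E >= 0)

    def test_negative_alpha_rejected(self):
        with pytest.raises(InvalidParameterError):
            cd.halfwave_suppress(np.zeros((4, 4)), np.zeros((4, 4)), -0.1)
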