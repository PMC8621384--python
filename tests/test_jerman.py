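import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselx import (
    DegenerateInputError,
    JermanParams,
    eigenvalues_2x2,
    hessian_at_scale,
    jerman_response,
    regularize_lambda,
    vesselness,
)
from vesselx.jerman import HessianField


def reference_vesselness(img, params):
    """Unvectorized per-pixel reference: library eigensolver + scalar
    branch logic, supremum over scales."""
    img = np.asarray(img, dtype=float)
    out = np.zeros_like(img)
    sign = 1.0 if params.polarity == "dark-on-bright" else -1.0
    for sigma in params.sigmas:
        h = hessian_at_scale(img, float(sigma))
        lam2 = np.zeros_like(img)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                m = np.array(
                    [[h.hxx[i, j], h.hxy[i, j]], [h.hxy[i, j], h.hyy[i, j]]]
                )
                vals = np.linalg.eigvalsh(m)
                big = vals[np.argmax(np.abs(vals))]
                lam2[i, j] = sign * big
        mx = lam2.max()
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                l2 = lam2[i, j]
                if mx <= 0:
                    lr = 0.0
                elif l2 > params.tau * mx:
                    lr = l2
                elif l2 > 0:
                    lr = params.tau * mx
                else:
                    lr = 0.0
                if l2 <= 0 or lr <= 0:
                    r = 0.0
                elif l2 >= lr / 2:
                    r = 1.0
                else:
                    r = l2 * l2 * (lr - l2) * (3.0 / (l2 + lr)) ** 3
                out[i, j] = max(out[i, j], r)
    return out


class TestHessian:
    def test_constant_image_has_zero_hessian(self):
        h = hessian_at_scale(np.full((32, 32), 0.3), 2.0)
        for arr in (h.hxx, h.hxy, h.hyy):
            np.testing.assert_allclose(arr, 0.0, atol=1e-12)

    def test_quadratic_in_x_gives_2_sigma_squared(self):
        c = np.arange(64, dtype=float)
        img = np.tile(c * c, (64, 1))
        h = hessian_at_scale(img, 2.0)
        interior = np.s_[20:44, 20:44]
        np.testing.assert_allclose(h.hxx[interior], 8.0, atol=1e-6)
        np.testing.assert_allclose(h.hxy[interior], 0.0, atol=1e-6)

    def test_bilinear_gives_sigma_squared_cross_term(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        h = hessian_at_scale(yy * xx, 2.0)
        np.testing.assert_allclose(h.hxy[20:44, 20:44], 4.0, atol=1e-6)

    def test_oversized_kernel_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            hessian_at_scale(np.zeros((16, 16)), 8.0)


class TestEigenvalues:
    def test_diagonal_matrix(self):
        h = HessianField(
            hxx=np.array([[2.0]]), hxy=np.array([[0.0]]),
            hyy=np.array([[1.0]]), scale=1.0,
        )
        e = eigenvalues_2x2(h)
        assert (e.lam1[0, 0], e.lam2[0, 0]) == (1.0, 2.0)

    def test_antidiagonal_tie_ordered_ascending(self):
        h = HessianField(
            hxx=np.array([[0.0]]), hxy=np.array([[1.0]]),
            hyy=np.array([[0.0]]), scale=1.0,
        )
        e = eigenvalues_2x2(h)
        assert (e.lam1[0, 0], e.lam2[0, 0]) == (-1.0, 1.0)

    def test_matches_library_eigensolver(self, rng):
        hxx, hyy, hxy = rng.normal(size=(3, 16, 16))
        e = eigenvalues_2x2(HessianField(hxx=hxx, hxy=hxy, hyy=hyy, scale=1.0))
        for i in range(16):
            for j in range(16):
                ref = np.linalg.eigvalsh(
                    np.array([[hxx[i, j], hxy[i, j]], [hxy[i, j], hyy[i, j]]])
                )
                got = sorted([e.lam1[i, j], e.lam2[i, j]])
                np.testing.assert_allclose(got, ref, atol=1e-12)
        # magnitude ordering
        assert (np.abs(e.lam1) <= np.abs(e.lam2) + 1e-15).all()

    @settings(derandomize=True, max_examples=50)
    @given(
        hxx=st.floats(-10, 10), hxy=st.floats(-10, 10), hyy=st.floats(-10, 10)
    )
    def test_trace_and_determinant_identities(self, hxx, hxy, hyy):
        h = HessianField(
            hxx=np.array([[hxx]]), hxy=np.array([[hxy]]),
            hyy=np.array([[hyy]]), scale=1.0,
        )
        e = eigenvalues_2x2(h)
        scale = max(1.0, abs(hxx), abs(hyy), abs(hxy))
        assert abs(e.lam1 + e.lam2 - (hxx + hyy))[0, 0] < 1e-9 * scale
        assert abs(e.lam1 * e.lam2 - (hxx * hyy - hxy * hxy))[0, 0] < 1e-9 * scale**2


class TestRegularization:
    def test_piecewise_branches(self):
        grid = np.array([10.0, 7.0, 3.0, -2.0])
        out = regularize_lambda(grid, 0.5)
        np.testing.assert_allclose(out, [10.0, 7.0, 5.0, 0.0])

    def test_nonpositive_maximum_gives_zero(self):
        out = regularize_lambda(np.array([-1.0, -5.0, 0.0]), 0.5)
        np.testing.assert_array_equal(out, 0.0)


class TestResponseFunction:
    @pytest.mark.parametrize(
        "lam2, lam_rho, expected",
        [
            (-1.0, 3.0, 0.0),      # nonpositive cross-section curvature
            (0.5, 0.0, 0.0),       # regularized eigenvalue vanished
            (2.0, 4.0, 1.0),       # plateau: lam2 >= lam_rho/2
            (5.0, 4.0, 1.0),       # above the plateau edge
            (1.0, 4.0, 81.0 / 125.0),  # cubic branch: 1*3*(3/5)^3
        ],
    )
    def test_branch_values(self, lam2, lam_rho, expected):
        assert jerman_response(lam2, lam_rho) == pytest.approx(expected, abs=1e-12)

    def test_continuity_at_plateau_edge(self):
        lo = jerman_response(1.9999999, 4.0)
        assert abs(lo - 1.0) < 1e-5

    @settings(derandomize=True, max_examples=200)
    @given(lam2=st.floats(-100, 100), lam_rho=st.floats(-100, 100))
    def test_bounded_between_zero_and_one(self, lam2, lam_rho):
        v = jerman_response(lam2, lam_rho)
        assert 0.0 <= v <= 1.0


class TestVesselness:
    def test_constant_image_zero_response(self):
        p = JermanParams(s_min=3, s_max=6, s_step=1)
        out = vesselness(np.full((32, 32), 0.7), p)
        np.testing.assert_array_equal(out.response, 0.0)

    def test_single_scale_equals_per_scale_map(self, clean_tube):
        img, _ = clean_tube
        p = JermanParams(s_min=8, s_max=8, s_step=1)
        out = vesselness(img.pixels, p)
        (only,) = out.per_scale.values()
        np.testing.assert_array_equal(out.response, only)

    def test_enlarging_scale_set_never_decreases_response(self, clean_tube):
        img, _ = clean_tube
        small = vesselness(img.pixels, JermanParams(s_min=4, s_max=8, s_step=2))
        large = vesselness(img.pixels, JermanParams(s_min=4, s_max=12, s_step=2))
        assert (large.response >= small.response - 1e-15).all()

    def test_matches_per_pixel_reference_on_random_images(self, rng):
        p = JermanParams(s_min=2.0, s_max=4.0, s_step=1.0)
        for _ in range(3):
            img = rng.random((16, 16))
            fast = vesselness(img, p).response
            slow = reference_vesselness(img, p)
            np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_bright_on_dark_polarity_mirrors_inverted_image(self, clean_tube):
        img, _ = clean_tube
        p_dark = JermanParams(s_min=6, s_max=10, s_step=2)
        p_bright = JermanParams(
            s_min=6, s_max=10, s_step=2, polarity="bright-on-dark"
        )
        dark = vesselness(img.pixels, p_dark).response
        bright = vesselness(1.0 - img.pixels, p_bright).response
        np.testing.assert_allclose(dark, bright, atol=1e-12)

    def test_response_within_unit_interval(self, tree_phantom):
        img, _ = tree_phantom
        out = vesselness(img.pixels, JermanParams(s_min=3, s_max=8, s_step=1))
        assert out.response.min() >= 0.0
        assert out.response.max() <= 1.0
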