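"""Pre-processing chain: normalization, homogenization, filters, moments,
principal-axis alignment."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from octmap import (GrayImage, align, anisotropic_diffusion, compute_moments,
                    generate_phantom, homogenize_resolution, median_filter_mm,
                    normalize_intensity, preprocess_image)
from octmap.preprocess import principal_axis


def gi(arr, px=0.05):
    return GrayImage(np.asarray(arr, dtype=float), px, px)


# -- normalize ---------------------------------------------------------------

def test_normalize_affine_map():
    out = normalize_intensity(gi([[2.0, 4.0], [6.0, 4.0]]))
    assert np.allclose(out.pixels, [[0.0, 0.5], [1.0, 0.5]])


def test_normalize_identity_on_unit_range():
    arr = np.array([[0.0, 0.25], [0.75, 1.0]])
    out = normalize_intensity(gi(arr))
    assert np.allclose(out.pixels, arr)


def test_normalize_constant_rejected():
    with pytest.raises(ValueError, match="dynamic range"):
        normalize_intensity(gi(np.full((4, 4), 3.0)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(hnp.arrays(np.uint8, (8, 11), elements=st.integers(0, 255)))
def test_normalize_elementwise_oracle(arr):
    img = gi(arr.astype(float))
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        with pytest.raises(ValueError):
            normalize_intensity(img)
        return
    out = normalize_intensity(img)
    expect = np.empty_like(out.pixels)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            expect[i, j] = (arr[i, j] - lo) / (hi - lo)
    assert np.allclose(out.pixels, expect)


# -- homogenize --------------------------------------------------------------

def test_homogenize_instrument_frame():
    """256 x 1024 at (15.625, 31.25) um -> 512 x 1024 isotropic."""
    img = GrayImage(np.random.default_rng(0).random((256, 1024)),
                    px_mm_x=0.015625, px_mm_y=0.03125)
    out = homogenize_resolution(img)
    assert out.shape == (512, 1024)
    assert out.px_mm_x == out.px_mm_y == 0.015625
    # physical extent preserved to within one pixel
    assert abs(out.shape[0] * out.px_mm_y - 256 * 0.03125) <= out.px_mm_y


def test_homogenize_isotropic_unchanged():
    img = gi(np.arange(12.0).reshape(3, 4))
    out = homogenize_resolution(img)
    assert out.shape == (3, 4)
    assert np.allclose(out.pixels, img.pixels)


def test_homogenize_preserves_constants():
    img = GrayImage(np.full((10, 20), 0.7), px_mm_x=0.01, px_mm_y=0.03)
    out = homogenize_resolution(img)
    assert np.allclose(out.pixels, 0.7)


# -- median filter -----------------------------------------------------------

def test_median_constant_unchanged():
    img = gi(np.full((12, 12), 0.4), px=0.01)
    out = median_filter_mm(img, (0.03, 0.03))
    assert np.allclose(out.pixels, 0.4)


def test_median_removes_isolated_pixel():
    arr = np.zeros((9, 9))
    arr[4, 4] = 1.0
    out = median_filter_mm(gi(arr, px=0.01), (0.03, 0.03))  # 3x3 window
    assert np.all(out.pixels == 0.0)


def test_median_subpixel_window_is_identity():
    img = gi(np.random.default_rng(1).random((6, 6)), px=0.1)
    out = median_filter_mm(img, (0.01, 0.01))
    assert np.array_equal(out.pixels, img.pixels)


# -- anisotropic diffusion ---------------------------------------------------

def _diffusion_loop_oracle(u, n_iter, kappa, lam):
    """Direct-loop Perona-Malik update, replicated-edge boundaries."""
    u = u.copy()
    h, w = u.shape
    g = lambda d: np.exp(-((d / kappa) ** 2))
    for _ in range(n_iter):
        new = u.copy()
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    d = u[ii, jj] - u[i, j]
                    acc += g(d) * d
                new[i, j] = u[i, j] + lam * acc
        u = new
    return u


def test_diffusion_zero_iterations_is_identity(random_image):
    out = anisotropic_diffusion(random_image, n_iter=0)
    assert np.array_equal(out.pixels, random_image.pixels)


def test_diffusion_constant_is_fixed_point():
    img = gi(np.full((8, 8), 0.3))
    out = anisotropic_diffusion(img, n_iter=20, kappa=0.1, lam=0.25)
    assert np.allclose(out.pixels, 0.3)


def test_diffusion_rejects_unstable_step():
    with pytest.raises(ValueError):
        anisotropic_diffusion(gi(np.zeros((4, 4)) + 0.1), n_iter=1, lam=0.3)


def test_diffusion_matches_loop_oracle():
    rng = np.random.default_rng(3)
    arr = rng.random((16, 16))
    out = anisotropic_diffusion(gi(arr), n_iter=5, kappa=0.15, lam=0.2)
    expect = _diffusion_loop_oracle(arr, 5, 0.15, 0.2)
    assert np.allclose(out.pixels, expect, atol=1e-12)


def test_diffusion_preserves_edge_and_smooths_plateaus():
    """A step edge keeps its location (max |gradient|) while the flat
    regions lose variance."""
    rng = np.random.default_rng(4)
    arr = np.where(np.arange(40) < 20, 0.1, 0.9)[None, :].repeat(8, axis=0)
    arr = arr + 0.02 * rng.standard_normal(arr.shape)
    out = anisotropic_diffusion(gi(arr), n_iter=10, kappa=0.05, lam=0.25)
    grad_in = np.abs(np.diff(arr.mean(axis=0)))
    grad_out = np.abs(np.diff(out.pixels.mean(axis=0)))
    assert np.argmax(grad_out) == np.argmax(grad_in)
    for sl in (slice(0, 18), slice(22, 40)):
        assert out.pixels[:, sl].var() < arr[:, sl].var()
    # range containment
    assert out.pixels.min() >= arr.min() - 1e-12
    assert out.pixels.max() <= arr.max() + 1e-12


# -- moments -----------------------------------------------------------------

def test_moments_uniform_3x3():
    m = compute_moments(gi(np.ones((3, 3))))
    assert m.s == 9
    assert m.centroid == (1.0, 1.0)
    assert np.allclose(m.cov, (2.0 / 3.0) * np.eye(2))


def test_moments_single_pixel():
    arr = np.zeros((7, 9))
    arr[2, 5] = 3.0
    m = compute_moments(gi(arr))
    assert m.centroid == (2.0, 5.0)
    assert np.allclose(m.cov, 0.0)


def test_moments_zero_image_rejected():
    with pytest.raises(ValueError):
        compute_moments(gi(np.zeros((4, 4))))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(hnp.arrays(np.int64, (10, 10), elements=st.integers(0, 50)))
def test_moments_match_double_loop_oracle_exactly(arr):
    if arr.sum() == 0:
        return
    m = compute_moments(gi(arr.astype(float)))
    s = x = y = xx = yy = xy = 0.0
    for i in range(10):
        for j in range(10):
            v = float(arr[i, j])
            s += v
            x += j * v
            y += i * v
            xx += j * j * v
            yy += i * i * v
            xy += i * j * v
    assert (m.s, m.x, m.y, m.xx, m.yy, m.xy) == (s, x, y, xx, yy, xy)


# -- alignment ---------------------------------------------------------------

def _bar_image(h=40, w=60, theta_deg=0.0):
    """A bright bar through the center at the given angle."""
    i, j = np.mgrid[0:h, 0:w]
    ci, cj = (h - 1) / 2, (w - 1) / 2
    th = np.radians(theta_deg)
    # distance from the line through the center at angle theta
    d = np.abs(-(i - ci) * np.cos(th) + (j - cj) * np.sin(th))
    along = (i - ci) * np.sin(th) + (j - cj) * np.cos(th)
    arr = ((d <= 2.0) & (np.abs(along) <= 20)).astype(float)
    return gi(arr)


def test_align_horizontal_bar_is_centered_copy():
    img = _bar_image(theta_deg=0.0)
    out = align(img)
    assert out.shape == (80, 120)
    assert abs(out.rotation_deg) < 1.0
    m = compute_moments(GrayImage(out.canvas, out.px_mm, out.px_mm))
    ci, cj = (out.shape[0] - 1) / 2, (out.shape[1] - 1) / 2
    assert np.hypot(m.centroid[0] - ci, m.centroid[1] - cj) <= 1.0


def test_align_rotated_bar_matches_unrotated():
    a0 = align(_bar_image(theta_deg=0.0))
    a30 = align(_bar_image(theta_deg=30.0))
    r = np.corrcoef(a0.canvas.ravel(), a30.canvas.ravel())[0, 1]
    assert r >= 0.95


def test_align_canvas_untouched_pixels_zero():
    out = align(_bar_image(theta_deg=20.0))
    assert out.canvas[0, 0] == 0.0
    assert np.all(out.canvas >= 0.0)


def test_align_idempotent(small_params):
    a1 = preprocess_image(generate_phantom(small_params))
    a2 = align(GrayImage(a1.canvas, a1.px_mm, a1.px_mm))
    assert abs(a2.rotation_deg) <= 1.0
    m = compute_moments(GrayImage(a1.canvas, a1.px_mm, a1.px_mm))
    ci, cj = (a1.shape[0] - 1) / 2, (a1.shape[1] - 1) / 2
    assert np.hypot(m.centroid[0] - ci, m.centroid[1] - cj) <= 1.0


def test_align_degenerate_covariance_warns_identity():
    # radially symmetric blob: equal eigenvalues, rotation undefined
    i, j = np.mgrid[0:31, 0:31]
    arr = np.exp(-(((i - 15) ** 2 + (j - 15) ** 2) / 50.0))
    with pytest.warns(UserWarning, match="rotation undefined"):
        out = align(gi(arr))
    assert abs(out.rotation_deg) < 1e-9


def test_principal_axis_sign_convention():
    """v1 is reported with nonnegative horizontal component, so the image
    is never mirrored; a pure-vertical axis takes nonnegative i-component."""
    m = compute_moments(_bar_image(theta_deg=25.0))
    v1, deg = principal_axis(m)
    assert not deg and v1[1] > 0
    m_vert = compute_moments(gi(_bar_image(theta_deg=0.0).pixels.T))
    v1v, deg = principal_axis(m_vert)
    assert not deg and v1v[1] == pytest.approx(0.0, abs=1e-6) and v1v[0] > 0


def test_pose_invariance_of_full_chain(small_params):
    """Aligned canvas of a rotated + shifted phantom correlates >= 0.95
    with the aligned original."""
    p1 = replace(small_params, rotation_deg=14.0, shift_px=(4, -7))
    a0 = preprocess_image(generate_phantom(small_params))
    a1 = preprocess_image(generate_phantom(p1))
    r = np.corrcoef(a0.canvas.ravel(), a1.canvas.ravel())[0, 1]
    assert r >= 0.95
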