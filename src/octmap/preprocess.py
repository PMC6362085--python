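"""Image pre-processing: homogenization, filtering and moment-based alignment.

The chain, applied in this fixed order, is

1. intensity normalization to [0, 1] (affine rescale),
2. resolution homogenization (the instrument samples anisotropically;
   the coarser axis is upsampled to the finer spacing),
3. a rectangular median filter specified in physical units
   (default 0.055 mm x 0.117 mm),
4. Perona-Malik anisotropic diffusion (edge-preserving smoothing),
5. moment-based centering and principal-axis alignment into a canvas
   twice the source size.

Step 5 computes the intensity-weighted pixel moments

    S = sum M(i,j),  X = sum j M(i,j),  Y = sum i M(i,j),
    XX = sum j^2 M,  YY = sum i^2 M,    XY = sum i j M,

from which the centroid (Y/S, X/S) and the 2x2 covariance follow; the
eigenvector of the largest covariance eigenvalue is rotated onto the
horizontal axis and the centroid is moved to the canvas center, removing
the irrelevant pose variability (eye position and tilt inside the frame).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from .types import AlignedImage, GrayImage, ImageMoments

logger = logging.getLogger(__name__)

DEFAULT_MEDIAN_WINDOW_MM: tuple[float, float] = (0.055, 0.117)  # (height, width)


def normalize_intensity(img: GrayImage) -> GrayImage:
    """Linearly rescale intensities so that min -> 0 and max -> 1.

    Raises ``ValueError`` on a constant image (zero dynamic range).
    """
    p = img.pixels
    lo, hi = float(p.min()), float(p.max())
    if hi == lo:
        raise ValueError("constant image: zero dynamic range, cannot normalize")
    return GrayImage((p - lo) / (hi - lo), img.px_mm_x, img.px_mm_y, img.image_id)


def homogenize_resolution(img: GrayImage) -> GrayImage:
    """Resample to isotropic pixels at the finer of the two input spacings.

    The coarser axis is upsampled with bilinear interpolation; the physical
    extent is preserved to within one pixel. Already-isotropic images are
    returned with unchanged shape.
    """
    if img.px_mm_x <= 0 or img.px_mm_y <= 0:
        raise ValueError("pixel spacings must be positive")
    target = min(img.px_mm_x, img.px_mm_y)
    h, w = img.shape
    new_h = int(round(h * img.px_mm_y / target))
    new_w = int(round(w * img.px_mm_x / target))
    if (new_h, new_w) == (h, w):
        return GrayImage(img.pixels.copy(), target, target, img.image_id)
    out = resize(img.pixels, (new_h, new_w), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return GrayImage(out, target, target, img.image_id)


def _nearest_odd(x: float) -> int:
    """Nearest odd integer to x (>= 1)."""
    k = int(np.floor((x - 1.0) / 2.0)) * 2 + 1
    return max(1, k if abs(k - x) <= abs(k + 2 - x) else k + 2)


def median_filter_mm(img: GrayImage,
                     window_mm: tuple[float, float] = DEFAULT_MEDIAN_WINDOW_MM
                     ) -> GrayImage:
    """Rectangular median filter with the window given in mm (height, width).

    The window is converted to the nearest odd pixel count per axis; borders
    are handled by edge replication. A window below one pixel on both axes
    degrades to the identity with a warning.
    """
    if not img.is_isotropic:
        raise ValueError("median_filter_mm requires an isotropic image")
    size_i = _nearest_odd(window_mm[0] / img.px_mm_y)
    size_j = _nearest_odd(window_mm[1] / img.px_mm_x)
    if size_i == 1 and size_j == 1:
        logger.warning("median window %s mm is below one pixel; identity applied",
                       window_mm)
        return GrayImage(img.pixels.copy(), img.px_mm_x, img.px_mm_y, img.image_id)
    out = ndimage.median_filter(img.pixels, size=(size_i, size_j), mode="nearest")
    return GrayImage(out, img.px_mm_x, img.px_mm_y, img.image_id)


def anisotropic_diffusion(img: GrayImage, n_iter: int = 15, kappa: float = 0.1,
                          lam: float = 0.25) -> GrayImage:
    """Perona-Malik anisotropic diffusion (explicit scheme, 4-neighbor).

    Conduction ``g(grad) = exp(-(grad/kappa)^2)``; update
    ``u += lam * sum_d g(grad_d) * grad_d`` with zero-flux (replicated edge)
    boundaries. ``lam <= 0.25`` guarantees stability, so the output range
    stays within the input range. ``n_iter = 0`` returns the input unchanged.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if not 0.0 < lam <= 0.25:
        raise ValueError("lam must lie in (0, 0.25] for stability")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    u = img.pixels.copy()
    inv_k2 = 1.0 / (kappa * kappa)
    for _ in range(n_iter):
        p = np.pad(u, 1, mode="edge")
        d_n = p[:-2, 1:-1] - u
        d_s = p[2:, 1:-1] - u
        d_w = p[1:-1, :-2] - u
        d_e = p[1:-1, 2:] - u
        flux = sum(np.exp(-(d * d) * inv_k2) * d for d in (d_n, d_s, d_w, d_e))
        u = u + lam * flux
    return GrayImage(u, img.px_mm_x, img.px_mm_y, img.image_id)


def compute_moments(img: GrayImage | np.ndarray) -> ImageMoments:
    """Raw intensity moments S, X, Y, XX, YY, XY with 0-based pixel indices.

    Exact (up to float64 summation) on integer-valued images; raises on an
    all-zero image, for which the centroid is undefined.
    """
    m = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    s = float(m.sum())
    if s <= 0:
        raise ValueError("moments undefined: image has zero total mass")
    h, w = m.shape
    i = np.arange(h, dtype=float)
    j = np.arange(w, dtype=float)
    row = m.sum(axis=1)   # mass per row
    col = m.sum(axis=0)   # mass per column
    y = float(i @ row)
    x = float(j @ col)
    yy = float((i * i) @ row)
    xx = float((j * j) @ col)
    xy = float(i @ m @ j)
    return ImageMoments(s=s, x=x, y=y, xx=xx, yy=yy, xy=xy)


def principal_axis(moments: ImageMoments,
                   degenerate_tol: float = 1e-9) -> tuple[np.ndarray, bool]:
    """Unit eigenvector of the largest covariance eigenvalue, in (i, j) order.

    Sign convention: nonnegative j-component (so alignment never flips the
    image left-right); a purely vertical axis takes nonnegative i-component.
    Returns ``(v1, degenerate)``; for near-equal eigenvalues the rotation is
    undefined and ``degenerate=True`` with ``v1`` horizontal.
    """
    cov = moments.cov
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] <= degenerate_tol * max(abs(evals[1]), 1e-300):
        return np.array([0.0, 1.0]), True
    v1 = evecs[:, 1]
    if v1[1] < 0 or (v1[1] == 0 and v1[0] < 0):
        v1 = -v1
    return v1, False


def align(img: GrayImage) -> AlignedImage:
    """Center and principal-axis-align an image into a double-size canvas.

    The source is resampled (bilinear, zero fill) under the single affine
    map that rotates the principal eigenvector onto the horizontal axis
    about the source centroid and places the centroid at the canvas center.
    Pixels not covered by the source are exactly zero. If the covariance
    eigenvalues are equal within tolerance the rotation is undefined; the
    identity rotation is applied with a warning.
    """
    if not img.is_isotropic:
        raise ValueError("align requires an isotropic image")
    mom = compute_moments(img)
    v1, degenerate = principal_axis(mom)
    if degenerate:
        warnings.warn("covariance eigenvalues equal within tolerance; "
                      "rotation undefined, applying identity", stacklevel=2)
    theta = float(np.arctan2(v1[0], v1[1]))  # angle of v1 above horizontal
    h, w = img.shape
    ch, cw = 2 * h, 2 * w
    center = np.array([(ch - 1) / 2.0, (cw - 1) / 2.0])
    centroid = np.array(mom.centroid)
    # forward map: p = R(theta) (q - centroid) + center takes v1 to the
    # horizontal axis; affine_transform needs the inverse, q(p)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, s], [-s, c]])
    offset = centroid - rot @ center
    canvas = ndimage.affine_transform(img.pixels, rot, offset=offset,
                                      output_shape=(ch, cw), order=1,
                                      mode="constant", cval=0.0)
    np.clip(canvas, 0.0, None, out=canvas)
    return AlignedImage(canvas=canvas, px_mm=img.px_mm_x,
                        source_id=img.image_id, rotation_deg=np.degrees(theta))


def preprocess_image(img: GrayImage,
                     median_window_mm: tuple[float, float] = DEFAULT_MEDIAN_WINDOW_MM,
                     diffusion_n_iter: int = 15,
                     diffusion_kappa: float = 0.1,
                     diffusion_lam: float = 0.25) -> AlignedImage:
    """Full chain: normalize -> homogenize -> median -> diffusion -> align."""
    x = normalize_intensity(img)
    x = homogenize_resolution(x)
    x = median_filter_mm(x, median_window_mm)
    x = anisotropic_diffusion(x, diffusion_n_iter, diffusion_kappa, diffusion_lam)
    return align(x)


class ImagePreprocessor(TransformerMixin, BaseEstimator):
    """Stateless transformer applying the full pre-processing chain.

    Parameters
    ----------
    median_window_mm : (float, float)
        Median-filter window (height_mm, width_mm); default 0.055 x 0.117.
    diffusion_n_iter, diffusion_kappa, diffusion_lam : diffusion parameters
        on [0, 1] intensities.
    """

    def __init__(self, median_window_mm: tuple[float, float] = DEFAULT_MEDIAN_WINDOW_MM,
                 diffusion_n_iter: int = 15, diffusion_kappa: float = 0.1,
                 diffusion_lam: float = 0.25):
        self.median_window_mm = median_window_mm
        self.diffusion_n_iter = diffusion_n_iter
        self.diffusion_kappa = diffusion_kappa
        self.diffusion_lam = diffusion_lam

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X) -> list[AlignedImage]:
        return [preprocess_image(im, self.median_window_mm, self.diffusion_n_iter,
                                 self.diffusion_kappa, self.diffusion_lam)
                for im in X]
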