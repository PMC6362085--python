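"""Core containers shared across the pipeline stages.

All images are 2-D grayscale arrays indexed ``(i, j)`` with ``i`` counting
pixels down from the top edge and ``j`` pixels right from the left edge.
Physical pixel spacing is carried alongside the array because the OCT
instrument samples anisotropically (the default frame is 256 x 1024 px
covering 8 mm x 16 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class GrayImage:
    """A grayscale image with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray of shape (height, width)
        Nonnegative finite intensities.
    px_mm_x : float
        Horizontal spacing in mm per pixel (along ``j``).
    px_mm_y : float
        Vertical spacing in mm per pixel (along ``i``).
    image_id : str, optional
        Identifier carried through the pipeline.
    """

    pixels: np.ndarray
    px_mm_x: float
    px_mm_y: float
    image_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={self.pixels.ndim}")
        if self.px_mm_x <= 0 or self.px_mm_y <= 0:
            raise ValueError("pixel spacings must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def is_isotropic(self) -> bool:
        return np.isclose(self.px_mm_x, self.px_mm_y)


@dataclass
class ImageMoments:
    """Raw intensity moments of an image and derived centroid / covariance.

    ``s`` is the total mass; ``x``/``y`` are first moments in ``j``/``i``;
    ``xx``/``yy``/``xy`` the second moments. ``centroid`` is ``(i, j) =
    (y/s, x/s)`` and ``cov`` the 2x2 intensity-weighted pixel covariance
    with row/column order ``(i, j)``. Indices are 0-based.
    """

    s: float
    x: float
    y: float
    xx: float
    yy: float
    xy: float

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.y / self.s, self.x / self.s)

    @property
    def cov(self) -> np.ndarray:
        ci, cj = self.centroid
        var_i = self.yy / self.s - ci**2
        var_j = self.xx / self.s - cj**2
        cov_ij = self.xy / self.s - ci * cj
        return np.array([[var_i, cov_ij], [cov_ij, var_j]])


@dataclass
class AlignedImage:
    """The centered, principal-axis-aligned canvas of a source image.

    The canvas is twice the height and width of the source, the source
    centroid sits at the canvas center, and the principal eigenvector of
    the intensity covariance is horizontal. Pixels never covered by the
    resampled source are exactly zero. ``s`` is the total mass of the
    canvas, used to normalize the Hellinger distance.
    """

    canvas: np.ndarray
    px_mm: float
    source_id: str | None = None
    s: float = field(default=0.0)
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        self.canvas = np.asarray(self.canvas, dtype=float)
        if self.s == 0.0:
            self.s = float(self.canvas.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.canvas.shape


@dataclass
class DistanceMatrix:
    """Symmetric pairwise inter-image distance matrix ``D(l, m)``."""

    values: np.ndarray
    metric: str
    ids: list[str]
    n_pair_evaluations: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if len(self.ids) != n:
            raise ValueError("ids length must match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, rtol: float = 1e-8, atol: float = 1e-10) -> None:
        """Raise if the metric-axiom invariants are violated."""
        d = self.values
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(d < -atol):
            raise ValueError("distance matrix contains negative entries")
        if not np.allclose(d, d.T, rtol=rtol, atol=atol):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=atol):
            raise ValueError("distance matrix diagonal is not zero")
        if self.metric == "hellinger" and np.any(d > 2.0 + 1e-8):
            raise ValueError("hellinger distances must not exceed 2")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, metric: str) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float), metric=metric,
                   ids=[str(c) for c in df.columns])


@dataclass
class Embedding2D:
    """2-D mapped coordinates ``(w, v)`` of a set of images."""

    coords: np.ndarray
    method: str
    params: dict
    ids: list[str]
    geodesic_distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D (n_images, n_dims)")
        if len(self.ids) != self.coords.shape[0]:
            raise ValueError("ids length must match number of coordinate rows")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"id": self.ids,
                           "w": self.coords[:, 0],
                           "v": self.coords[:, 1]})
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, method: str = "loaded",
                 params: dict | None = None) -> "Embedding2D":
        df = pd.read_csv(path)
        coords = df[["w", "v"]].to_numpy(dtype=float)
        return cls(coords=coords, method=method, params=params or {},
                   ids=[str(i) for i in df["id"]])


def as_ids(images: Sequence, prefix: str = "img") -> list[str]:
    """Identifiers for a sequence of images, falling back to positional names."""
    out = []
    for k, im in enumerate(images):
        iid = getattr(im, "image_id", None) or getattr(im, "source_id", None)
        out.append(str(iid) if iid is not None else f"{prefix}_{k:04d}")
    return out
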