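"""Evaluation of an embedding: Image Map montage, best-correlating
direction in the (w, v) plane, and class-label overlays.

The direction statistic quantifies how well a scalar feature (chamber
depth, mean iridocorneal angle, an ordinal class label) is captured by
the unsupervised map: among all unit directions u(theta) in the mapped
plane it finds the one maximizing |Pearson r| between the projection
coords . u and the feature. The maximized |r| equals the multiple
correlation coefficient sqrt(R^2) of the least-squares regression of the
feature on the two centered coordinates, which gives a closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .types import AlignedImage, Embedding2D


@dataclass
class DirectionCorrelation:
    """Best-correlating direction for one feature: angle ``theta`` in
    [0, pi) radians and the signed Pearson r of the projection there."""

    theta: float
    r: float
    feature_name: str = ""


def best_correlation_direction(emb: Embedding2D | np.ndarray,
                               feature: np.ndarray,
                               feature_name: str = "") -> DirectionCorrelation:
    """Direction in the mapped plane maximizing |corr(projection, feature)|.

    Pairs with missing (NaN) feature values are dropped. The closed form:
    with centered coordinates Z and centered feature f, the least-squares
    coefficients b = argmin |Z b - f| point along the optimal direction and
    the correlation there is sqrt(R^2), up to sign.
    """
    coords = emb.coords if isinstance(emb, Embedding2D) else np.asarray(emb, float)
    f = np.asarray(feature, dtype=float)
    if coords.shape[0] != f.shape[0]:
        raise ValueError("feature length must match number of embedded points")
    keep = np.isfinite(f) & np.all(np.isfinite(coords), axis=1)
    coords, f = coords[keep], f[keep]
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points with finite feature values")
    if np.ptp(f) == 0:
        raise ValueError("constant feature: correlation undefined")
    z = coords - coords.mean(axis=0)
    fc = f - f.mean()
    beta, *_ = np.linalg.lstsq(z, fc, rcond=None)
    norm = np.linalg.norm(beta)
    if norm == 0:
        return DirectionCorrelation(theta=0.0, r=0.0, feature_name=feature_name)
    u = beta / norm
    theta = math.atan2(u[1], u[0])
    if theta < 0:
        theta += math.pi
        u = -u
    proj = z @ u
    r = float(np.corrcoef(proj, fc)[0, 1])
    return DirectionCorrelation(theta=float(theta), r=r, feature_name=feature_name)


@dataclass
class ImageMapGrid:
    """A regular grid over the mapped plane with at most one image per cell."""

    grid_shape: tuple[int, int]
    cell_assignments: dict            # (row, col) -> image id
    montage: np.ndarray | None = None


def _grid_points(coords: np.ndarray, grid_shape: tuple[int, int]):
    rows, cols = grid_shape
    w_lo, w_hi = coords[:, 0].min(), coords[:, 0].max()
    v_lo, v_hi = coords[:, 1].min(), coords[:, 1].max()
    # a zero-span axis (all points identical there) gets a unit-span pad so
    # the degenerate cluster still lands on one grid point
    if w_hi == w_lo:
        w_lo, w_hi = w_lo - 0.5, w_hi + 0.5
    if v_hi == v_lo:
        v_lo, v_hi = v_lo - 0.5, v_hi + 0.5
    ws = np.linspace(w_lo, w_hi, cols)
    vs = np.linspace(v_hi, v_lo, rows)   # top row = largest v, like a plot
    dw = ws[1] - ws[0]
    dv = abs(vs[1] - vs[0])
    return ws, vs, max(dw, dv)


def assign_grid_cells(emb: Embedding2D, grid_shape: tuple[int, int]) -> dict:
    """Greedy unique nearest assignment of images to grid points.

    All (cell, image) pairs are ranked by Euclidean distance in the mapped
    plane (ties broken by id order); a cell takes the closest unused image
    within half a grid spacing, and an image appears in at most one cell.
    """
    rows, cols = grid_shape
    if rows < 2 or cols < 2:
        raise ValueError("grid_shape must be at least (2, 2)")
    coords = emb.coords
    if not np.all(np.isfinite(coords)):
        raise ValueError("degenerate coordinates: non-finite values")
    ws, vs, spacing = _grid_points(coords, grid_shape)
    cutoff = 0.5 * spacing
    pairs = []
    for r in range(rows):
        for c in range(cols):
            gp = np.array([ws[c], vs[r]])
            d = np.hypot(coords[:, 0] - gp[0], coords[:, 1] - gp[1])
            for k in np.where(d <= cutoff)[0]:
                pairs.append((d[k], k, r, c))
    pairs.sort(key=lambda t: (t[0], t[1]))
    taken_cells: set[tuple[int, int]] = set()
    taken_imgs: set[int] = set()
    assignment: dict[tuple[int, int], str] = {}
    for d, k, r, c in pairs:
        if (r, c) in taken_cells or k in taken_imgs:
            continue
        assignment[(r, c)] = emb.ids[k]
        taken_cells.add((r, c))
        taken_imgs.add(k)
    return assignment


def render_image_map(emb: Embedding2D, images: list[AlignedImage],
                     grid_shape: tuple[int, int],
                     cell_px: tuple[int, int] = (64, 128)) -> ImageMapGrid:
    """Compose the Image Map montage: one thumbnail per occupied grid cell."""
    assignment = assign_grid_cells(emb, grid_shape)
    by_id = {}
    for k, im in enumerate(images):
        iid = im.source_id if im.source_id is not None else emb.ids[k]
        by_id[str(iid)] = im.canvas
    rows, cols = grid_shape
    ch, cw = cell_px
    montage = np.zeros((rows * ch, cols * cw))
    for (r, c), iid in assignment.items():
        if iid not in by_id:
            continue
        thumb = resize(by_id[iid], (ch, cw), order=1, mode="edge",
                       anti_aliasing=True, preserve_range=True)
        montage[r * ch:(r + 1) * ch, c * cw:(c + 1) * cw] = thumb
    return ImageMapGrid(grid_shape=grid_shape, cell_assignments=assignment,
                        montage=montage)


def label_overlay(emb: Embedding2D, labels: dict[str, object]) -> dict:
    """Scatter data of the mapped plane colored by class.

    Returns plain arrays ready for plotting: ``w``, ``v``, per-point
    ``label`` (None where unlabeled -> gray), the ordered ``classes`` and a
    per-point ``color`` from the matplotlib tab10 cycle.
    """
    classes = sorted({str(v) for v in labels.values()})
    palette = ["tab:blue", "tab:orange", "tab:green", "tab:red", "tab:purple",
               "tab:brown", "tab:pink", "tab:olive", "tab:cyan"]
    color_of = {c: palette[i % len(palette)] for i, c in enumerate(classes)}
    point_labels, colors = [], []
    for iid in emb.ids:
        lab = labels.get(iid)
        lab = None if lab is None else str(lab)
        point_labels.append(lab)
        colors.append("gray" if lab is None else color_of[lab])
    return {"w": emb.coords[:, 0].copy(), "v": emb.coords[:, 1].copy(),
            "label": point_labels, "classes": classes, "color": colors}


def plot_label_overlay(emb: Embedding2D, labels: dict[str, object], ax=None):
    """Matplotlib scatter of the label overlay; returns the axes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    data = label_overlay(emb, labels)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(data["w"], data["v"], c=data["color"], s=12)
    ax.set_xlabel("w")
    ax.set_ylabel("v")
    return ax
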