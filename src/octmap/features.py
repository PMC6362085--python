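"""Clinical features from manually annotated landmarks.

The landmarks mirror standard anterior-segment goniometry practice: on
each side the scleral spur plus a second point on the inner corneal edge
define a line approximating the cornea; two points on the iris top edge
define the iris line. Centrally, points on the inner and outer cornea and
the lens apex are annotated. From these the package derives

* ``L`` — anterior chamber depth, the distance from the central inner
  cornea to the lens apex (mm);
* ``alpha``, ``beta`` — the iridocorneal angles, the acute angle between
  the cornea and iris lines on each side (degrees);
* ``ARA_500`` — the angle-recess area, approximated with both edges as
  lines: the triangle spanned by the recess apex A (line intersection),
  the point P on the cornea line 0.5 mm from the scleral spur away from
  the apex, and the foot Q of the perpendicular from P onto the iris
  line (mm^2).

Angles and L are exactly rigid-motion invariant; ARA scales with the
square of a uniform scaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ARA_OFFSET_MM = 0.5


@dataclass
class SideLandmarks:
    """Landmarks of one side (left or right) of the angle recess."""

    scleral_spur: tuple[float, float]
    cornea_inner_aux: tuple[float, float]
    iris_pts: tuple[tuple[float, float], tuple[float, float]]

    def validate(self) -> None:
        pts = [self.scleral_spur, self.cornea_inner_aux, *self.iris_pts]
        arr = np.asarray(pts, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("landmark coordinates must be finite")
        if np.allclose(self.scleral_spur, self.cornea_inner_aux):
            raise ValueError("cornea_inner_aux must differ from scleral_spur")
        if np.allclose(self.iris_pts[0], self.iris_pts[1]):
            raise ValueError("the two iris points must be distinct")


@dataclass
class LandmarkSet:
    """Full annotation of one image: per-side recess landmarks plus the
    central cornea (inner/outer) and lens-apex points, all (x, y) in mm in
    the image frame (y increasing downward)."""

    cornea_inner: tuple[float, float]
    cornea_outer: tuple[float, float]
    lens_top: tuple[float, float]
    left: SideLandmarks | None = None
    right: SideLandmarks | None = None
    image_id: str | None = None


@dataclass
class AnnotationFeatures:
    """Derived clinical features; absent sides yield NaN, never 0."""

    L: float
    alpha: float          # left-side angle, degrees
    beta: float           # right-side angle, degrees
    mean_angle: float
    ara500_left: float
    ara500_right: float
    ara500_min: float
    image_id: str | None = None


def chamber_depth(lm: LandmarkSet) -> float:
    """Anterior chamber depth: |central inner cornea - lens apex| in mm."""
    if lm.cornea_inner is None or lm.lens_top is None:
        raise ValueError("chamber depth needs cornea_inner and lens_top")
    return float(math.hypot(lm.lens_top[0] - lm.cornea_inner[0],
                            lm.lens_top[1] - lm.cornea_inner[1]))


def _line_dirs(side: SideLandmarks) -> tuple[np.ndarray, np.ndarray]:
    side.validate()
    dc = np.asarray(side.cornea_inner_aux, float) - np.asarray(side.scleral_spur, float)
    di = np.asarray(side.iris_pts[1], float) - np.asarray(side.iris_pts[0], float)
    return dc / np.linalg.norm(dc), di / np.linalg.norm(di)


def iris_corneal_angle(side: SideLandmarks) -> float:
    """Acute angle (degrees) between the cornea and iris edge lines."""
    dc, di = _line_dirs(side)
    c = float(np.clip(abs(np.dot(dc, di)), 0.0, 1.0))
    return math.degrees(math.acos(c))


def _line_intersection(p0: np.ndarray, d0: np.ndarray,
                       p1: np.ndarray, d1: np.ndarray) -> np.ndarray | None:
    """Intersection of lines p0 + t d0 and p1 + s d1; None if parallel."""
    det = d0[0] * d1[1] - d0[1] * d1[0]
    if abs(det) < 1e-12:
        return None
    rhs = p1 - p0
    t = (rhs[0] * d1[1] - rhs[1] * d1[0]) / det
    return p0 + t * d0


def ara500(side: SideLandmarks, offset_mm: float = ARA_OFFSET_MM) -> float:
    """Angle-recess area (mm^2) of the triangle (A, P, Q); see module doc.

    P sits on the cornea line ``offset_mm`` from the scleral spur on the
    side away from the apex A (for a spur coincident with A, toward the
    open chamber, i.e. the side where the iris points lie).
    """
    dc, di = _line_dirs(side)
    spur = np.asarray(side.scleral_spur, float)
    iris0 = np.asarray(side.iris_pts[0], float)
    apex = _line_intersection(spur, dc, iris0, di)
    if apex is None:
        raise ValueError("edge lines are parallel: angle recess apex undefined")
    away = spur - apex
    if np.linalg.norm(away) > 1e-12:
        u = dc if np.dot(dc, away) > 0 else -dc
    else:
        toward_iris = 0.5 * (iris0 + np.asarray(side.iris_pts[1], float)) - apex
        u = dc if np.dot(dc, toward_iris) >= 0 else -dc
    p = spur + offset_mm * u
    # foot of perpendicular from P onto the iris line
    q = apex + np.dot(p - apex, di) * di
    x1, y1 = p - apex
    x2, y2 = q - apex
    return float(0.5 * abs(x1 * y2 - x2 * y1))


def features_from_landmarks(lm: LandmarkSet) -> AnnotationFeatures:
    """Assemble L, alpha, beta, mean angle and per-side / minimum ARA_500.

    A missing side yields NaN for its angle and area; the mean angle and
    minimum area are taken over the sides present. Both sides absent is an
    error.
    """
    if lm.left is None and lm.right is None:
        raise ValueError("at least one side of landmarks is required")
    depth = chamber_depth(lm)
    alpha = iris_corneal_angle(lm.left) if lm.left is not None else float("nan")
    beta = iris_corneal_angle(lm.right) if lm.right is not None else float("nan")
    ara_l = ara500(lm.left) if lm.left is not None else float("nan")
    ara_r = ara500(lm.right) if lm.right is not None else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_angle = float(np.nanmean([alpha, beta]))
        ara_min = float(np.nanmin([ara_l, ara_r]))
    return AnnotationFeatures(L=depth, alpha=alpha, beta=beta,
                              mean_angle=mean_angle, ara500_left=ara_l,
                              ara500_right=ara_r, ara500_min=ara_min,
                              image_id=lm.image_id)


# ---------------------------------------------------------------------------
# landmark CSV I/O: rows of (image_id, landmark_name, side, x_mm, y_mm)

_SIDE_NAMES = ("scleral_spur", "cornea_inner_aux", "iris_1", "iris_2")
_CENTER_NAMES = ("cornea_inner", "cornea_outer", "lens_top")


def landmarks_to_frame(sets: list[LandmarkSet]) -> pd.DataFrame:
    rows = []
    for lm in sets:
        for name in _CENTER_NAMES:
            x, y = getattr(lm, name)
            rows.append((lm.image_id, name, "center", x, y))
        for side_name in ("left", "right"):
            side = getattr(lm, side_name)
            if side is None:
                continue
            pts = {"scleral_spur": side.scleral_spur,
                   "cornea_inner_aux": side.cornea_inner_aux,
                   "iris_1": side.iris_pts[0], "iris_2": side.iris_pts[1]}
            for name, (x, y) in pts.items():
                rows.append((lm.image_id, name, side_name, x, y))
    return pd.DataFrame(rows, columns=["image_id", "landmark_name", "side",
                                       "x_mm", "y_mm"])


def landmarks_from_frame(df: pd.DataFrame) -> list[LandmarkSet]:
    out = []
    for image_id, grp in df.groupby("image_id", sort=True):
        pts = {(r.landmark_name, r.side): (float(r.x_mm), float(r.y_mm))
               for r in grp.itertuples()}
        sides = {}
        for side_name in ("left", "right"):
            if ("scleral_spur", side_name) in pts:
                sides[side_name] = SideLandmarks(
                    scleral_spur=pts[("scleral_spur", side_name)],
                    cornea_inner_aux=pts[("cornea_inner_aux", side_name)],
                    iris_pts=(pts[("iris_1", side_name)],
                              pts[("iris_2", side_name)]))
        out.append(LandmarkSet(
            cornea_inner=pts[("cornea_inner", "center")],
            cornea_outer=pts[("cornea_outer", "center")],
            lens_top=pts[("lens_top", "center")],
            left=sides.get("left"), right=sides.get("right"),
            image_id=str(image_id)))
    return out


def features_table(sets: list[LandmarkSet]) -> pd.DataFrame:
    """One row of derived features per annotated image."""
    rows = []
    for lm in sets:
        f = features_from_landmarks(lm)
        rows.append({"image_id": f.image_id, "L_mm": f.L, "alpha_deg": f.alpha,
                     "beta_deg": f.beta, "mean_angle_deg": f.mean_angle,
                     "ara500_left_mm2": f.ara500_left,
                     "ara500_right_mm2": f.ara500_right,
                     "ara500_min_mm2": f.ara500_min})
    return pd.DataFrame(rows)
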