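"""Synthetic anterior-chamber OCT phantoms with known ground truth.

A phantom emulates the structures seen in an anterior-segment B-scan: a
bright corneal band (two concentric arcs), left and right iris bands whose
top edges meet the inner corneal edge at a controllable apex angle (the
iridocorneal angle), and a lens arc whose apex sits at a controllable
chamber depth below the central inner cornea. Multiplicative lognormal
speckle and an additive uniform background emulate OCT noise.

All geometry is defined analytically in physical (mm) coordinates; the
whole-eye pose (in-plane rotation about the image center plus an integer
pixel shift) is applied to the analytic geometry itself, so the stored
edge-line parameters remain exact ground truth for the rendered image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .types import GrayImage

# Fixed anatomy of the phantom eye (mm); chosen to resemble adult anterior
# segment dimensions on the instrument's 16 mm x 8 mm field of view.
CORNEA_RADIUS_MM = 7.0          # inner corneal curvature radius
CORNEA_THICKNESS_MM = 0.6
CORNEA_APEX_Y_MM = 2.2          # inner corneal apex depth from the top edge
RECESS_HALF_WIDTH_MM = 5.5      # horizontal offset of each angle recess
IRIS_THICKNESS_MM = 0.35
PUPIL_RADIUS_MM = 1.5
LENS_RADIUS_MM = 9.0
LENS_THICKNESS_MM = 0.3
LENS_HALF_WIDTH_MM = 3.0

# Band intensities: distinct but overlapping distributions.
CORNEA_INTENSITY = 0.9
IRIS_INTENSITY = 0.7
LENS_INTENSITY = 0.5


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one synthetic phantom.

    The default canvas mirrors the Visante instrument frame: 256 x 1024 px
    covering 8 mm x 16 mm, i.e. 31.25 um vertical x 15.625 um horizontal
    pixels. ``iridocorneal_angle_deg`` is the apex angle between the inner
    corneal edge and the iris top edge on each side; ``chamber_depth_mm``
    the distance from the central inner cornea to the lens apex.
    """

    width_px: int = 1024
    height_px: int = 256
    px_mm_x: float = 16.0 / 1024
    px_mm_y: float = 8.0 / 256
    iridocorneal_angle_deg: float = 35.0
    chamber_depth_mm: float = 3.0
    rotation_deg: float = 0.0
    shift_px: tuple[int, int] = (0, 0)   # (di, dj)
    speckle_sigma: float = 0.2
    background_level: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.px_mm_x <= 0 or self.px_mm_y <= 0:
            raise ValueError("pixel spacings must be positive")
        if not 0.0 < self.iridocorneal_angle_deg < 90.0:
            raise ValueError("iridocorneal_angle_deg must lie in (0, 90)")
        if self.chamber_depth_mm <= 0:
            raise ValueError("chamber_depth_mm must be positive")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be nonnegative")
        if not 0.0 <= self.background_level < 1.0:
            raise ValueError("background_level must lie in [0, 1)")


@dataclass(frozen=True)
class PhantomGeometry:
    """Analytic edge-line / arc parameters of a rendered phantom, in the
    rendered (posed) mm frame. These are the ground-truth oracle against
    which measured angles and depths are checked."""

    apex_left: np.ndarray            # angle-recess apex (x, y) mm
    apex_right: np.ndarray
    cornea_dir_left: np.ndarray      # unit tangent of the inner cornea at the apex,
    cornea_dir_right: np.ndarray     # pointing inward toward the dome apex
    iris_dir_left: np.ndarray        # unit direction of the iris top edge at the apex,
    iris_dir_right: np.ndarray       # pointing inward toward the pupil
    cornea_inner_center: np.ndarray  # central inner cornea (x, y) mm
    cornea_outer_center: np.ndarray
    lens_apex: np.ndarray

    def measured_angle_deg(self, side: str) -> float:
        """Apex angle between cornea and iris edge lines, from the stored
        directions (independent of the rasterization)."""
        uc = self.cornea_dir_left if side == "left" else self.cornea_dir_right
        ui = self.iris_dir_left if side == "left" else self.iris_dir_right
        c = float(np.clip(np.dot(uc, ui), -1.0, 1.0))
        return math.degrees(math.acos(c))

    def measured_depth_mm(self) -> float:
        return float(np.linalg.norm(self.lens_apex - self.cornea_inner_center))


def _rot2(deg: float) -> np.ndarray:
    th = math.radians(deg)
    return np.array([[math.cos(th), -math.sin(th)],
                     [math.sin(th), math.cos(th)]])


def _unposed_geometry(params: PhantomParams) -> dict:
    """Geometry in the unrotated, unshifted frame (x right, y down, mm)."""
    cx = params.width_px * params.px_mm_x / 2.0
    r_in = CORNEA_RADIUS_MM
    cy0 = CORNEA_APEX_Y_MM + r_in          # cornea circle center (below apex)
    x_a = RECESS_HALF_WIDTH_MM
    y_a = cy0 - math.sqrt(r_in**2 - x_a**2)

    geo: dict = {
        "cornea_center": np.array([cx, cy0]),
        "r_in": r_in,
        "r_out": r_in + CORNEA_THICKNESS_MM,
        "x_a": x_a,
    }

    for side, sx in (("left", -1.0), ("right", 1.0)):
        apex = np.array([cx + sx * x_a, y_a])
        # tangent to the inner corneal circle at the apex, oriented inward
        radial = apex - geo["cornea_center"]
        tangent = np.array([-radial[1], radial[0]])
        tangent /= np.linalg.norm(tangent)
        if tangent[0] * sx > 0:            # make x-component point toward center
            tangent = -tangent
        # iris top edge: cornea tangent rotated by the apex angle, opening
        # downward into the chamber
        cand_a = _rot2(params.iridocorneal_angle_deg) @ tangent
        cand_b = _rot2(-params.iridocorneal_angle_deg) @ tangent
        iris_dir = cand_a if cand_a[1] > cand_b[1] else cand_b
        geo[f"apex_{side}"] = apex
        geo[f"cornea_dir_{side}"] = tangent
        geo[f"iris_dir_{side}"] = iris_dir

    y_ci = CORNEA_APEX_Y_MM
    geo["cornea_inner_center"] = np.array([cx, y_ci])
    geo["cornea_outer_center"] = np.array([cx, y_ci - CORNEA_THICKNESS_MM])
    geo["lens_apex"] = np.array([cx, y_ci + params.chamber_depth_mm])
    geo["lens_center"] = np.array([cx, y_ci + params.chamber_depth_mm + LENS_RADIUS_MM])
    return geo


def _pose_transform(params: PhantomParams):
    """Forward rigid pose: geometry frame -> rendered frame (both mm)."""
    cx = params.width_px * params.px_mm_x / 2.0
    cy = params.height_px * params.px_mm_y / 2.0
    center = np.array([cx, cy])
    rot = _rot2(params.rotation_deg)
    di, dj = params.shift_px
    shift = np.array([dj * params.px_mm_x, di * params.px_mm_y])

    def fwd(p: np.ndarray) -> np.ndarray:
        return rot @ (p - center) + center + shift

    return fwd, rot, center, shift


def geometry_mask_and_image(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the noiseless phantom.

    Returns ``(image, mask)`` where ``mask`` is the boolean union of the
    anatomical bands and ``image`` carries the band intensities (cornea
    0.9 > iris 0.7 > lens 0.5; overlaps take the maximum).
    """
    params.validate()
    geo = _unposed_geometry(params)
    _, rot, center, shift = _pose_transform(params)

    jj, ii = np.meshgrid(np.arange(params.width_px), np.arange(params.height_px))
    px = (jj + 0.5) * params.px_mm_x
    py = (ii + 0.5) * params.px_mm_y
    # invert the pose: rendered pixel centers -> geometry frame
    qx = px - center[0] - shift[0]
    qy = py - center[1] - shift[1]
    gx = rot[0, 0] * qx + rot[1, 0] * qy + center[0]
    gy = rot[0, 1] * qx + rot[1, 1] * qy + center[1]

    img = np.zeros((params.height_px, params.width_px))

    # cornea: annulus between the two arcs, upper half, clipped at the recesses
    cc = geo["cornea_center"]
    rad = np.hypot(gx - cc[0], gy - cc[1])
    cornea = ((rad >= geo["r_in"]) & (rad <= geo["r_out"]) & (gy < cc[1])
              & (np.abs(gx - cc[0]) <= geo["x_a"]))
    np.maximum(img, np.where(cornea, CORNEA_INTENSITY, 0.0), out=img)

    # iris bands: strip of fixed thickness below the top-edge line, from the
    # recess apex inward to the pupil margin
    cx_mm = cc[0]
    for side, sx in (("left", -1.0), ("right", 1.0)):
        apex = geo[f"apex_{side}"]
        u = geo[f"iris_dir_{side}"]
        normal = np.array([-u[1], u[0]])
        if normal[1] < 0:
            normal = -normal                 # point into the iris (downward)
        dxp = gx - apex[0]
        dyp = gy - apex[1]
        perp = dxp * normal[0] + dyp * normal[1]
        in_strip = (perp >= 0.0) & (perp <= IRIS_THICKNESS_MM)
        lateral = sx * (gx - cx_mm)
        in_span = (lateral >= PUPIL_RADIUS_MM) & (lateral <= RECESS_HALF_WIDTH_MM)
        np.maximum(img, np.where(in_strip & in_span, IRIS_INTENSITY, 0.0), out=img)

    # lens: upper arc band visible through the pupil
    lc = geo["lens_center"]
    rad_l = np.hypot(gx - lc[0], gy - lc[1])
    lens = ((rad_l >= LENS_RADIUS_MM) & (rad_l <= LENS_RADIUS_MM + LENS_THICKNESS_MM)
            & (gy < lc[1]) & (np.abs(gx - lc[0]) <= LENS_HALF_WIDTH_MM))
    np.maximum(img, np.where(lens, LENS_INTENSITY, 0.0), out=img)

    return img, img > 0


def phantom_geometry(params: PhantomParams) -> PhantomGeometry:
    """Ground-truth geometry of the rendered phantom (pose applied)."""
    params.validate()
    geo = _unposed_geometry(params)
    fwd, rot, _, _ = _pose_transform(params)
    return PhantomGeometry(
        apex_left=fwd(geo["apex_left"]),
        apex_right=fwd(geo["apex_right"]),
        cornea_dir_left=rot @ geo["cornea_dir_left"],
        cornea_dir_right=rot @ geo["cornea_dir_right"],
        iris_dir_left=rot @ geo["iris_dir_left"],
        iris_dir_right=rot @ geo["iris_dir_right"],
        cornea_inner_center=fwd(geo["cornea_inner_center"]),
        cornea_outer_center=fwd(geo["cornea_outer_center"]),
        lens_apex=fwd(geo["lens_apex"]),
    )


def generate_phantom(params: PhantomParams) -> GrayImage:
    """Render a phantom with speckle and background noise.

    Noise model: each signal pixel is multiplied by a lognormal factor
    ``exp(sigma * Z)``, ``Z ~ N(0, 1)`` (a simple stand-in for coherent
    speckle), then a per-pixel additive background uniform in
    ``[0, background_level)`` is added and the result clipped to [0, 1].
    Same seed and parameters give a bit-identical image.
    """
    params.validate()
    img, _ = geometry_mask_and_image(params)
    rng = np.random.default_rng(params.seed)
    if params.speckle_sigma > 0:
        z = rng.standard_normal(img.shape)
        img = img * np.exp(params.speckle_sigma * z)
    if params.background_level > 0:
        img = img + rng.uniform(0.0, params.background_level, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return GrayImage(pixels=img, px_mm_x=params.px_mm_x, px_mm_y=params.px_mm_y,
                     image_id=f"phantom_seed{params.seed}")


def landmarks_from_phantom(params: PhantomParams,
                           image_id: str | None = None) -> "LandmarkSet":
    """Analytic landmark annotation of a phantom, in the rendered mm frame.

    Emulates an expert annotation with zero placement error: the scleral
    spur sits at the angle-recess apex, the auxiliary cornea point 0.4 mm
    along the corneal edge line, and the two iris points 0.5 mm and 1.5 mm
    along the iris top edge.
    """
    from .features import LandmarkSet, SideLandmarks

    g = phantom_geometry(params)
    sides = {}
    for side in ("left", "right"):
        apex = getattr(g, f"apex_{side}")
        uc = getattr(g, f"cornea_dir_{side}")
        ui = getattr(g, f"iris_dir_{side}")
        sides[side] = SideLandmarks(
            scleral_spur=tuple(apex),
            cornea_inner_aux=tuple(apex + 0.4 * uc),
            iris_pts=(tuple(apex + 0.5 * ui), tuple(apex + 1.5 * ui)))
    return LandmarkSet(cornea_inner=tuple(g.cornea_inner_center),
                       cornea_outer=tuple(g.cornea_outer_center),
                       lens_top=tuple(g.lens_apex),
                       left=sides["left"], right=sides["right"],
                       image_id=image_id or f"phantom_seed{params.seed}")


@dataclass(frozen=True)
class PoseJitter:
    """Pose randomization spec for cohorts: rotation uniform in
    ``[-max_rotation_deg, +max_rotation_deg]``, integer shifts uniform in
    ``[-max_shift_px, +max_shift_px]`` per axis."""

    max_rotation_deg: float = 5.0
    max_shift_px: int = 10


def generate_cohort(
    n: int,
    angle_range: tuple[float, float] = (10.0, 70.0),
    depth_range: tuple[float, float] = (2.0, 4.0),
    pose_jitter: PoseJitter = PoseJitter(),
    seed: int = 0,
    base_params: PhantomParams = PhantomParams(),
) -> list[tuple[GrayImage, PhantomParams]]:
    """Generate ``n`` phantoms with angle and depth sampled uniformly.

    Child seeds are derived deterministically from ``seed`` via
    ``numpy.random.SeedSequence``, so a fixed seed reproduces the cohort
    bit-exactly. Ground-truth parameters are returned with each image.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not angle_range[0] < angle_range[1]:
        raise ValueError("angle_range must be nondegenerate (lo < hi)")
    if not depth_range[0] < depth_range[1]:
        raise ValueError("depth_range must be nondegenerate (lo < hi)")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    out = []
    for k in range(n):
        angle = float(rng.uniform(*angle_range))
        depth = float(rng.uniform(*depth_range))
        rot = float(rng.uniform(-pose_jitter.max_rotation_deg,
                                pose_jitter.max_rotation_deg))
        di = int(rng.integers(-pose_jitter.max_shift_px,
                              pose_jitter.max_shift_px + 1))
        dj = int(rng.integers(-pose_jitter.max_shift_px,
                              pose_jitter.max_shift_px + 1))
        p = replace(base_params, iridocorneal_angle_deg=angle,
                    chamber_depth_mm=depth, rotation_deg=rot,
                    shift_px=(di, dj), seed=int(child_seeds[k]))
        img = generate_phantom(p)
        img.image_id = f"phantom_{k:04d}"
        out.append((img, p))
    return out
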