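"""Camera models, epipolar geometry, triangulation and rigid transforms.

All 3D quantities are in millimetres.  Pixel coordinates are 0-based with the
origin at the top-left corner, x pointing right and y pointing down.  A
:class:`RigidTransform` maps points from a source frame into a target frame
(``x_target = R @ x_source + t``); for camera poses the transform maps world
coordinates into the camera frame.

The camera follows the standard pinhole model with radial (k1, k2) and
tangential (p1, p2) polynomial lens distortion applied to normalized image
coordinates:

    x_d = x (1 + k1 r^2 + k2 r^4) + 2 p1 x y + p2 (r^2 + 2 x^2)
    y_d = y (1 + k1 r^2 + k2 r^4) + p1 (r^2 + 2 y^2) + 2 p2 x y

with r^2 = x^2 + y^2, and pixel coordinates u = fx x_d + skew y_d + cx,
v = fy y_d + cy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import (
    ConfigError,
    DegenerateGeometryError,
    DegenerateRigError,
    DistortionInversionError,
    NonProjectablePointError,
    NonTriangulablePairError,
)

__all__ = [
    "CameraModel",
    "RigidTransform",
    "StereoRig",
    "project",
    "undistort",
    "undistorted_pixels",
    "fundamental_matrix",
    "triangulate",
    "estimate_rigid",
    "load_calibration",
    "save_calibration",
]

_ORTHO_TOL = 1e-6


def _as_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ConfigError(f"rotation must be 3x3, got shape {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ConfigError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ConfigError("rotation matrix has determinant -1 (reflection)")
    return R


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with polynomial lens distortion.

    Focal lengths and the principal point are in pixels, distortion
    coefficients are dimensionless, ``width``/``height`` give the sensor
    raster size in pixels.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    skew: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ConfigError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ConfigError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [
                [self.fx, self.skew, self.cx],
                [0.0, self.fy, self.cy],
                [0.0, 0.0, 1.0],
            ]
        )

    @property
    def has_distortion(self) -> bool:
        return any(c != 0.0 for c in (self.k1, self.k2, self.p1, self.p2))

    def distort_normalized(self, xy: np.ndarray) -> np.ndarray:
        """Apply the distortion polynomial to normalized coordinates."""
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        radial = 1.0 + self.k1 * r2 + self.k2 * r2 * r2
        xd = x * radial + 2 * self.p1 * x * y + self.p2 * (r2 + 2 * x * x)
        yd = y * radial + self.p1 * (r2 + 2 * y * y) + 2 * self.p2 * x * y
        return np.stack([xd, yd], axis=-1)

    def pixels_from_normalized(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        u = self.fx * xy[..., 0] + self.skew * xy[..., 1] + self.cx
        v = self.fy * xy[..., 1] + self.cy
        return np.stack([u, v], axis=-1)

    def normalized_from_pixels(self, px: np.ndarray) -> np.ndarray:
        """Invert the affine K only (no distortion handling)."""
        px = np.asarray(px, dtype=float)
        y = (px[..., 1] - self.cy) / self.fy
        x = (px[..., 0] - self.cx - self.skew * y) / self.fx
        return np.stack([x, y], axis=-1)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``apply(x) = rotation @ x + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _as_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, rotvec: np.ndarray, translation: np.ndarray | None = None
    ) -> "RigidTransform":
        """Rotation given as an axis-angle vector (radians * unit axis)."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        t = np.zeros(3) if translation is None else translation
        return cls(R, t)

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        if M.shape != (4, 4):
            raise ConfigError("expected a 4x4 homogeneous matrix")
        return cls(M[:3, :3], M[:3, 3])

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass(frozen=True)
class StereoRig:
    """Calibrated stereo pair.

    ``rotation``/``translation`` map left-camera coordinates to right-camera
    coordinates: ``x_right = R @ x_left + t`` with ``t`` in mm.
    """

    left: CameraModel
    right: CameraModel
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _as_rotation(self.rotation, tol=1e-9))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @property
    def baseline(self) -> float:
        return float(np.linalg.norm(self.translation))

    @property
    def relative(self) -> RigidTransform:
        return RigidTransform(self.rotation, self.translation)


def project(
    cam: CameraModel, pose: RigidTransform, points: np.ndarray, *, min_depth: float = 1e-9
) -> np.ndarray:
    """Project world point(s) into distorted pixel coordinates.

    ``pose`` maps world to camera coordinates.  Raises
    :class:`NonProjectablePointError` if any point has non-positive depth.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pc = pose.apply(np.atleast_2d(pts))
    z = pc[:, 2]
    if np.any(z <= min_depth):
        raise NonProjectablePointError(
            f"{int(np.sum(z <= min_depth))} point(s) at or behind the camera center"
        )
    xy = pc[:, :2] / z[:, None]
    px = cam.pixels_from_normalized(cam.distort_normalized(xy))
    return px[0] if single else px


def _project_unchecked(cam: CameraModel, pose: RigidTransform, points: np.ndarray):
    """Vectorized projection returning (pixels, depth) without raising.

    Used by the renderer where behind-camera points are masked, not errors.
    """
    pc = pose.apply(np.atleast_2d(np.asarray(points, dtype=float)))
    z = pc[:, 2]
    safe = np.where(z > 1e-9, z, np.nan)
    xy = pc[:, :2] / safe[:, None]
    px = cam.pixels_from_normalized(cam.distort_normalized(xy))
    return px, z


def undistort(
    cam: CameraModel,
    pixels: np.ndarray,
    *,
    max_iter: int = 50,
    residual_tol: float = 1e-10,
) -> np.ndarray:
    """Map distorted pixel coordinates to undistorted *normalized* coordinates.

    The distortion polynomial is inverted by fixed-point iteration; the result
    is verified by pushing it back through the forward model.  With all
    coefficients zero this reduces to the inverse affine calibration map.
    """
    px = np.asarray(pixels, dtype=float)
    single = px.ndim == 1
    xd = cam.normalized_from_pixels(np.atleast_2d(px))
    if not cam.has_distortion:
        return xd[0] if single else xd

    x = xd[:, 0].copy()
    y = xd[:, 1].copy()
    for _ in range(max_iter):
        r2 = x * x + y * y
        radial = 1.0 + cam.k1 * r2 + cam.k2 * r2 * r2
        dx = 2 * cam.p1 * x * y + cam.p2 * (r2 + 2 * x * x)
        dy = cam.p1 * (r2 + 2 * y * y) + 2 * cam.p2 * x * y
        with np.errstate(divide="ignore", invalid="ignore"):
            x_new = (xd[:, 0] - dx) / radial
            y_new = (xd[:, 1] - dy) / radial
        if not np.all(np.isfinite(x_new)) or not np.all(np.isfinite(y_new)):
            raise DistortionInversionError("distortion inversion diverged")
        step = np.max(np.abs(x_new - x) + np.abs(y_new - y))
        x, y = x_new, y_new
        if step < 1e-14:
            break
    xy = np.stack([x, y], axis=-1)
    residual = np.max(np.abs(cam.distort_normalized(xy) - xd))
    if not np.isfinite(residual) or residual > residual_tol:
        raise DistortionInversionError(
            f"distortion inversion residual {residual:.3g} exceeds {residual_tol:g}"
        )
    return xy[0] if single else xy


def undistorted_pixels(cam: CameraModel, pixels: np.ndarray) -> np.ndarray:
    """Undistort pixel coordinates and re-express them as ideal pinhole pixels.

    Convenience for epipolar computations that work in pixel units.
    """
    return cam.pixels_from_normalized(undistort(cam, pixels))


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def fundamental_matrix(rig: StereoRig) -> np.ndarray:
    """Fundamental matrix for *undistorted* pixel coordinates.

    Satisfies ``x_r^T F x_l = 0`` for homogeneous undistorted pixels.
    Normalized to unit Frobenius norm with a deterministic sign.
    """
    if rig.baseline == 0.0:
        raise DegenerateRigError("stereo baseline is zero")
    E = _skew(rig.translation) @ rig.rotation
    F = np.linalg.inv(rig.right.K).T @ E @ np.linalg.inv(rig.left.K)
    F = F / np.linalg.norm(F)
    # deterministic sign: make the largest-magnitude entry positive
    idx = np.unravel_index(np.argmax(np.abs(F)), F.shape)
    if F[idx] < 0:
        F = -F
    return F


def triangulate(
    rig: StereoRig,
    left_px: np.ndarray,
    right_px: np.ndarray,
    *,
    pixels_undistorted: bool = False,
):
    """Triangulate pixel correspondences by the midpoint method.

    Back-projects both pixels to rays (undistorting them unless
    ``pixels_undistorted``), finds the common perpendicular of the two rays
    and returns ``(points_mm, gap_mm)`` where the point is the segment
    midpoint in the *left camera frame* and the gap is the closest distance
    between the rays — a quality score for the correspondence.

    Accepts single pixel pairs or (N, 2) arrays.
    """
    if rig.baseline == 0.0:
        raise DegenerateRigError("stereo baseline is zero")
    lp = np.asarray(left_px, dtype=float)
    single = lp.ndim == 1
    lp = np.atleast_2d(lp)
    rp = np.atleast_2d(np.asarray(right_px, dtype=float))
    if pixels_undistorted:
        nl = rig.left.normalized_from_pixels(lp)
        nr = rig.right.normalized_from_pixels(rp)
    else:
        nl = undistort(rig.left, lp)
        nr = undistort(rig.right, rp)

    d1 = np.concatenate([nl, np.ones((len(nl), 1))], axis=1)
    R = rig.rotation
    t = rig.translation
    o2 = -R.T @ t  # right camera center in the left frame
    d2 = np.concatenate([nr, np.ones((len(nr), 1))], axis=1) @ R  # R.T @ d per row

    # closest points on the two rays: o1 + s d1 and o2 + u d2
    a = np.einsum("ij,ij->i", d1, d1)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d2, d2)
    w0 = -o2[None, :]
    d = np.einsum("ij,ij->i", d1, w0)
    e = np.einsum("ij,ij->i", d2, w0)
    denom = a * c - b * b
    degenerate = denom <= 1e-14 * a * c
    if np.any(degenerate):
        raise NonTriangulablePairError(
            f"{int(np.sum(degenerate))} correspondence(s) back-project to parallel rays"
        )
    s = (b * e - c * d) / denom
    u = (a * e - b * d) / denom
    p1 = s[:, None] * d1
    p2 = o2[None, :] + u[:, None] * d2
    mid = 0.5 * (p1 + p2)
    gap = np.linalg.norm(p1 - p2, axis=1)
    if single:
        return mid[0], float(gap[0])
    return mid, gap


def estimate_rigid(
    source: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    collinearity_tol: float = 1e-9,
) -> RigidTransform:
    """Weighted least-squares rigid fit mapping ``source`` onto ``target``.

    Closed-form solution via SVD of the weighted cross-covariance with a
    reflection guard (the returned rotation always has determinant +1).
    Requires at least three non-collinear correspondences.
    """
    src = np.asarray(source, dtype=float)
    dst = np.asarray(target, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise DegenerateGeometryError("source/target must be matching (N, 3) arrays")
    n = len(src)
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 correspondences, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise DegenerateGeometryError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cs = w @ src
    ct = w @ dst
    src_c = src - cs
    dst_c = dst - ct
    sv = np.linalg.svd(src_c * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] <= collinearity_tol * max(sv[0], 1.0):
        raise DegenerateGeometryError("source points are (near-)collinear")
    H = (src_c * w[:, None]).T @ dst_c
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = ct - R @ cs
    return RigidTransform(R, t)


# ---------------------------------------------------------------------------
# calibration file I/O
# ---------------------------------------------------------------------------

_CALIB_SCHEMA = "gridstereo-calibration/1"
_CAM_KEYS = {"fx", "fy", "cx", "cy", "skew", "k1", "k2", "p1", "p2", "width", "height"}


def _camera_to_dict(cam: CameraModel) -> dict:
    return {
        "fx": float(cam.fx),
        "fy": float(cam.fy),
        "cx": float(cam.cx),
        "cy": float(cam.cy),
        "skew": float(cam.skew),
        "k1": float(cam.k1),
        "k2": float(cam.k2),
        "p1": float(cam.p1),
        "p2": float(cam.p2),
        "width": int(cam.width),
        "height": int(cam.height),
    }


def _camera_from_dict(d: dict, name: str) -> CameraModel:
    if not isinstance(d, dict):
        raise ConfigError(f"calibration section '{name}' must be a mapping")
    unknown = set(d) - _CAM_KEYS
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    missing = {"fx", "fy", "cx", "cy", "width", "height"} - set(d)
    if missing:
        raise ConfigError(f"missing key(s) in '{name}': {sorted(missing)}")
    return CameraModel(**d)


def save_calibration(rig: StereoRig, path) -> None:
    """Write a stereo calibration file (YAML schema ``gridstereo-calibration/1``)."""
    doc = {
        "schema": _CALIB_SCHEMA,
        "left": _camera_to_dict(rig.left),
        "right": _camera_to_dict(rig.right),
        "rotation": [float(v) for v in rig.rotation.reshape(-1)],
        "translation_mm": [float(v) for v in rig.translation],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_calibration(path) -> StereoRig:
    """Read a stereo calibration file.

    The rig rotation may be given either as 9 row-major numbers under
    ``rotation`` or as an axis-angle 3-vector under ``axis_angle``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"calibration file {path} is not a mapping")
    allowed = {"schema", "left", "right", "rotation", "axis_angle", "translation_mm"}
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown calibration key(s): {sorted(unknown)}")
    if doc.get("schema") != _CALIB_SCHEMA:
        raise ConfigError(
            f"unsupported calibration schema {doc.get('schema')!r}; expected {_CALIB_SCHEMA!r}"
        )
    left = _camera_from_dict(doc.get("left"), "left")
    right = _camera_from_dict(doc.get("right"), "right")
    if "rotation" in doc:
        R = np.asarray(doc["rotation"], dtype=float).reshape(3, 3)
    elif "axis_angle" in doc:
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(np.asarray(doc["axis_angle"], dtype=float)).as_matrix()
    else:
        raise ConfigError("calibration needs 'rotation' or 'axis_angle'")
    t = np.asarray(doc.get("translation_mm"), dtype=float).reshape(3)
    return StereoRig(left=left, right=right, rotation=R, translation=t)
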