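"""Synthetic structured-light stereo scenes with exact ground truth.

This module stands in for the physical experiment: a smooth liver-like
surface patch, a pocket projector casting a gridline pattern onto it, and a
narrow-baseline stereo endoscope imaging the scene from a set of poses.
Every rendered stereo pair comes with exact ground truth (3D gridline
crossings, their projections in both views, grid indices, a dense reference
mesh), so each downstream stage of the reconstruction pipeline can be scored
against truth rather than eyeballed.

Conventions and default study conditions
----------------------------------------
* World frame: the surface is a height field ``z = f(x, y)`` (mm) roughly
  30 mm in front of the endoscope; the base endoscope pose is the identity
  (left camera at the origin looking along +z).
* The projector is modelled as a reverse pinhole camera (848x480, the
  resolution of a small commercial pocket projector) mounted a few mm off
  the endoscope axis; it is fixed in the world while the endoscope moves.
* Gridlines are rendered dark on a bright background — the downstream
  pipeline inverts the grayscale image so lines become bright.
* Illumination is a multiplicative radial falloff; sensor noise is additive
  Gaussian, quantized to 8 bit.  Rendering is a pure function of the scene
  and its seed.
* Optional "clutter": a few dark X-shaped smudges on the surface outside
  the pattern footprint.  They are real 3D features (consistent between the
  two views) and exist to give the region-of-interest stage something real
  to reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import trimesh

from .errors import ConfigError, NonProjectablePointError, PatternNotVisibleError
from .geometry import CameraModel, RigidTransform, StereoRig, _project_unchecked, project, undistort

__all__ = [
    "GridPattern",
    "Surface",
    "SyntheticScene",
    "GroundTruth",
    "make_surface",
    "default_projector",
    "default_rig",
    "default_scene",
    "render_stereo",
    "make_experiment",
    "save_ground_truth",
    "load_ground_truth",
]


@dataclass(frozen=True)
class GridPattern:
    """Projected lattice: ``rows`` horizontal and ``cols`` vertical lines.

    ``spacing`` and ``line_width`` are in projector pixels.  The lattice is
    centred on the projector's principal point; its crossings are the
    ``rows * cols`` feature points of the method.
    """

    rows: int = 7
    cols: int = 11
    spacing: float = 32.0
    line_width: float = 5.0
    overhang: float = 10.0  # how far lines extend past the outermost crossing

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ConfigError("pattern needs at least 2 rows and 2 columns")
        if self.spacing <= 0 or self.line_width <= 0:
            raise ConfigError("spacing and line width must be positive")

    @property
    def n_points(self) -> int:
        return self.rows * self.cols

    def crossing_pixels(self, projector: CameraModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Projector-pixel coordinates of all crossings plus (row, col) indices."""
        u0 = projector.cx - (self.cols - 1) * self.spacing / 2.0
        v0 = projector.cy - (self.rows - 1) * self.spacing / 2.0
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        rows = rr.reshape(-1)
        cols = cc.reshape(-1)
        uv = np.stack([u0 + cols * self.spacing, v0 + rows * self.spacing], axis=-1)
        return uv, rows, cols


@dataclass(frozen=True)
class Surface:
    """Smooth height field ``z = fn(x, y)`` with a triangulated reference mesh."""

    fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    mesh: trimesh.Trimesh
    extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax (mm)
    kind: str
    params: dict = field(default_factory=dict)


def _mesh_from_heightfield(fn, extent, resolution: float) -> trimesh.Trimesh:
    xmin, xmax, ymin, ymax = extent
    nx = max(int(round((xmax - xmin) / resolution)) + 1, 2)
    ny = max(int(round((ymax - ymin) / resolution)) + 1, 2)
    xs = np.linspace(xmin, xmax, nx)
    ys = np.linspace(ymin, ymax, ny)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    Z = fn(X, Y)
    verts = np.stack([X.reshape(-1), Y.reshape(-1), Z.reshape(-1)], axis=-1)
    idx = np.arange(nx * ny).reshape(ny, nx)
    a = idx[:-1, :-1].reshape(-1)
    b = idx[:-1, 1:].reshape(-1)
    c = idx[1:, :-1].reshape(-1)
    d = idx[1:, 1:].reshape(-1)
    faces = np.concatenate(
        [np.stack([a, b, c], axis=-1), np.stack([b, d, c], axis=-1)], axis=0
    )
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def make_surface(
    kind: str = "liver_like",
    *,
    extent: tuple[float, float, float, float] = (-14.0, 14.0, -11.0, 11.0),
    resolution: float = 0.4,
    z0: float = 30.0,
    amplitude: float = 2.5,
    sigma: float = 5.0,
    center: tuple[float, float] = (0.0, 0.0),
    n_bumps: int | None = None,
    seed: int = 0,
) -> Surface:
    """Build a smooth surface patch emulating an organ surface.

    Kinds: ``plane`` (constant depth ``z0``), ``bump`` (one Gaussian bump of
    the given ``amplitude``/``sigma``), ``liver_like`` (a seeded sum of 3-5
    Gaussian bumps on the base depth — gently undulating like a liver lobe).
    Deterministic given its parameters.
    """
    xmin, xmax, ymin, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ConfigError("surface extent must have positive area")
    if resolution <= 0:
        raise ConfigError("resolution must be positive")

    params = dict(extent=extent, resolution=resolution, z0=z0, seed=seed)
    if kind == "plane":

        def fn(x, y, _z0=z0):
            return np.full(np.broadcast(x, y).shape, float(_z0))

    elif kind == "bump":
        params.update(amplitude=amplitude, sigma=sigma, center=center)

        def fn(x, y, _z0=z0, _a=amplitude, _s=sigma, _c=center):
            return _z0 - _a * np.exp(
                -(((x - _c[0]) ** 2 + (y - _c[1]) ** 2) / (2.0 * _s**2))
            )

    elif kind == "liver_like":
        rng = np.random.default_rng(seed)
        k = int(n_bumps) if n_bumps is not None else int(rng.integers(3, 6))
        cx = rng.uniform(xmin * 0.6, xmax * 0.6, size=k)
        cy = rng.uniform(ymin * 0.6, ymax * 0.6, size=k)
        amp = rng.uniform(0.6, 1.0, size=k) * amplitude * rng.choice([-1.0, 1.0], size=k)
        sig = rng.uniform(3.0, 7.0, size=k)
        params.update(n_bumps=k, amplitude=amplitude)

        def fn(x, y, _z0=z0, _cx=cx, _cy=cy, _amp=amp, _sig=sig):
            z = np.full(np.broadcast(x, y).shape, float(_z0))
            for j in range(len(_amp)):
                z = z + _amp[j] * np.exp(
                    -(((x - _cx[j]) ** 2 + (y - _cy[j]) ** 2) / (2.0 * _sig[j] ** 2))
                )
            return z

    else:
        raise ConfigError(f"unknown surface kind {kind!r}")

    mesh = _mesh_from_heightfield(fn, extent, resolution)
    return Surface(fn=fn, mesh=mesh, extent=extent, kind=kind, params=params)


def _look_at(position, target) -> RigidTransform:
    """World-to-camera pose for a camera at ``position`` looking at ``target``.

    Camera convention: x right, y down, z forward; the world +y axis maps to
    (roughly) image-down.
    """
    p = np.asarray(position, dtype=float)
    f = np.asarray(target, dtype=float) - p
    z = f / np.linalg.norm(f)
    x = np.cross(np.array([0.0, 1.0, 0.0]), z)
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        x = np.array([1.0, 0.0, 0.0])
    else:
        x = x / nx
    y = np.cross(z, x)
    R = np.stack([x, y, z], axis=0)
    return RigidTransform(R, -R @ p)


def default_projector() -> tuple[CameraModel, RigidTransform]:
    """Pocket-projector model (848x480) mounted 6.4 mm off-axis."""
    cam = CameraModel(fx=800.0, fy=800.0, cx=424.0, cy=240.0, width=848, height=480)
    pose = _look_at((5.0, 4.0, -2.0), (0.0, 0.0, 30.0))
    return cam, pose


def default_rig(
    *,
    baseline: float = 4.0,
    convergence_deg: float = 2.0,
    distortion: bool = True,
) -> StereoRig:
    """Stereo endoscope rig: 4 mm baseline, 2 degree convergence.

    640x480 sensors with 700 px focal length give a ~27x21 mm field of view
    at the 30 mm working distance.  Mild radial distortion is on by default
    so the undistortion path is exercised end to end.
    """
    from scipy.spatial.transform import Rotation

    k1, k2 = (-0.06, 0.004) if distortion else (0.0, 0.0)
    cam = dict(fx=700.0, fy=700.0, cx=320.0, cy=240.0, width=640, height=480, k1=k1, k2=k2)
    left = CameraModel(**cam)
    right = CameraModel(**cam)
    theta = np.deg2rad(convergence_deg)
    R = Rotation.from_rotvec([0.0, theta, 0.0]).as_matrix()
    center_right_in_left = np.array([baseline, 0.0, 0.0])
    t = -R @ center_right_in_left
    return StereoRig(left=left, right=right, rotation=R, translation=t)


@dataclass(frozen=True)
class SyntheticScene:
    """Complete description of one rendered stereo acquisition."""

    surface: Surface
    pattern: GridPattern
    rig: StereoRig
    camera_pose: RigidTransform  # world -> left camera
    projector: CameraModel
    projector_pose: RigidTransform  # world -> projector
    background: float = 210.0
    line_depth: float = 130.0  # gray levels subtracted at a line centre
    illumination_strength: float = 0.35  # 1 - ambient level; 0 disables shading
    illumination_center: tuple[float, float] = (0.3, 0.35)  # fractional image coords
    illumination_sigma: float = 0.23  # spot half-width as a fraction of image width
    illumination_exponent: float = 1.0  # super-Gaussian order; 1 = plain Gaussian spot
    projector_falloff_sigma: float = 120.0  # projector px; 0 disables contrast falloff
    noise_sigma: float = 3.0
    n_clutter: int = 4
    seed: int = 0


def default_scene(
    seed: int = 0,
    *,
    surface: Surface | None = None,
    noise_sigma: float = 3.0,
    illumination_strength: float = 0.35,
    n_clutter: int = 4,
    pattern: GridPattern | None = None,
) -> SyntheticScene:
    """The default study scene: liver-like surface, 7x11 grid, noisy, shaded."""
    projector, projector_pose = default_projector()
    return SyntheticScene(
        surface=surface if surface is not None else make_surface("liver_like", seed=1),
        pattern=pattern if pattern is not None else GridPattern(),
        rig=default_rig(),
        camera_pose=RigidTransform.identity(),
        projector=projector,
        projector_pose=projector_pose,
        background=210.0,
        line_depth=130.0,
        illumination_strength=illumination_strength,
        illumination_center=(0.35, 0.35),
        noise_sigma=noise_sigma,
        n_clutter=n_clutter,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Exact truth for one rendered stereo pair.

    2D projections are pre-quantization, i.e. exactly ``project()`` of the 3D
    crossings; ``line_core_*`` mask pixels whose gridline coverage is >= 0.9
    (used to score binarization recall).
    """

    points3d_world: np.ndarray  # (N, 3) mm
    points3d_left: np.ndarray  # (N, 3) mm, left-camera frame
    left2d: np.ndarray  # (N, 2) px (distorted, as imaged)
    right2d: np.ndarray  # (N, 2) px
    rows: np.ndarray  # (N,) grid row index
    cols: np.ndarray  # (N,) grid column index
    visible_left: np.ndarray  # (N,) bool
    visible_right: np.ndarray  # (N,) bool
    mesh: trimesh.Trimesh  # dense reference surface mesh (world frame)
    line_core_left: np.ndarray | None = None  # (H, W) bool
    line_core_right: np.ndarray | None = None


def _intersect_heightfield(
    origin: np.ndarray, dirs: np.ndarray, fn, z_init: float, n_iter: int = 15
):
    """Ray/height-field intersection by depth fixed-point iteration.

    Valid for rays that are not grazing (|dz| bounded away from 0), which
    holds for near-nadir endoscope/projector geometry with gentle slopes.
    Returns (points (N,3), valid (N,) bool).
    """
    dz = dirs[:, 2]
    valid = dz > 1e-6
    z = np.full(len(dirs), float(z_init))
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(n_iter):
            s = (z - origin[2]) / dz
            x = origin[0] + s * dirs[:, 0]
            y = origin[1] + s * dirs[:, 1]
            z = fn(x, y)
    s = (z - origin[2]) / dz
    pts = origin[None, :] + s[:, None] * dirs
    valid &= np.isfinite(pts).all(axis=1) & (s > 0)
    return pts, valid


def _camera_rays_world(cam: CameraModel, pose: RigidTransform):
    """Ray origin and per-pixel world direction for every pixel centre."""
    u, v = np.meshgrid(np.arange(cam.width, dtype=float), np.arange(cam.height, dtype=float))
    px = np.stack([u.reshape(-1), v.reshape(-1)], axis=-1)
    n = undistort(cam, px, residual_tol=1e-8)
    d_cam = np.concatenate([n, np.ones((len(n), 1))], axis=1)
    inv = pose.inverse()
    dirs = d_cam @ inv.rotation.T
    return inv.translation, dirs


def _pattern_line_distance(scene: SyntheticScene, proj_px: np.ndarray) -> np.ndarray:
    """Distance (projector px) from projector-plane points to the nearest gridline."""
    pat = scene.pattern
    u0 = scene.projector.cx - (pat.cols - 1) * pat.spacing / 2.0
    v0 = scene.projector.cy - (pat.rows - 1) * pat.spacing / 2.0
    u = proj_px[:, 0]
    v = proj_px[:, 1]
    umax = u0 + (pat.cols - 1) * pat.spacing
    vmax = v0 + (pat.rows - 1) * pat.spacing

    j = np.clip(np.round((u - u0) / pat.spacing), 0, pat.cols - 1)
    d_vert = np.abs(u - (u0 + j * pat.spacing))
    in_v = (v >= v0 - pat.overhang) & (v <= vmax + pat.overhang)
    d_vert = np.where(in_v, d_vert, np.inf)

    i = np.clip(np.round((v - v0) / pat.spacing), 0, pat.rows - 1)
    d_horz = np.abs(v - (v0 + i * pat.spacing))
    in_u = (u >= u0 - pat.overhang) & (u <= umax + pat.overhang)
    d_horz = np.where(in_u, d_horz, np.inf)

    return np.minimum(d_vert, d_horz)


def _clutter_segments(scene: SyntheticScene, footprint) -> np.ndarray:
    """Seeded X-shaped clutter strokes (world-xy segments) outside the pattern.

    Returns (M, 5) rows of (x0, y0, x1, y1, half_width_mm).  Strokes sit in a
    band between the pattern footprint and the edge of the base field of
    view, far enough from the pattern that morphological ROI closing cannot
    bridge to them.
    """
    if scene.n_clutter <= 0:
        return np.zeros((0, 5))
    rng = np.random.default_rng([scene.seed, 7])
    xmin, xmax, ymin, ymax = footprint
    half_len = 0.9
    half_width = 0.1
    clearance = 2.6  # mm from the outermost gridline to the nearest stroke tip
    segs = []
    for k in range(scene.n_clutter):
        side = k % 4  # deterministic rotation through top/bottom/right/left
        if side == 0:
            cx_, cy_ = rng.uniform(xmin, xmax), rng.uniform(
                ymax + clearance + half_len, ymax + clearance + half_len + 0.4
            )
        elif side == 1:
            cx_, cy_ = rng.uniform(xmin, xmax), -rng.uniform(
                -ymin + clearance + half_len, -ymin + clearance + half_len + 0.4
            )
        elif side == 2:
            cx_, cy_ = rng.uniform(
                xmax + clearance + half_len, xmax + clearance + half_len + 1.0
            ), rng.uniform(ymin, ymax)
        else:
            cx_, cy_ = -rng.uniform(
                -xmin + clearance + half_len, -xmin + clearance + half_len + 1.0
            ), rng.uniform(ymin, ymax)
        theta = rng.uniform(0, np.pi)
        dtheta = np.deg2rad(rng.uniform(70, 110))
        for ang in (theta, theta + dtheta):
            dx, dy = np.cos(ang) * half_len, np.sin(ang) * half_len
            segs.append([cx_ - dx, cy_ - dy, cx_ + dx, cy_ + dy, half_width])
    return np.asarray(segs)


def _segment_coverage(xy: np.ndarray, segs: np.ndarray, aa: float = 0.05) -> np.ndarray:
    """Anti-aliased coverage of world-xy points by clutter strokes."""
    cov = np.zeros(len(xy))
    for x0, y0, x1, y1, hw in segs:
        a = np.array([x0, y0])
        ab = np.array([x1 - x0, y1 - y0])
        t = np.clip(((xy - a) @ ab) / (ab @ ab), 0.0, 1.0)
        d = np.linalg.norm(xy - (a + t[:, None] * ab), axis=1)
        cov = np.maximum(cov, np.clip((hw - d) / aa + 0.5, 0.0, 1.0))
    return cov


def _render_view(
    scene: SyntheticScene,
    cam: CameraModel,
    pose: RigidTransform,
    segs: np.ndarray,
    rng: np.random.Generator,
    z_init: float,
):
    origin, dirs = _camera_rays_world(cam, pose)
    pts, valid = _intersect_heightfield(origin, dirs, scene.surface.fn, z_init)

    proj_px, proj_z = _project_unchecked(scene.projector, scene.projector_pose, pts)
    ok = valid & (proj_z > 0) & np.isfinite(proj_px).all(axis=1)
    d_line = np.full(len(pts), np.inf)
    d_line[ok] = _pattern_line_distance(scene, proj_px[ok])
    coverage = np.clip(scene.pattern.line_width / 2.0 - d_line + 0.5, 0.0, 1.0)
    line_core = coverage >= 0.9  # geometric line centres, independent of shading
    if scene.projector_falloff_sigma > 0:
        # projector brightness falls off from its optical axis, so the
        # line/background contrast fades towards the pattern borders — the
        # second non-uniformity (besides the viewing light) of a real setup.
        rp2 = np.zeros(len(pts))
        rp2[ok] = (proj_px[ok, 0] - scene.projector.cx) ** 2 + (
            proj_px[ok, 1] - scene.projector.cy
        ) ** 2
        coverage = coverage * np.exp(-rp2 / (2.0 * scene.projector_falloff_sigma**2))

    if len(segs):
        cov_cl = np.zeros(len(pts))
        cov_cl[valid] = _segment_coverage(pts[valid, :2], segs)
        coverage = np.maximum(coverage, cov_cl)

    img = scene.background - scene.line_depth * coverage

    if scene.illumination_strength > 0:
        # spotlight shading: ambient floor plus a super-Gaussian spot with a
        # steep shoulder, emulating the near-field light cone of an
        # endoscope.  Illumination then varies strongly between the lit and
        # ambient zones, which is what defeats a single global threshold on
        # the uncorrected image.
        u, v = np.meshgrid(np.arange(cam.width, dtype=float), np.arange(cam.height, dtype=float))
        cu = scene.illumination_center[0] * cam.width
        cv = scene.illumination_center[1] * cam.height
        r2 = (u.reshape(-1) - cu) ** 2 + (v.reshape(-1) - cv) ** 2
        sig = scene.illumination_sigma * cam.width
        ambient = 1.0 - scene.illumination_strength
        spot = np.exp(-((r2 / (2.0 * sig**2)) ** scene.illumination_exponent))
        img = img * (ambient + (1.0 - ambient) * spot)

    if scene.noise_sigma > 0:
        img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img.reshape(cam.height, cam.width), line_core.reshape(cam.height, cam.width)


def _ground_truth_geometry(scene: SyntheticScene):
    """3D crossings and their exact projections for the current poses."""
    uv, rows, cols = scene.pattern.crossing_pixels(scene.projector)
    n = scene.projector.normalized_from_pixels(uv)  # projector has no distortion
    d_proj = np.concatenate([n, np.ones((len(n), 1))], axis=1)
    inv = scene.projector_pose.inverse()
    dirs = d_proj @ inv.rotation.T
    z_init = float(np.mean(scene.surface.mesh.vertices[:, 2]))
    pts, valid = _intersect_heightfield(inv.translation, dirs, scene.surface.fn, z_init)
    if not np.all(valid):
        raise PatternNotVisibleError("some pattern crossings do not hit the surface")

    left_pose = scene.camera_pose
    right_pose = scene.rig.relative.compose(left_pose)
    l2d = project(scene.rig.left, left_pose, pts)
    r2d = project(scene.rig.right, right_pose, pts)

    def _inside(px, cam, margin=3.0):
        return (
            (px[:, 0] >= margin)
            & (px[:, 0] <= cam.width - 1 - margin)
            & (px[:, 1] >= margin)
            & (px[:, 1] <= cam.height - 1 - margin)
        )

    vis_l = _inside(l2d, scene.rig.left)
    vis_r = _inside(r2d, scene.rig.right)
    return pts, l2d, r2d, rows, cols, vis_l, vis_r, z_init


def render_stereo(scene: SyntheticScene):
    """Render the stereo pair and its ground truth.

    Returns ``(left_image, right_image, truth)`` with uint8 grayscale images.
    Deterministic: the same scene (including its seed) always produces
    bit-identical images.  Raises :class:`PatternNotVisibleError` when no
    crossing is visible in both views.
    """
    pts, l2d, r2d, rows, cols, vis_l, vis_r, z_init = _ground_truth_geometry(scene)
    both = vis_l & vis_r
    if not np.any(both):
        raise PatternNotVisibleError(
            "pattern entirely out of view (0.0% of crossings visible in both views)"
        )

    footprint = (
        float(pts[:, 0].min()),
        float(pts[:, 0].max()),
        float(pts[:, 1].min()),
        float(pts[:, 1].max()),
    )
    segs = _clutter_segments(scene, footprint)

    left_pose = scene.camera_pose
    right_pose = scene.rig.relative.compose(left_pose)
    rng_l = np.random.default_rng([scene.seed, 0])
    rng_r = np.random.default_rng([scene.seed, 1])
    left, core_l = _render_view(scene, scene.rig.left, left_pose, segs, rng_l, z_init)
    right, core_r = _render_view(scene, scene.rig.right, right_pose, segs, rng_r, z_init)

    truth = GroundTruth(
        points3d_world=pts,
        points3d_left=left_pose.apply(pts),
        left2d=l2d,
        right2d=r2d,
        rows=rows,
        cols=cols,
        visible_left=vis_l,
        visible_right=vis_r,
        mesh=scene.surface.mesh,
        line_core_left=core_l,
        line_core_right=core_r,
    )
    return left, right, truth


def make_experiment(
    n_poses: int,
    base_scene: SyntheticScene | None = None,
    *,
    rot_jitter_deg: float = 1.5,
    trans_jitter_mm: float = 1.2,
    seed: int = 0,
    max_attempts: int = 25,
) -> list[SyntheticScene]:
    """Generate ``n_poses`` scenes with the endoscope perturbed around its base pose.

    The projector and surface stay fixed in the world (the pattern is painted
    on the same spot); only the camera pose and the per-scene noise seed
    change.  Each pose is rejected and resampled (bounded attempts) unless
    every grid crossing stays visible in both views.
    """
    if n_poses < 1:
        raise ConfigError("n_poses must be >= 1")
    base = base_scene if base_scene is not None else default_scene()
    rng = np.random.default_rng(seed)
    scenes: list[SyntheticScene] = []
    for k in range(n_poses):
        scene_seed = int(rng.integers(2**31))
        for attempt in range(max_attempts):
            if rot_jitter_deg == 0 and trans_jitter_mm == 0:
                jitter = RigidTransform.identity()
            else:
                axis = rng.normal(size=3)
                axis = axis / np.linalg.norm(axis)
                angle = np.deg2rad(rng.uniform(0, rot_jitter_deg))
                tr = rng.uniform(-trans_jitter_mm, trans_jitter_mm, size=3)
                jitter = RigidTransform.from_axis_angle(axis * angle, tr)
            candidate = replace(
                base, camera_pose=jitter.compose(base.camera_pose), seed=scene_seed
            )
            try:
                _, _, _, _, _, vis_l, vis_r, _ = _ground_truth_geometry(candidate)
            except (PatternNotVisibleError, NonProjectablePointError):
                continue
            if np.all(vis_l & vis_r):
                scenes.append(candidate)
                break
        else:
            raise PatternNotVisibleError(
                f"pose {k}: could not keep the pattern in view after {max_attempts} attempts"
            )
    return scenes


# ---------------------------------------------------------------------------
# ground-truth sidecar I/O (structured text)
# ---------------------------------------------------------------------------

_TRUTH_HEADER = "# gridstereo-truth/1"


def save_ground_truth(truth: GroundTruth, path) -> None:
    """Write crossings (3D + both projections + indices) as a text sidecar."""
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        fh.write("# row col X_mm Y_mm Z_mm ul_px vl_px ur_px vr_px visible_left visible_right\n")
        for i in range(len(truth.rows)):
            fh.write(
                f"{truth.rows[i]} {truth.cols[i]} "
                f"{truth.points3d_world[i, 0]:.9g} {truth.points3d_world[i, 1]:.9g} "
                f"{truth.points3d_world[i, 2]:.9g} "
                f"{truth.left2d[i, 0]:.9g} {truth.left2d[i, 1]:.9g} "
                f"{truth.right2d[i, 0]:.9g} {truth.right2d[i, 1]:.9g} "
                f"{int(truth.visible_left[i])} {int(truth.visible_right[i])}\n"
            )


def load_ground_truth(path) -> dict:
    """Read a truth sidecar back into arrays (no mesh / masks)."""
    with open(path) as fh:
        first = fh.readline().strip()
        if first != _TRUTH_HEADER:
            raise ConfigError(f"{path} is not a gridstereo truth file")
        data = np.loadtxt(fh, comments="#", ndmin=2)
    return {
        "rows": data[:, 0].astype(int),
        "cols": data[:, 1].astype(int),
        "points3d_world": data[:, 2:5],
        "left2d": data[:, 5:7],
        "right2d": data[:, 7:9],
        "visible_left": data[:, 9].astype(bool),
        "visible_right": data[:, 10].astype(bool),
    }
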