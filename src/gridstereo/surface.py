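"""3D grid reconstruction, smooth surface fitting, and the ASD metric.

Matched crossings are triangulated into an R x C grid of 3D points (left
camera frame).  The grid is a natural parameterization of the observed
surface patch, so a smooth surface is obtained by interpolating each
coordinate (x, y, z) over the (row, col) parameter plane with a bicubic
spline and evaluating it on an upsampled lattice.  Accuracy of a
reconstructed or registered surface against a reference mesh is summarised
by the average surface distance (ASD): the mean over source vertices of the
exact distance to the nearest reference triangle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.interpolate import RBFInterpolator, RectBivariateSpline

from ._mesh import MeshDistance
from .errors import ConfigError, DegenerateGeometryError
from .geometry import StereoRig, triangulate
from .matching import MatchedGrid

__all__ = [
    "GridSurface",
    "AsdReport",
    "reconstruct_grid",
    "fit_surface",
    "average_surface_distance",
]


@dataclass
class GridSurface:
    """R x C lattice of triangulated 3D points (NaN where missing)."""

    points: np.ndarray  # (R, C, 3) mm, left-camera frame
    gaps: np.ndarray  # (R, C) mm ray gap per point (NaN where missing)
    n_dropped: int  # matches discarded for exceeding the gap limit

    @property
    def present(self) -> np.ndarray:
        return np.isfinite(self.points).all(axis=2)

    @property
    def n_points(self) -> int:
        return int(self.present.sum())


def reconstruct_grid(
    matches: MatchedGrid,
    rig: StereoRig,
    max_gap: float = 2.0,
    *,
    pixels_undistorted: bool = True,
    depth_gate: float = 3.5,
) -> GridSurface:
    """Triangulate every matched pair and organise the points by grid index.

    Pairs whose back-projected rays pass farther than ``max_gap`` mm from
    each other are treated as mismatches and dropped (counted in
    ``n_dropped``).  A robust depth gate additionally drops points whose
    depth deviates from the median by more than ``depth_gate`` times the
    median absolute deviation (floored at 6 mm) — a false correspondence
    with near-identical pixel coordinates triangulates to a wildly wrong
    depth while keeping a small ray gap, so the gap alone cannot catch it.
    If two pairs land on the same grid cell the one with the smaller ray
    gap wins.
    """
    if len(matches) < 4:
        raise DegenerateGeometryError(f"need at least 4 matches, got {len(matches)}")
    pts, gaps = triangulate(
        rig, matches.left, matches.right, pixels_undistorted=pixels_undistorted
    )
    keep = gaps <= max_gap
    if depth_gate > 0 and keep.sum() >= 4:
        z = pts[:, 2]
        z_med = np.median(z[keep])
        mad = 1.4826 * np.median(np.abs(z[keep] - z_med))
        keep &= np.abs(z - z_med) <= depth_gate * max(mad, 6.0 / depth_gate)
    n_dropped = int((~keep).sum())
    rows = matches.rows[keep]
    cols = matches.cols[keep]
    if len(rows) < 4 or len(np.unique(rows)) < 2 or len(np.unique(cols)) < 2:
        raise DegenerateGeometryError(
            "too few surviving points spanning at least 2 rows and 2 columns"
        )
    R = int(rows.max()) + 1
    C = int(cols.max()) + 1
    grid = np.full((R, C, 3), np.nan)
    grid_gap = np.full((R, C), np.nan)
    for p, g, r, c in zip(pts[keep], gaps[keep], rows, cols):
        if not np.isfinite(grid_gap[r, c]) or g < grid_gap[r, c]:
            grid[r, c] = p
            grid_gap[r, c] = g
    return GridSurface(points=grid, gaps=grid_gap, n_dropped=n_dropped)


def _grid_mesh(verts_grid: np.ndarray) -> trimesh.Trimesh:
    ny, nx, _ = verts_grid.shape
    verts = verts_grid.reshape(-1, 3)
    idx = np.arange(ny * nx).reshape(ny, nx)
    a = idx[:-1, :-1].reshape(-1)
    b = idx[:-1, 1:].reshape(-1)
    c = idx[1:, :-1].reshape(-1)
    d = idx[1:, 1:].reshape(-1)
    faces = np.concatenate(
        [np.stack([a, b, c], axis=-1), np.stack([b, d, c], axis=-1)], axis=0
    )
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def fit_surface(
    grid: GridSurface, upsample: int = 8, *, method: str = "bicubic"
) -> trimesh.Trimesh:
    """Fit a smooth surface through the grid points and mesh it.

    Each coordinate is interpolated over the (row, col) parameter plane —
    ``method='bicubic'`` uses an interpolating bicubic spline (missing cells
    are first filled with a thin-plate-spline prediction so the spline has
    full support), ``method='tps'`` uses the thin-plate spline throughout.
    The fitted surface passes through every present grid point; ``upsample``
    controls the evaluation density (``upsample=1`` returns the grid points
    themselves).
    """
    if upsample < 1:
        raise ConfigError("upsample must be >= 1")
    if method not in ("bicubic", "tps"):
        raise ConfigError(f"unknown surface fit method {method!r}")
    pts = grid.points
    present = grid.present
    R, C = present.shape
    rows_ok = present.any(axis=1)
    cols_ok = present.any(axis=0)
    if present.sum() < 9 or rows_ok.sum() < 3 or cols_ok.sum() < 3:
        raise DegenerateGeometryError("surface fit needs >= 3x3 present grid points")

    rr, cc = np.nonzero(present)
    params = np.stack([rr, cc], axis=-1).astype(float)
    values = pts[rr, cc]

    ru = np.linspace(0, R - 1, (R - 1) * upsample + 1)
    cu = np.linspace(0, C - 1, (C - 1) * upsample + 1)

    if method == "tps" or not present.all():
        tps = RBFInterpolator(params, values, kernel="thin_plate_spline", smoothing=0.0)
    if method == "tps":
        RU, CU = np.meshgrid(ru, cu, indexing="ij")
        dense = tps(np.stack([RU.reshape(-1), CU.reshape(-1)], axis=-1))
        return _grid_mesh(dense.reshape(len(ru), len(cu), 3))

    filled = pts.copy()
    if not present.all():
        mr, mc = np.nonzero(~present)
        filled[mr, mc] = tps(np.stack([mr, mc], axis=-1).astype(float))
    kx = min(3, R - 1)
    ky = min(3, C - 1)
    dense = np.empty((len(ru), len(cu), 3))
    for dim in range(3):
        spl = RectBivariateSpline(
            np.arange(R), np.arange(C), filled[:, :, dim], kx=kx, ky=ky, s=0
        )
        dense[:, :, dim] = spl(ru, cu)
    return _grid_mesh(dense)


@dataclass
class AsdReport:
    """Average surface distance summary (mm)."""

    mean: float
    std: float
    distances: np.ndarray
    direction: str  # 'forward' (source -> reference) or 'symmetric'

    def __str__(self) -> str:
        return f"ASD {self.mean:.2f} ± {self.std:.2f} mm ({self.direction})"


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, trimesh.Trimesh):
        return np.asarray(obj.vertices, dtype=float)
    if isinstance(obj, trimesh.PointCloud):
        return np.asarray(obj.vertices, dtype=float)
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ConfigError("expected a mesh or an (N, 3) point array")
    return arr


def average_surface_distance(
    source, reference: trimesh.Trimesh, direction: str = "forward"
) -> AsdReport:
    """ASD between a source surface (mesh or points) and a reference mesh.

    ``forward`` averages exact point-to-mesh distances of the source
    vertices (the reconstruction usually covers only part of the reference
    organ surface, so this direction is not inflated by uncovered area).
    ``symmetric`` additionally measures reference vertices against the
    source mesh and averages the two directional means.
    """
    if direction not in ("forward", "symmetric"):
        raise ConfigError(f"unknown ASD direction {direction!r}")
    src_pts = _as_points(source)
    if len(src_pts) == 0:
        raise ConfigError("source surface is empty")
    if not isinstance(reference, trimesh.Trimesh) or len(reference.faces) == 0:
        raise ConfigError("reference must be a non-degenerate triangle mesh")
    d_fwd, _ = MeshDistance(reference).query(src_pts)
    if direction == "forward":
        return AsdReport(
            mean=float(d_fwd.mean()),
            std=float(d_fwd.std()),
            distances=d_fwd,
            direction="forward",
        )
    if not isinstance(source, trimesh.Trimesh) or len(source.faces) == 0:
        raise ConfigError("symmetric ASD needs the source as a triangle mesh")
    d_bwd, _ = MeshDistance(source).query(np.asarray(reference.vertices, dtype=float))
    mean = 0.5 * (float(d_fwd.mean()) + float(d_bwd.mean()))
    dists = np.concatenate([d_fwd, d_bwd])
    return AsdReport(
        mean=mean, std=float(dists.std()), distances=dists, direction="symmetric"
    )
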