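"""Left/right correspondence of detected crossings.

Gridline crossings all look alike, so descriptor matching is hopeless; the
constraints that identify a match are (a) the epipolar geometry of the
calibrated rig and (b) the lattice structure of the pattern.  Points are
first organised into grid columns (1-D gap clustering of x-coordinates) and
rows (y-order within a column); a left/right pair is accepted only when the
two points share a column index and the right point lies within a tolerance
of the left point's epipolar line.  Points that find no partner are
discarded and counted — this is what removes spurious detections that
survive the image-space filters.

All coordinates entering this module should be undistorted pixel
coordinates consistent with the fundamental matrix in use
(:func:`gridstereo.geometry.undistorted_pixels`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateLayoutError
from .features import IntersectionSet
from .synthetic import GridPattern

__all__ = ["IndexedPoints", "MatchedGrid", "assign_grid_indices", "match_epipolar"]


@dataclass
class IndexedPoints:
    """Detected points with tentative grid (row, column) indices."""

    points: np.ndarray  # (N, 2) px, (x, y)
    rows: np.ndarray  # (N,) int
    cols: np.ndarray  # (N,) int
    flagged: np.ndarray  # (N,) bool — point sits in an implausibly full column
    n_columns: int

    def __len__(self) -> int:
        return len(self.points)


def assign_grid_indices(points, pattern: GridPattern) -> IndexedPoints:
    """Organise detections into grid columns and rows.

    X-coordinates are clustered into at most ``pattern.cols`` columns found
    as peaks of a smoothed 1-D density (robust: a column is a *concentration*
    of x-values, so scattered spurious detections neither create columns nor
    bridge the gaps between real ones).  Points farther than half the peak
    spacing from every column receive index -1 — they cannot shift the
    numbering of the real columns between the two views.  Within a column,
    points are ordered by y to obtain row indices; columns holding more than
    ``pattern.rows`` points are flagged as implausible.
    """
    pts = points.points if isinstance(points, IntersectionSet) else np.asarray(points)
    pts = pts.reshape(-1, 2).astype(float)
    if len(pts) < 4:
        raise DegenerateLayoutError(f"need at least 4 points, got {len(pts)}")
    xs = pts[:, 0]
    span = xs.max() - xs.min()
    if span <= 0:
        raise DegenerateLayoutError("all points share one x-coordinate")

    # smoothed density of x-coordinates on a fine grid
    h = max(span / (4.0 * pattern.cols), 1.0)  # kernel bandwidth
    grid = np.arange(xs.min() - 3 * h, xs.max() + 3 * h, max(h / 4.0, 0.25))
    dens = np.exp(-0.5 * ((grid[:, None] - xs[None, :]) / h) ** 2).sum(axis=1)
    interior = (dens >= np.roll(dens, 1)) & (dens > np.roll(dens, -1))
    interior[0] = interior[-1] = False
    peak_pos = grid[interior]
    peak_height = dens[interior]
    # a real column concentrates several points; reject shallow bumps
    keep = peak_height >= max(1.5, 0.25 * peak_height.max())
    peak_pos, peak_height = peak_pos[keep], peak_height[keep]
    if len(peak_pos) > pattern.cols:  # keep the strongest, preserve x-order
        strongest = np.sort(np.argsort(peak_height)[-pattern.cols :])
        peak_pos = peak_pos[strongest]
    if len(peak_pos) < 2:
        raise DegenerateLayoutError("fewer than 2 resolvable columns")

    gap = float(np.median(np.diff(peak_pos))) if len(peak_pos) > 2 else float(
        peak_pos[-1] - peak_pos[0]
    )
    nearest = np.argmin(np.abs(xs[:, None] - peak_pos[None, :]), axis=1)
    dist = np.abs(xs - peak_pos[nearest])
    cols = np.where(dist <= 0.5 * gap, nearest, -1)
    if len(np.unique(cols[cols >= 0])) < 2:
        raise DegenerateLayoutError("fewer than 2 resolvable columns")

    rows = np.zeros(len(pts), dtype=int)
    flagged = cols < 0
    for c in range(len(peak_pos)):
        sel = np.nonzero(cols == c)[0]
        sel = sel[np.argsort(pts[sel, 1], kind="stable")]
        rows[sel] = np.arange(len(sel))
        if len(sel) > pattern.rows:
            flagged[sel] = True
    return IndexedPoints(
        points=pts, rows=rows, cols=cols, flagged=flagged, n_columns=len(peak_pos)
    )


@dataclass
class MatchedGrid:
    """One-to-one left/right correspondences with grid indices."""

    left: np.ndarray  # (M, 2) px
    right: np.ndarray  # (M, 2) px
    rows: np.ndarray  # (M,) int
    cols: np.ndarray  # (M,) int
    residuals: np.ndarray  # (M,) px, point-to-epipolar-line distance
    n_discarded_left: int = 0
    n_discarded_right: int = 0

    def __len__(self) -> int:
        return len(self.left)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# gridstereo-matches/1\n")
            fh.write("# xl yl xr yr row col residual_px\n")
            for i in range(len(self.left)):
                fh.write(
                    f"{self.left[i, 0]:.6f} {self.left[i, 1]:.6f} "
                    f"{self.right[i, 0]:.6f} {self.right[i, 1]:.6f} "
                    f"{self.rows[i]} {self.cols[i]} {self.residuals[i]:.6f}\n"
                )

    @classmethod
    def load(cls, path) -> "MatchedGrid":
        with open(path) as fh:
            first = fh.readline().strip()
            if first != "# gridstereo-matches/1":
                raise ConfigError(f"{path} is not a match file")
            data = np.loadtxt(fh, comments="#", ndmin=2)
        if data.size == 0:
            data = data.reshape(0, 7)
        return cls(
            left=data[:, 0:2],
            right=data[:, 2:4],
            rows=data[:, 4].astype(int),
            cols=data[:, 5].astype(int),
            residuals=data[:, 6],
        )


def _epipolar_distances(F: np.ndarray, left_pts: np.ndarray, right_pts: np.ndarray):
    """(n_left, n_right) perpendicular distances of right points to left epilines."""
    hl = np.concatenate([left_pts, np.ones((len(left_pts), 1))], axis=1)
    lines = hl @ F.T  # (n_left, 3)
    norm = np.linalg.norm(lines[:, :2], axis=1)
    hr = np.concatenate([right_pts, np.ones((len(right_pts), 1))], axis=1)
    return np.abs(lines @ hr.T) / norm[:, None]


def match_epipolar(
    left: IndexedPoints,
    right: IndexedPoints,
    F: np.ndarray,
    tol: float = 2.0,
) -> MatchedGrid:
    """Match left and right detections column-by-column under the epipolar gate.

    For each left point (walked in row order within its column), candidate
    right points are the unused points of the same column whose distance to
    the left point's epipolar line is at most ``tol``.  Ties prefer the
    candidate with the matching row index, then the smallest residual.
    Unmatched points on either side are discarded and counted.
    """
    if tol <= 0:
        raise ConfigError("tol must be positive")
    F = np.asarray(F, dtype=float)
    sv = np.linalg.svd(F, compute_uv=False)
    if sv[1] <= 1e-7 * sv[0] or sv[2] > 1e-7 * sv[0]:
        raise ConfigError("fundamental matrix must have rank exactly 2")

    D = _epipolar_distances(F, left.points, right.points)
    used_r = np.zeros(len(right), dtype=bool)
    out_l, out_r, out_row, out_col, out_res = [], [], [], [], []
    for c in range(max(left.n_columns, right.n_columns)):
        li = np.nonzero(left.cols == c)[0]
        li = li[np.argsort(left.rows[li])]
        ri_all = np.nonzero(right.cols == c)[0]
        for i in li:
            cand = ri_all[(~used_r[ri_all]) & (D[i, ri_all] <= tol)]
            if len(cand) == 0:
                continue
            same_row = cand[right.rows[cand] == left.rows[i]]
            pick = same_row[0] if len(same_row) else cand[np.argmin(D[i, cand])]
            used_r[pick] = True
            out_l.append(i)
            out_r.append(pick)
            out_row.append(int(left.rows[i]))
            out_col.append(c)
            out_res.append(float(D[i, pick]))

    m = len(out_l)
    return MatchedGrid(
        left=left.points[out_l].reshape(m, 2),
        right=right.points[out_r].reshape(m, 2),
        rows=np.asarray(out_row, dtype=int),
        cols=np.asarray(out_col, dtype=int),
        residuals=np.asarray(out_res, dtype=float),
        n_discarded_left=len(left) - m,
        n_discarded_right=len(right) - m,
    )
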