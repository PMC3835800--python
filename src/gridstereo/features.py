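"""Skeletonization and cross-point-number (CPN) junction detection.

A skeleton pixel's CPN is half the number of 0/1 transitions met when
walking once around a closed ring of its neighbours: 0 for an isolated
pixel, 1 for a line endpoint, 2 for an interior line pixel, >= 3 for a
junction.  Two rings are used:

* SCN (simple cross-point number): the 8-pixel ring of the 3x3 window.
* MCN (modified cross-point number): the 16-pixel perimeter of the 5x5
  window, which sees past single-pixel thinning artifacts at a crossing.

A skeleton pixel is a junction candidate when *both* numbers reach the
threshold (the combined criterion).  An ideal 4-arm crossing scores 4;
thinning often renders a crossing as two nearby 3-arm junctions, which is
why the threshold may be relaxed down to 3.  Adjacent candidates are merged
to sub-pixel centroids, and each centroid is optionally refined by fitting
the two gridline directions to nearby skeleton pixels and intersecting them.

The transition count is invariant to the ring's starting pixel and
traversal direction; the implementation walks clockwise from the top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import thin as _skimage_thin

from .errors import ConfigError

__all__ = [
    "thin",
    "cpn_scn",
    "cpn_mcn",
    "detect_intersections",
    "score_detection",
    "IntersectionSet",
    "DetectionScore",
    "SCN_RING",
    "MCN_RING",
]

# (dy, dx) offsets, clockwise starting directly above the centre pixel
SCN_RING = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
# clockwise 16-pixel perimeter of the 5x5 window, starting two above centre
MCN_RING = [
    (-2, 0), (-2, 1), (-2, 2), (-1, 2), (0, 2), (1, 2), (2, 2), (2, 1),
    (2, 0), (2, -1), (2, -2), (1, -2), (0, -2), (-1, -2), (-2, -2), (-2, -1),
]


def thin(image: np.ndarray) -> np.ndarray:
    """Morphologically thin a binary image to unit-width 8-connected curves."""
    img = np.asarray(image).astype(bool)
    if img.ndim != 2:
        raise ConfigError("thin expects a 2D binary image")
    return _skimage_thin(img)


def _ring_values(skeleton: np.ndarray, pixel, ring) -> np.ndarray:
    y, x = int(pixel[0]), int(pixel[1])
    H, W = skeleton.shape
    margin = max(abs(d) for off in ring for d in off)
    if not (margin <= y < H - margin and margin <= x < W - margin):
        raise ConfigError(
            f"pixel ({y}, {x}) too close to the border for a ring of radius {margin}"
        )
    return np.array([bool(skeleton[y + dy, x + dx]) for dy, dx in ring], dtype=int)


def _transition_count(ring_vals: np.ndarray) -> float:
    return 0.5 * float(np.sum(np.abs(np.diff(np.append(ring_vals, ring_vals[0])))))


def cpn_scn(skeleton: np.ndarray, pixel) -> float:
    """Simple cross-point number at ``pixel`` (given as (y, x) or (row, col)).

    Half the transition count around the 8-neighbour ring, traversed
    clockwise from the pixel directly above, closing back onto the first.
    """
    return _transition_count(_ring_values(skeleton, pixel, SCN_RING))


def cpn_mcn(skeleton: np.ndarray, pixel) -> float:
    """Modified cross-point number: transition count on the 5x5 perimeter."""
    return _transition_count(_ring_values(skeleton, pixel, MCN_RING))


def _cpn_map(skeleton: np.ndarray, ring) -> np.ndarray:
    """Vectorized CPN over the whole image (zero-padded borders)."""
    S = np.asarray(skeleton).astype(np.int8)
    pad = max(abs(d) for off in ring for d in off)
    P = np.pad(S, pad)
    H, W = S.shape
    stack = np.stack(
        [P[pad + dy : pad + dy + H, pad + dx : pad + dx + W] for dy, dx in ring]
    )
    diffs = np.abs(np.diff(np.concatenate([stack, stack[:1]], axis=0), axis=0))
    return 0.5 * diffs.sum(axis=0)


@dataclass
class IntersectionSet:
    """Detected gridline crossings with sub-pixel centroids.

    ``points`` are (x, y) pixel coordinates; ``scn``/``mcn`` carry the
    maximum CPN values over each merged candidate cluster.
    """

    points: np.ndarray  # (N, 2) float, (x, y)
    scn: np.ndarray  # (N,)
    mcn: np.ndarray  # (N,)
    source: str = ""

    def __len__(self) -> int:
        return len(self.points)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# gridstereo-intersections/1\n")
            fh.write("# x_px y_px cpn_scn cpn_mcn\n")
            for i in range(len(self.points)):
                fh.write(
                    f"{self.points[i, 0]:.6f} {self.points[i, 1]:.6f} "
                    f"{self.scn[i]:g} {self.mcn[i]:g}\n"
                )

    @classmethod
    def load(cls, path) -> "IntersectionSet":
        with open(path) as fh:
            first = fh.readline().strip()
            if first != "# gridstereo-intersections/1":
                raise ConfigError(f"{path} is not an intersection file")
            data = np.loadtxt(fh, comments="#", ndmin=2)
        if data.size == 0:
            data = data.reshape(0, 4)
        return cls(points=data[:, :2], scn=data[:, 2], mcn=data[:, 3], source=str(path))


def _merge_close(points, scn, mcn, weights, min_separation):
    """Union-find merge of centroids closer than ``min_separation``."""
    n = len(points)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(points)
    for i, j in tree.query_pairs(min_separation):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    out_pts, out_scn, out_mcn = [], [], []
    for r in np.unique(roots):
        sel = roots == r
        w = weights[sel]
        out_pts.append((points[sel] * w[:, None]).sum(axis=0) / w.sum())
        out_scn.append(scn[sel].max())
        out_mcn.append(mcn[sel].max())
    return np.array(out_pts), np.array(out_scn), np.array(out_mcn)


def _intersect_lines(lines):
    (m1, u1), (m2, u2) = lines
    cross = u1[0] * u2[1] - u1[1] * u2[0]
    if abs(cross) < 0.2:  # < ~11 degrees between arms: unreliable
        return None
    rhs = m2 - m1
    t1 = (rhs[0] * u2[1] - rhs[1] * u2[0]) / cross
    return m1 + t1 * u1


def _arm_partition(centroid, skel_points, tree, radius):
    """Split nearby skeleton pixels into the two gridline orientations.

    2-means on the doubled orientation angle; returns (points, labels, the
    two unit direction vectors) or None when the local geometry is too thin.
    """
    idx = tree.query_ball_point(centroid, radius)
    if len(idx) < 8:
        return None
    pts = skel_points[idx]
    rel = pts - centroid
    d = np.linalg.norm(rel, axis=1)
    keep = d > 1.5  # the junction core itself is biased; use the arms
    if keep.sum() < 8:
        return None
    rel = rel[keep]
    pts = pts[keep]
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    v = np.stack([np.cos(2 * ang), np.sin(2 * ang)], axis=1)
    c1 = v[np.argmax(np.linalg.norm(rel, axis=1))]
    c1 /= np.linalg.norm(c1)
    c2 = np.array([-c1[1], c1[0]])
    lab = np.zeros(len(v), dtype=bool)
    for _ in range(8):
        lab = np.einsum("ij,j->i", v, c1) < np.einsum("ij,j->i", v, c2)
        if lab.sum() < 3 or (~lab).sum() < 3:
            return None
        c1 = v[~lab].mean(axis=0)
        c2 = v[lab].mean(axis=0)
        n1, n2 = np.linalg.norm(c1), np.linalg.norm(c2)
        if n1 < 1e-9 or n2 < 1e-9:
            return None
        c1, c2 = c1 / n1, c2 / n2

    def _undouble(cv):
        a = 0.5 * np.arctan2(cv[1], cv[0])
        return np.array([np.cos(a), np.sin(a)])

    return pts, lab, (_undouble(c1), _undouble(c2))


def _refine_junction_skeleton(centroid, partition):
    """Intersect total-least-squares line fits of the two skeleton arm families."""
    pts, lab, _ = partition
    lines = []
    for sel in (~lab, lab):
        q = pts[sel]
        m = q.mean(axis=0)
        _, _, vt = np.linalg.svd(q - m, full_matrices=False)
        lines.append((m, vt[0]))
    new = _intersect_lines(lines)
    if new is None or np.linalg.norm(new - centroid) > 2.5:
        return centroid
    return new


def _refine_junction_gray(centroid, partition, image, radius):
    """Sub-pixel refinement on the grayscale ridge.

    For each of the two arm directions, perpendicular intensity profiles are
    sampled (bilinear) at several offsets along the arm, skipping the
    junction core; each profile's intensity-weighted centroid gives one
    point on the true line centre.  The two total-least-squares line fits
    through those points are intersected.  Falls back to the skeleton-based
    estimate when profiles are unusable.
    """
    _, _, dirs = partition
    offsets = np.concatenate(
        [np.arange(-radius, -2.4, 1.0), np.arange(3.0, radius + 0.1, 1.0)]
    )
    ws = np.arange(-3.5, 3.51, 1.0)
    H, W = image.shape
    lines = []
    for u in dirs:
        n = np.array([-u[1], u[0]])
        ridge_pts = []
        for s in offsets:
            P = centroid + s * u + ws[:, None] * n  # (k, 2) as (x, y)
            if (
                P[:, 0].min() < 0
                or P[:, 1].min() < 0
                or P[:, 0].max() > W - 1
                or P[:, 1].max() > H - 1
            ):
                continue
            vals = ndimage.map_coordinates(
                image, [P[:, 1], P[:, 0]], order=1, mode="nearest"
            )
            w = np.clip(vals - vals.min(), 0.0, None)
            if w.sum() < 1e-6:
                continue
            wc = float(w @ ws) / float(w.sum())
            ridge_pts.append(centroid + s * u + wc * n)
        if len(ridge_pts) < 6:
            return None
        q = np.asarray(ridge_pts)
        m = q.mean(axis=0)
        _, _, vt = np.linalg.svd(q - m, full_matrices=False)
        lines.append((m, vt[0]))
    new = _intersect_lines(lines)
    if new is None or np.linalg.norm(new - centroid) > 2.5:
        return None
    return new


def detect_intersections(
    skeleton: np.ndarray,
    threshold: float = 3.0,
    min_separation: float | None = None,
    *,
    refine: bool = True,
    image: np.ndarray | None = None,
) -> IntersectionSet:
    """Find gridline crossings on a skeleton image.

    Candidate pixels must satisfy ``SCN >= threshold`` and
    ``MCN >= threshold`` with ``threshold`` in [3, 4].  8-connected
    candidate clusters are reduced to centroids; centroids closer than
    ``min_separation`` are merged (by default half the median
    nearest-neighbour distance between clusters, a proxy for half the line
    spacing).  With ``refine`` the centroids are polished to sub-pixel
    accuracy by fitting and intersecting the two local line directions —
    on the grayscale ridge when ``image`` (e.g. the intensity-corrected
    image) is supplied, otherwise on the skeleton pixels.
    """
    if not (3.0 <= threshold <= 4.0):
        raise ConfigError(f"threshold must lie in [3, 4], got {threshold}")
    skel = np.asarray(skeleton).astype(bool)
    scn_map = _cpn_map(skel, SCN_RING)
    mcn_map = _cpn_map(skel, MCN_RING)
    cand = skel & (scn_map >= threshold) & (mcn_map >= threshold)
    cand[:2, :] = cand[-2:, :] = False
    cand[:, :2] = cand[:, -2:] = False
    if not np.any(cand):
        return IntersectionSet(
            points=np.zeros((0, 2)), scn=np.zeros(0), mcn=np.zeros(0)
        )

    labels, n_lab = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    index = np.arange(1, n_lab + 1)
    cy, cx = zip(*ndimage.center_of_mass(cand, labels, index))
    pts = np.stack([np.asarray(cx), np.asarray(cy)], axis=-1)
    scn_v = ndimage.maximum(scn_map, labels, index)
    mcn_v = ndimage.maximum(mcn_map, labels, index)
    sizes = ndimage.sum_labels(cand, labels, index).astype(float)

    if min_separation is None:
        if len(pts) >= 2:
            tree = cKDTree(pts)
            nn, _ = tree.query(pts, k=2)
            min_separation = float(np.clip(np.median(nn[:, 1]) / 2.0, 3.0, 25.0))
        else:
            min_separation = 3.0
    if len(pts) >= 2:
        pts, scn_v, mcn_v = _merge_close(pts, scn_v, mcn_v, sizes, min_separation)

    if refine and len(pts):
        ys, xs = np.nonzero(skel)
        skel_pts = np.stack([xs, ys], axis=-1).astype(float)
        tree = cKDTree(skel_pts)
        radius = float(np.clip(0.8 * min_separation, 5.0, 14.0))
        gray = np.asarray(image, dtype=float) if image is not None else None
        refined = []
        for p in pts:
            part = _arm_partition(p, skel_pts, tree, radius)
            if part is None:
                refined.append(p)
                continue
            new = None
            if gray is not None:
                new = _refine_junction_gray(p, part, gray, radius)
            if new is None:
                new = _refine_junction_skeleton(p, part)
            refined.append(new)
        pts = np.array(refined)

    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return IntersectionSet(points=pts[order], scn=scn_v[order], mcn=mcn_v[order])


@dataclass(frozen=True)
class DetectionScore:
    """Detection quality against ground truth (one image)."""

    n_truth: int
    n_detected: int
    n_correct: int
    sensitivity: float
    fpp: int  # false positive points
    fnp: int  # false negative points


def score_detection(
    detected, truth_points: np.ndarray, match_radius: float = 3.0
) -> DetectionScore:
    """Greedy one-to-one nearest matching of detections to truth points."""
    if match_radius <= 0:
        raise ConfigError("match_radius must be positive")
    det = detected.points if isinstance(detected, IntersectionSet) else np.asarray(detected)
    det = det.reshape(-1, 2)
    truth = np.asarray(truth_points, dtype=float).reshape(-1, 2)
    n_t, n_d = len(truth), len(det)
    matched_d = np.zeros(n_d, dtype=bool)
    matched_t = np.zeros(n_t, dtype=bool)
    if n_t and n_d:
        dist = np.linalg.norm(det[:, None, :] - truth[None, :, :], axis=-1)
        pairs = np.argwhere(dist <= match_radius)
        order = np.argsort(dist[pairs[:, 0], pairs[:, 1]])
        for i, j in pairs[order]:
            if not matched_d[i] and not matched_t[j]:
                matched_d[i] = matched_t[j] = True
    n_correct = int(matched_t.sum())
    return DetectionScore(
        n_truth=n_t,
        n_detected=n_d,
        n_correct=n_correct,
        sensitivity=n_correct / n_t if n_t else 0.0,
        fpp=int(n_d - n_correct),
        fnp=int(n_t - n_correct),
    )
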