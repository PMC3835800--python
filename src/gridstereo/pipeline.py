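"""End-to-end stereo reconstruction pipeline.

Chains the stages in their canonical order for both images of a stereo
pair: grayscale inversion -> intensity correction -> ROI masking ->
thresholding -> morphological cleanup -> thinning -> junction detection,
then cross-image matching under the epipolar constraint, triangulation of
the matched grid and smooth surface fitting.  The per-stage counts that a
validation protocol reports (detected / matched / reconstructed /
discarded) are collected along the way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from . import features, matching, preprocess
from .config import PipelineConfig
from .errors import GridStereoError
from .features import IntersectionSet
from .geometry import StereoRig, fundamental_matrix, undistorted_pixels
from .matching import MatchedGrid
from .surface import GridSurface, fit_surface, reconstruct_grid
from .synthetic import GridPattern

__all__ = [
    "detect_image",
    "reconstruct_pair",
    "reconstruct_from_detections",
    "PipelineResult",
]


def detect_image(image: np.ndarray, config: PipelineConfig | None = None):
    """Run the single-image half of the pipeline.

    Returns ``(intersections, stages)`` where ``stages`` is a dict of the
    intermediate rasters (inverted, corrected, roi, binary, skeleton) for
    inspection and debugging.
    """
    cfg = config if config is not None else PipelineConfig()
    inverted = preprocess.to_gray_inverted(image)
    if cfg.intensity_correction:
        corrected = preprocess.intensity_correct(
            inverted, cfg.correction_window, mode=cfg.correction_mode
        )
        method = cfg.threshold_method
    else:
        # without correction there is no flat background to key on; use the
        # conventional histogram threshold (this is the ablated condition)
        corrected = inverted
        method = "otsu" if cfg.threshold_method == "background" else cfg.threshold_method
    roi = None
    mask = None
    if cfg.roi:
        roi = preprocess.detect_roi(
            corrected,
            cfg.roi_close_radius,
            cfg.roi_min_area_fraction,
            threshold_method=method if method != "fixed" else "otsu",
        )
        mask = roi.mask
    binary = preprocess.binarize(
        corrected, method, cfg.threshold_level, mask=mask
    )
    cleaned = preprocess.clean_binary(
        binary, cfg.clean_radius, cfg.clean_min_size, cfg.clean_max_hole
    )
    skeleton = features.thin(cleaned)
    intersections = features.detect_intersections(
        skeleton,
        cfg.cpn_threshold,
        cfg.min_separation,
        refine=cfg.refine,
        image=corrected if cfg.refine else None,
    )
    stages = {
        "inverted": inverted,
        "corrected": corrected,
        "roi": roi,
        "binary": binary,
        "cleaned": cleaned,
        "skeleton": skeleton,
    }
    return intersections, stages


@dataclass
class PipelineResult:
    """Everything the reconstruction half of the pipeline produced."""

    intersections_left: IntersectionSet
    intersections_right: IntersectionSet
    matches: MatchedGrid
    grid: GridSurface
    mesh: trimesh.Trimesh
    counts: dict = field(default_factory=dict)


def reconstruct_pair(
    left_image: np.ndarray,
    right_image: np.ndarray,
    rig: StereoRig,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Reconstruct a smooth 3D surface patch from one stereo pair.

    Detection coordinates are undistorted once and used consistently for
    epipolar matching (pixel-space distance to the epipolar line) and
    triangulation.  Raises the stage-specific :class:`GridStereoError`
    subclasses on failure.
    """
    cfg = config if config is not None else PipelineConfig()
    det_l, _ = detect_image(left_image, cfg)
    det_r, _ = detect_image(right_image, cfg)
    return reconstruct_from_detections(det_l, det_r, rig, cfg)


def reconstruct_from_detections(
    det_l: IntersectionSet,
    det_r: IntersectionSet,
    rig: StereoRig,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Matching + triangulation + surface fit for already-detected crossings."""
    cfg = config if config is not None else PipelineConfig()
    und_l = IntersectionSet(
        points=undistorted_pixels(rig.left, det_l.points) if len(det_l) else det_l.points,
        scn=det_l.scn, mcn=det_l.mcn, source="left",
    )
    und_r = IntersectionSet(
        points=undistorted_pixels(rig.right, det_r.points) if len(det_r) else det_r.points,
        scn=det_r.scn, mcn=det_r.mcn, source="right",
    )
    pattern = GridPattern(rows=cfg.pattern_rows, cols=cfg.pattern_cols)
    idx_l = matching.assign_grid_indices(und_l, pattern)
    idx_r = matching.assign_grid_indices(und_r, pattern)
    F = fundamental_matrix(rig)
    matches = matching.match_epipolar(idx_l, idx_r, F, cfg.epipolar_tol)
    grid = reconstruct_grid(matches, rig, cfg.max_ray_gap_mm, pixels_undistorted=True)
    mesh = fit_surface(grid, cfg.upsample, method=cfg.surface_method)
    counts = {
        "detected_left": len(det_l),
        "detected_right": len(det_r),
        "matched": len(matches),
        "discarded_left": matches.n_discarded_left,
        "discarded_right": matches.n_discarded_right,
        "grid_points": grid.n_points,
        "dropped_gap": grid.n_dropped,
    }
    return PipelineResult(
        intersections_left=det_l,
        intersections_right=det_r,
        matches=matches,
        grid=grid,
        mesh=mesh,
        counts=counts,
    )
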